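"""Confusion-count statistics and dataset-similarity characterization.

The statistic suite mirrors the standard screening-evaluation table:
sensitivity, specificity, the two error ratios, predictive values, correct
and misclassification rates, and F1.  One deliberate quirk is preserved
from the source convention: the false-positive ratio is computed against
the positive total (fp / (tp + fn)), *not* as 1 - specificity; a note is
logged whenever it is reported.

Display values are truncated (not rounded) to three decimals, which is the
convention the reference results table uses (e.g. an NPV of 85/95 = 0.8947
prints as 0.894).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

_ROW_ORDER = (
    ("Sensitivity", "sensitivity"),
    ("Specificity", "specificity"),
    ("False-negative ratio", "false_negative_ratio"),
    ("False-positive ratio", "false_positive_ratio"),
    ("Positive prediction value", "ppv"),
    ("Negative prediction value", "npv"),
    ("Correct classification ratio", "correct_classification_ratio"),
    ("Misclassification ratio", "misclassification_ratio"),
    ("F1 Score", "f1"),
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fn + other.fn,
            self.tn + other.tn,
            self.fp + other.fp,
        )


@dataclass(frozen=True)
class MetricsReport:
    """All statistics for one confusion matrix.

    A statistic whose denominator is zero is NaN and its field name is
    listed in ``undefined`` — it is never silently coerced to 0.
    """

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    false_negative_ratio: float
    false_positive_ratio: float
    ppv: float
    npv: float
    correct_classification_ratio: float
    misclassification_ratio: float
    f1: float
    undefined: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict:
        out = {"counts": {"tp": self.counts.tp, "fn": self.counts.fn,
                          "tn": self.counts.tn, "fp": self.counts.fp}}
        for _, key in _ROW_ORDER:
            value = getattr(self, key)
            out[key] = None if key in self.undefined else value
        out["undefined"] = sorted(self.undefined)
        return out

    def to_table(self) -> str:
        """Aligned text table in the canonical row order."""
        width = max(len(label) for label, _ in _ROW_ORDER)
        lines = [f"{'Parameter':<{width}}  Result"]
        for label, key in _ROW_ORDER:
            value = "n/a" if key in self.undefined else format_display(getattr(self, key))
            lines.append(f"{label:<{width}}  {value}")
        return "\n".join(lines)


def format_display(value: float, decimals: int = 3) -> str:
    """Truncate toward zero at ``decimals`` places for display."""
    scale = 10**decimals
    return f"{math.floor(value * scale + 1e-12) / scale:.{decimals}f}"


def _ratio(num: float, den: float, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return float("nan")
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Evaluate every statistic of the suite from raw counts."""
    if c.total == 0:
        raise ValueError("all four confusion counts are zero")
    undefined: set[str] = set()
    pos = c.tp + c.fn
    neg = c.tn + c.fp
    sensitivity = _ratio(c.tp, pos, "sensitivity", undefined)
    specificity = _ratio(c.tn, neg, "specificity", undefined)
    fnr = _ratio(c.fn, pos, "false_negative_ratio", undefined)
    # source convention: fp over the positive total, not 1 - specificity
    fpr = _ratio(c.fp, pos, "false_positive_ratio", undefined)
    if "false_positive_ratio" not in undefined:
        logger.debug(
            "false_positive_ratio uses fp/(tp+fn) by convention; "
            "it is not 1 - specificity"
        )
    ppv = _ratio(c.tp, c.tp + c.fp, "ppv", undefined)
    npv = _ratio(c.tn, c.tn + c.fn, "npv", undefined)
    correct = (c.tp + c.tn) / c.total
    miscls = (c.fp + c.fn) / c.total
    if "ppv" in undefined or "sensitivity" in undefined or ppv + sensitivity == 0:
        undefined.add("f1")
        f1 = float("nan")
    else:
        f1 = 2.0 * ppv * sensitivity / (ppv + sensitivity)
    return MetricsReport(
        counts=c,
        sensitivity=sensitivity,
        specificity=specificity,
        false_negative_ratio=fnr,
        false_positive_ratio=fpr,
        ppv=ppv,
        npv=npv,
        correct_classification_ratio=correct,
        misclassification_ratio=miscls,
        f1=f1,
        undefined=frozenset(undefined),
    )


def counts_from_labels(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts from parallel +1/-1 (or boolean) label arrays."""
    t = np.asarray(y_true) > 0
    p = np.asarray(y_pred) > 0
    if t.shape != p.shape:
        raise ValueError("label arrays must have equal length")
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
    )


def pairwise_similarity(
    pos_features,
    neg_features,
    statistic=None,
) -> tuple[np.ndarray, float]:
    """Location-test p-values for index-paired positive/negative features.

    Each positive feature vector is compared element-wise against its paired
    negative vector with a two-sample test (independent t-test by default;
    pass ``statistic(x, y) -> p`` to substitute another).  A NaN p-value —
    which arises when the negative vector is empty of edge content (all
    zeros, hence zero variance against an all-zero positive complement) — is
    recorded as 0 by convention before averaging: such a pair is maximally
    dissimilar from a worm-bearing sample, not missing data.

    Returns the per-pair p-values and their mean.
    """
    if len(pos_features) == 0 or len(neg_features) == 0:
        raise ValueError("feature lists must be nonempty")
    if len(pos_features) != len(neg_features):
        raise ValueError("positive and negative lists must pair by index")
    if statistic is None:
        def statistic(x, y):
            return stats.ttest_ind(x, y).pvalue

    p_values = np.empty(len(pos_features))
    for i, (x, y) in enumerate(zip(pos_features, neg_features)):
        p = statistic(np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64))
        p_values[i] = 0.0 if np.isnan(p) else p
    return p_values, float(p_values.mean())
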