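"""Kernel SVM over HOG features, with the histogram intersection kernel.

The intersection kernel K(x, y) = sum_d min(x_d, y_d) measures how much of
two nonnegative histograms overlaps; it is positive semidefinite on
nonnegative inputs and cheap to evaluate, which made it the kernel of
choice for smartphone-side classification.  The soft-margin dual problem
is solved through scikit-learn's libsvm binding on a precomputed Gram
matrix (any solver satisfying the KKT conditions would be conforming);
the trained state — support vectors, dual coefficients alpha_i * y_i,
bias, and the feature-configuration fingerprint — is kept explicitly so
decision values can be recomputed as f(z) = sum_i a_i K(s_i, z) + b.

A Gaussian RBF kernel is retained as a configuration option; its gamma is
stored but inert under the intersection kernel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ConfigurationError, TrainingError
from .metrics import MetricsReport, compute_metrics, counts_from_labels

MODEL_FORMAT_VERSION = 1
_MODEL_MAGIC = b"PLATEWORM-MODEL\n"

POSITIVE, NEGATIVE = 1, -1
LABEL_MAP = {"positive": POSITIVE, "negative": NEGATIVE}


@dataclass(frozen=True)
class SvmConfig:
    C: float = 12.5
    kernel: str = "intersection"
    gamma: float = 0.5
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.kernel not in ("intersection", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.kernel == "rbf" and self.gamma <= 0:
            raise ValueError("gamma must be positive for the rbf kernel")

    def as_dict(self) -> dict:
        return {"C": self.C, "kernel": self.kernel, "gamma": self.gamma,
                "cv_folds": self.cv_folds, "seed": self.seed}


@dataclass
class TrainedModel:
    support_vectors: np.ndarray  # (n_sv, d)
    dual_coefficients: np.ndarray  # alpha_i * y_i, signed
    bias: float
    svm_config: SvmConfig
    fingerprint: str = ""
    label_map: dict = field(default_factory=lambda: dict(LABEL_MAP))

    @property
    def n_support(self) -> int:
        return len(self.dual_coefficients)

    def check_fingerprint(self, fingerprint: str) -> None:
        if self.fingerprint and fingerprint != self.fingerprint:
            raise ConfigurationError(
                "feature configuration fingerprint mismatch: model was "
                f"trained with {self.fingerprint}, pipeline has {fingerprint}"
            )


def intersection_kernel(x: np.ndarray, y: np.ndarray) -> float:
    """Histogram intersection of two nonnegative vectors."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("intersection kernel requires nonnegative entries")
    return float(np.minimum(x, y).sum())


def intersection_gram(X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    """Gram matrix K[i, j] = sum_d min(X[i, d], Y[j, d]).

    Row-chunked so the min buffer stays small; float32 accumulation of the
    elementwise minima keeps memory traffic down without affecting the
    decision sign at HOG feature scales.
    """
    X = np.asarray(X, dtype=np.float32)
    Y = X if Y is None else np.asarray(Y, dtype=np.float32)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError(f"feature matrices disagree: {X.shape} vs {Y.shape}")
    if (X < 0).any() or (Y < 0).any():
        raise ValueError("intersection kernel requires nonnegative entries")
    out = np.empty((X.shape[0], Y.shape[0]), dtype=np.float64)
    for i in range(X.shape[0]):
        out[i] = np.minimum(X[i], Y).sum(axis=1, dtype=np.float64)
    return out


def _gram(config: SvmConfig, X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    if config.kernel == "intersection":
        return intersection_gram(X, Y)
    return rbf_kernel(X, X if Y is None else Y, gamma=config.gamma)


def _as_signed_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "US":
        try:
            return np.array([LABEL_MAP[str(v)] for v in arr], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"unknown label {exc.args[0]!r}") from None
    return np.where(np.asarray(arr, dtype=np.float64) > 0, POSITIVE, NEGATIVE)


def train(
    features: np.ndarray,
    labels,
    config: SvmConfig | None = None,
    fingerprint: str = "",
) -> TrainedModel:
    """Fit the soft-margin kernel SVM on labeled feature vectors.

    Deterministic for a fixed input order: the dual problem has a unique
    decision function and libsvm's solver introduces no randomness for
    binary classification without probability estimates.
    """
    cfg = config or SvmConfig()
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if np.isnan(X).any():
        raise ValueError("features contain NaN")
    y = _as_signed_labels(labels)
    if len(y) != len(X):
        raise ValueError("feature/label length mismatch")
    if len(np.unique(y)) < 2:
        raise TrainingError("training requires at least one example per class")

    gram = _gram(cfg, X)
    svc = SVC(C=cfg.C, kernel="precomputed")
    svc.fit(gram, y)
    return TrainedModel(
        support_vectors=X[svc.support_].copy(),
        dual_coefficients=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        svm_config=cfg,
        fingerprint=fingerprint,
    )


def decision_values(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """f(z) = sum_i a_i K(s_i, z) + b for each row z of ``features``."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.support_vectors.shape[1]:
        raise ValueError(
            f"feature length {X.shape[1]} does not match model "
            f"({model.support_vectors.shape[1]})"
        )
    K = _gram(model.svm_config, X, model.support_vectors)
    return K @ model.dual_coefficients + model.bias


def predict(
    model: TrainedModel, features: np.ndarray, fingerprint: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Signed labels (+1 worm / -1 background) and raw decision values.

    A decision value of exactly zero maps to the negative class — on a
    plate, the cheaper error is a missed frame, not a spurious one.
    """
    if fingerprint is not None:
        model.check_fingerprint(fingerprint)
    f = decision_values(model, features)
    labels = np.where(f > 0, POSITIVE, NEGATIVE)
    return labels, f


def cross_validate(
    features: np.ndarray, labels, config: SvmConfig | None = None
) -> tuple[list[MetricsReport], MetricsReport]:
    """Stratified k-fold error estimate (no hyperparameter search).

    Returns per-fold reports and the report pooled over all folds'
    held-out predictions.  The fold shuffle is seeded from the config.
    """
    cfg = config or SvmConfig()
    X = np.asarray(features, dtype=np.float64)
    y = _as_signed_labels(labels)
    if len(X) < cfg.cv_folds:
        raise ValueError(f"need at least cv_folds={cfg.cv_folds} samples")
    gram = _gram(cfg, X)
    splitter = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    fold_reports = []
    pooled_true, pooled_pred = [], []
    for train_idx, test_idx in splitter.split(X, y):
        if len(np.unique(y[train_idx])) < 2:
            raise TrainingError("a class is absent from a training fold")
        svc = SVC(C=cfg.C, kernel="precomputed")
        svc.fit(gram[np.ix_(train_idx, train_idx)], y[train_idx])
        pred = svc.predict(gram[np.ix_(test_idx, train_idx)])
        fold_reports.append(compute_metrics(counts_from_labels(y[test_idx], pred)))
        pooled_true.append(y[test_idx])
        pooled_pred.append(pred)
    pooled = compute_metrics(
        counts_from_labels(np.concatenate(pooled_true), np.concatenate(pooled_pred))
    )
    return fold_reports, pooled


def save_model(model: TrainedModel, path) -> None:
    """Write the model archive (deterministic bytes for identical models).

    Layout: magic line, JSON header line (format version, configs, array
    shapes), then the raw little-endian float64 bytes of the support
    vectors followed by the dual coefficients.
    """
    sv = np.ascontiguousarray(model.support_vectors, dtype="<f8")
    dc = np.ascontiguousarray(model.dual_coefficients, dtype="<f8")
    header = {
        "format_version": MODEL_FORMAT_VERSION,
        "svm_config": model.svm_config.as_dict(),
        "fingerprint": model.fingerprint,
        "label_map": model.label_map,
        "bias": model.bias,
        "sv_shape": list(sv.shape),
        "n_dual": len(dc),
    }
    from .io import atomic_write_bytes

    blob = (
        _MODEL_MAGIC
        + json.dumps(header, sort_keys=True).encode()
        + b"\n"
        + sv.tobytes()
        + dc.tobytes()
    )
    atomic_write_bytes(path, blob)


def load_model(path) -> TrainedModel:
    with open(path, "rb") as fh:
        blob = fh.read()
    if not blob.startswith(_MODEL_MAGIC):
        raise ConfigurationError(f"{path} is not a model archive")
    rest = blob[len(_MODEL_MAGIC):]
    header_line, _, payload = rest.partition(b"\n")
    header = json.loads(header_line)
    if header["format_version"] > MODEL_FORMAT_VERSION:
        raise ConfigurationError(
            f"model format version {header['format_version']} is newer than "
            f"supported version {MODEL_FORMAT_VERSION}"
        )
    n_sv, d = header["sv_shape"]
    sv_bytes = n_sv * d * 8
    sv = np.frombuffer(payload[:sv_bytes], dtype="<f8").reshape(n_sv, d).copy()
    dc = np.frombuffer(payload[sv_bytes : sv_bytes + header["n_dual"] * 8], dtype="<f8").copy()
    return TrainedModel(
        support_vectors=sv,
        dual_coefficients=dc,
        bias=float(header["bias"]),
        svm_config=SvmConfig(**header["svm_config"]),
        fingerprint=header["fingerprint"],
        label_map=header["label_map"],
    )
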