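"""End-to-end crop experiment: generate, featurize, train, evaluate.

This is the reference experiment of the package: a balanced labeled crop
set is generated synthetically (600 positive / 600 negative by default),
split 1000 train / 200 test with both splits balanced, the preprocessing
and HOG chain turns each 168-px crop into a 14 400-element feature
vector, the intersection-kernel SVM is trained at C = 12.5, and the
held-out crops are scored with the full statistic suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .classifier import SvmConfig, TrainedModel, predict, train
from .hog import HogConfig, feature_fingerprint, window_descriptor
from .metrics import MetricsReport, compute_metrics, counts_from_labels
from .preprocess import PreprocessConfig, preprocess
from .synthetic import LabeledCropSet, SceneConfig, make_crop_set


def crop_features(
    crops: np.ndarray,
    preprocess_config: PreprocessConfig | None = None,
    hog_config: HogConfig | None = None,
) -> np.ndarray:
    """Preprocess each crop independently and extract its HOG descriptor."""
    pre_cfg = preprocess_config or PreprocessConfig()
    hog_cfg = hog_config or HogConfig(window_size=crops.shape[1])
    out = np.empty((len(crops), hog_cfg.descriptor_length))
    for i, crop in enumerate(crops):
        out[i] = window_descriptor(preprocess(crop, pre_cfg), (0, 0), hog_cfg)
    return out


@dataclass
class CropExperiment:
    """Everything produced by one train/test run on synthetic crops."""

    train_set: LabeledCropSet
    test_set: LabeledCropSet
    model: TrainedModel
    report: MetricsReport
    decision_values: np.ndarray
    fingerprint: str


def run_crop_experiment(
    seed: int = 0,
    n_train_per_class: int = 500,
    n_test_per_class: int = 100,
    scene_config: SceneConfig | None = None,
    preprocess_config: PreprocessConfig | None = None,
    hog_config: HogConfig | None = None,
    svm_config: SvmConfig | None = None,
) -> CropExperiment:
    """Run the full balanced train/test experiment at the default geometry.

    The train and test sets come from disjoint seeded streams derived from
    ``seed``, so enlarging one set never perturbs the other.
    """
    base = scene_config or SceneConfig()
    pre_cfg = preprocess_config or PreprocessConfig()
    hog_cfg = hog_config or HogConfig()
    svm_cfg = svm_config or SvmConfig(seed=seed)

    train_seed, test_seed = np.random.SeedSequence(seed).generate_state(2) >> 1
    train_set = make_crop_set(
        n_train_per_class, n_train_per_class,
        replace(base, seed=int(train_seed)),
        crop_size=hog_cfg.window_size,
    )
    test_set = make_crop_set(
        n_test_per_class, n_test_per_class,
        replace(base, seed=int(test_seed)),
        crop_size=hog_cfg.window_size,
    )

    fingerprint = feature_fingerprint(hog_cfg, pre_cfg)
    X_train = crop_features(train_set.crops, pre_cfg, hog_cfg)
    X_test = crop_features(test_set.crops, pre_cfg, hog_cfg)
    model = train(X_train, train_set.labels, svm_cfg, fingerprint=fingerprint)
    pred, values = predict(model, X_test, fingerprint=fingerprint)
    truth = np.where(np.array(test_set.labels) == "positive", 1, -1)
    report = compute_metrics(counts_from_labels(truth, pred))
    return CropExperiment(
        train_set=train_set,
        test_set=test_set,
        model=model,
        report=report,
        decision_values=values,
        fingerprint=fingerprint,
    )
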