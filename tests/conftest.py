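import numpy as np
import pytest

import plateworm as pw


@pytest.fixture
def rng():
    return np.random.default_rng(77)


@pytest.fixture(scope="session")
def full_experiment():
    """Full-scale balanced experiment: 1000 training / 200 test crops.

    Shared across the suite because training the intersection-kernel SVM on
    1000 crops dominates runtime; every consumer treats it as read-only.
    """
    return pw.run_crop_experiment(seed=0)


@pytest.fixture(scope="session")
def full_model(full_experiment):
    return full_experiment.model


@pytest.fixture(scope="session")
def small_experiment():
    """Cheap 80-crop experiment for tests that only need a valid model."""
    return pw.run_crop_experiment(seed=123, n_train_per_class=40, n_test_per_class=10)


@pytest.fixture(scope="session")
def small_model(small_experiment):
    return small_experiment.model
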