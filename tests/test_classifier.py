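import itertools

import numpy as np
import pytest

from oracles import decision_bruteforce, dual_objective
from plateworm.classifier import (
    SvmConfig,
    cross_validate,
    decision_values,
    intersection_gram,
    intersection_kernel,
    load_model,
    predict,
    save_model,
    train,
)
from plateworm.errors import ConfigurationError, TrainingError

TOY_X = np.array([[0.1], [0.2], [0.9], [1.0]])
TOY_Y = np.array([-1, -1, 1, 1])


class TestIntersectionKernel:
    def test_self_kernel_is_total_mass(self, rng):
        x = rng.uniform(0, 3, size=20)
        assert intersection_kernel(x, x) == pytest.approx(x.sum())

    def test_hand_example(self):
        assert intersection_kernel([1, 2, 3], [3, 2, 1]) == 4.0

    def test_zero_vector_annihilates(self, rng):
        x = rng.uniform(0, 3, size=12)
        assert intersection_kernel(x, np.zeros(12)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            intersection_kernel([1, 2], [1, 2, 3])

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            intersection_kernel([-1.0, 2.0], [1.0, 2.0])

    def test_gram_matrix_symmetric_psd(self, rng):
        X = rng.uniform(0, 1, size=(30, 15))
        G = intersection_gram(X)
        assert np.allclose(G, G.T)
        assert np.linalg.eigvalsh(G).min() >= -1e-8

    def test_gram_agrees_with_scalar_kernel(self, rng):
        X = rng.uniform(0, 1, size=(5, 8))
        Y = rng.uniform(0, 1, size=(4, 8))
        G = intersection_gram(X, Y)
        for i in range(5):
            for j in range(4):
                assert G[i, j] == pytest.approx(intersection_kernel(X[i], Y[j]), abs=1e-6)


class TestTraining:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        model = train(TOY_X, TOY_Y, SvmConfig())
        labels, _ = predict(model, TOY_X)
        assert np.array_equal(labels, TOY_Y)

    def test_dual_solution_matches_gridsearch_oracle(self):
        """libsvm's dual objective on the 4-point toy must match (within
        grid resolution) an exhaustive search over feasible alpha vectors."""
        cfg = SvmConfig(C=12.5)
        model = train(TOY_X, TOY_Y, cfg)
        gram = intersection_gram(TOY_X)
        achieved = dual_objective(
            intersection_gram(model.support_vectors), model.dual_coefficients
        )
        best = -np.inf
        grid = np.linspace(0, cfg.C, 26)
        for a in itertools.product(grid, repeat=4):
            a = np.array(a)
            if abs((a * TOY_Y).sum()) > 1e-9:
                continue
            best = max(best, dual_objective(gram, a * TOY_Y))
        assert achieved >= best - 0.05

    def test_kkt_conditions(self, small_model):
        cfg = small_model.svm_config
        assert np.all(np.abs(small_model.dual_coefficients) <= cfg.C + 1e-9)
        assert abs(small_model.dual_coefficients.sum()) < 1e-6

    def test_duplicated_training_set_same_decision_function(self, rng):
        X = rng.uniform(0, 1, size=(20, 6))
        y = np.where(X.sum(axis=1) > 3, 1, -1)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        probes = rng.uniform(0, 1, size=(7, 6))
        f1 = decision_values(train(X, y), probes)
        f2 = decision_values(train(np.vstack([X, X]), np.concatenate([y, y])), probes)
        # agreement is limited by the dual solver's convergence tolerance
        assert np.allclose(f1, f2, atol=1e-3)

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError):
            train(TOY_X, np.ones(4), SvmConfig())

    def test_nan_features_rejected(self):
        X = TOY_X.copy()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train(X, TOY_Y)

    def test_string_labels_accepted(self):
        model = train(TOY_X, ["negative", "negative", "positive", "positive"])
        labels, _ = predict(model, TOY_X)
        assert np.array_equal(labels, TOY_Y)


class TestPredict:
    def test_support_vectors_classified_as_own_label(self):
        model = train(TOY_X, TOY_Y)
        labels, _ = predict(model, model.support_vectors)
        # the toy is separable with margin: every SV sits on its own side
        signs = np.sign(model.dual_coefficients).astype(int)
        assert np.array_equal(labels, signs)

    def test_decision_values_permutation_equivariant(self, small_model, rng):
        probes = rng.uniform(0, 0.5, size=(9, small_model.support_vectors.shape[1]))
        perm = rng.permutation(9)
        f = decision_values(small_model, probes)
        # equivariant up to the reduction order of the threaded BLAS
        assert np.allclose(f[perm], decision_values(small_model, probes[perm]),
                           rtol=1e-12, atol=1e-12)

    def test_matches_explicit_kernel_expansion(self, small_model, rng):
        probes = rng.uniform(0, 0.3, size=(10, small_model.support_vectors.shape[1]))
        f = decision_values(small_model, probes)
        for i in range(10):
            assert f[i] == pytest.approx(decision_bruteforce(small_model, probes[i]), abs=1e-8)

    def test_fingerprint_mismatch_refused(self, small_model):
        with pytest.raises(ConfigurationError):
            predict(small_model, small_model.support_vectors[:1], fingerprint="bogus")


class TestPersistence:
    def test_save_load_predict_bit_identical(self, small_model, tmp_path, rng):
        path = tmp_path / "model.bin"
        save_model(small_model, path)
        loaded = load_model(path)
        probes = rng.uniform(0, 0.4, size=(6, small_model.support_vectors.shape[1]))
        assert np.array_equal(
            decision_values(small_model, probes), decision_values(loaded, probes)
        )
        assert loaded.fingerprint == small_model.fingerprint
        assert loaded.svm_config == small_model.svm_config

    def test_save_is_deterministic(self, small_model, tmp_path):
        p1, p2 = tmp_path / "a.bin", tmp_path / "b.bin"
        save_model(small_model, p1)
        save_model(small_model, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_newer_format_version_refused(self, small_model, tmp_path):
        path = tmp_path / "model.bin"
        save_model(small_model, path)
        blob = path.read_bytes().replace(b'"format_version": 1', b'"format_version": 9')
        path.write_bytes(blob)
        with pytest.raises(ConfigurationError):
            load_model(path)


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(5)
    X = rng.uniform(0, 1, size=(100, 8))
    y = np.where(X[:, 0] + X[:, 1] > 1, 1, -1)
    return X, y


class TestCrossValidation:
    def test_ten_folds_of_equal_size(self, toy_data):
        X, y = toy_data
        folds, pooled = cross_validate(X, y, SvmConfig(cv_folds=10, seed=3))
        assert len(folds) == 10
        assert all(r.counts.total == 10 for r in folds)
        assert pooled.counts.total == 100

    def test_same_seed_same_folds(self, toy_data):
        X, y = toy_data
        folds1, _ = cross_validate(X, y, SvmConfig(cv_folds=5, seed=9))
        folds2, _ = cross_validate(X, y, SvmConfig(cv_folds=5, seed=9))
        for a, b in zip(folds1, folds2):
            assert a.counts == b.counts

    def test_pooled_counts_partition_the_sample(self, toy_data):
        X, y = toy_data
        folds, pooled = cross_validate(X, y, SvmConfig(cv_folds=4, seed=1))
        assert sum(r.counts.total for r in folds) == pooled.counts.total == len(X)

    def test_too_few_samples_rejected(self, rng):
        X = rng.uniform(0, 1, size=(5, 3))
        with pytest.raises(ValueError):
            cross_validate(X, [1, 1, 1, -1, -1], SvmConfig(cv_folds=10))
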