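import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from swarmfs.data import SyntheticSpec, TabularDataset, generate_synthetic
from swarmfs.features import (
    binarize,
    estimate_error,
    select_features,
    sigmoid_transfer,
    subset_fitness,
    _fold_indices,
)


class TestTransferAndBinarize:
    def test_sigmoid_values(self):
        assert sigmoid_transfer(0.0) == 0.5
        assert sigmoid_transfer(2.0) == pytest.approx(0.8807970779778823)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-30, 30))
    def test_sigmoid_odd_symmetry(self, x):
        assert sigmoid_transfer(x) + sigmoid_transfer(-x) == pytest.approx(1.0)

    def test_binarize_threshold_behaviour(self):
        class _Rng:
            def __init__(self, r):
                self.r = r

            def random(self, size=None):
                return np.full(size, self.r)

            def integers(self, n):
                return 0

        # position 0 has T = 0.5: draw below selects, draw above does not
        assert binarize(np.array([0.0, 40.0]), _Rng(0.3))[0] == 1
        assert binarize(np.array([0.0, 40.0]), _Rng(0.7))[0] == 0

    def test_saturated_positions(self):
        rng = np.random.default_rng(0)
        assert np.all(binarize(np.full(20, 40.0), rng) == 1)

    def test_all_zero_mask_repaired_to_single_bit(self):
        rng = np.random.default_rng(1)
        mask = binarize(np.full(20, -40.0), rng)
        assert mask.sum() == 1


class TestSubsetFitness:
    def test_hand_evaluated_weighting(self):
        mask = np.array([1, 1, 1, 1] + [0] * 9)
        assert subset_fitness(mask, 0.1, 0.99, 13) == pytest.approx(0.1020769230769231)

    def test_pure_error_and_pure_size_limits(self):
        m = np.ones(6, dtype=int)
        assert subset_fitness(m, 0.37, 1.0, 6) == pytest.approx(0.37)
        assert subset_fitness(m, 0.37, 0.0, 6) == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            subset_fitness(np.zeros(5, dtype=int), 0.1, 0.99, 5)

    def test_monotone_in_error_and_size(self):
        D = 12
        for omega in (0.3, 0.7, 0.99):
            fits = [subset_fitness(np.ones(D), e, omega, D) for e in np.linspace(0, 1, 11)]
            assert np.all(np.diff(fits) > 0)
            by_size = [
                subset_fitness(np.r_[np.ones(k), np.zeros(D - k)], 0.2, omega, D)
                for k in range(1, D + 1)
            ]
            if omega < 1:
                assert np.all(np.diff(by_size) > 0)


class TestEstimateError:
    def test_label_leak_gives_zero_error(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 80)
        X = np.c_[y.astype(float), rng.normal(size=(80, 3))]
        ds = TabularDataset(X, y, [f"f{i}" for i in range(4)])
        mask = np.array([1, 0, 0, 0])
        assert estimate_error(mask, ds, folds=5, seed=0) == 0.0

    def test_deterministic(self, default_dataset):
        mask = np.array([1] * 5 + [0] * 8)
        a = estimate_error(mask, default_dataset, folds=5, seed=3)
        assert a == estimate_error(mask, default_dataset, folds=5, seed=3)

    def test_permuted_labels_approach_chance(self):
        rng = np.random.default_rng(5)
        ds0 = generate_synthetic(SyntheticSpec(n=400, D=6, m_informative=2, seed=5))
        y_perm = ds0.y.copy()
        rng.shuffle(y_perm)
        ds = TabularDataset(ds0.X, y_perm, ds0.feature_names)
        err = estimate_error(np.ones(6, dtype=int), ds, folds=5, seed=0)
        chance = 1 - max(np.mean(y_perm), 1 - np.mean(y_perm))  # minority rate
        assert abs(err - chance) < 0.1

    def test_single_class_fold_refused(self):
        # 3 positives cannot be stratified into 5 folds
        y = np.r_[np.ones(3, dtype=int), np.zeros(47, dtype=int)]
        X = np.random.default_rng(0).normal(size=(50, 4))
        ds = TabularDataset(X, y, list("abcd"))
        with pytest.raises(ValueError):
            estimate_error(np.ones(4, dtype=int), ds, folds=5, seed=0)

    def test_fast_knn_agrees_with_sklearn_pipeline(self, default_dataset):
        """Dual-route check: vectorized 1-NN CV error == sklearn estimator route."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            mask = rng.integers(0, 2, 13)
            if not mask.any():
                mask[0] = 1
            fast = estimate_error(mask, default_dataset, folds=5, seed=2)
            skl_est = KNeighborsClassifier(n_neighbors=1)
            splits = _fold_indices(default_dataset, 5, 2)
            X = default_dataset.X[:, mask.astype(bool)]
            y = default_dataset.y
            wrong = 0
            for tr, te in splits:
                pipe = make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=1))
                pipe.fit(X[tr], y[tr])
                wrong += int(np.sum(pipe.predict(X[te]) != y[te]))
            assert fast == pytest.approx(wrong / y.size)


class TestSelectFeatures:
    def test_label_leak_feature_always_selected(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 100)
        X = np.c_[y.astype(float) + 0.01 * rng.normal(size=100), rng.normal(size=(100, 5))]
        ds = TabularDataset(X, y, [f"f{i}" for i in range(6)])
        res = select_features(ds, num_sardines=20, max_iter=30, seed=0)
        assert res.mask[0] == 1
        assert res.error_rate <= 0.05

    def test_deterministic_result(self, small_dataset):
        a = select_features(small_dataset, num_sardines=20, max_iter=20, seed=4)
        b = select_features(small_dataset, num_sardines=20, max_iter=20, seed=4)
        assert np.array_equal(a.mask, b.mask)
        assert a.fitness == b.fitness
        assert a.n_estimator_calls == b.n_estimator_calls

    def test_result_is_internally_consistent(self, small_dataset):
        res = select_features(small_dataset, num_sardines=20, max_iter=20, seed=4)
        assert res.n_selected == int(res.mask.sum()) >= 1
        assert res.fitness == pytest.approx(
            0.99 * res.error_rate + 0.01 * res.n_selected / small_dataset.n_features
        )
        assert np.all(np.diff(res.history) <= 1e-15)
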