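"""Gain-ratio tree, forest, stratified cross-validation, and metrics."""

import numpy as np
import pandas as pd
import pytest

from raacdip.classify import (
    ConfusionCounts,
    best_split,
    compute_metrics,
    confusion_from_predictions,
    cross_validate,
    stratified_folds,
    train_forest,
    train_tree,
)
from raacdip.features import FeatureMatrix


def make_matrix(X, y, names=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and len(y) > 1:
        X = X.T
    names = names or [f"f{j}" for j in range(X.shape[1])]
    data = pd.DataFrame(X, columns=names, index=[f"s{i}" for i in range(X.shape[0])])
    return FeatureMatrix(data, pd.Series(y, index=data.index))


# ---------------------------------------------------------------------------
# metrics


class TestMetrics:
    def test_sensitivity_direct_formula(self):
        se, sp, acc = compute_metrics(ConfusionCounts(TP=50, TN=0, FP=0, FN=50))
        assert se == pytest.approx(0.5)

    def test_accuracy_arithmetic(self):
        se, sp, acc = compute_metrics(ConfusionCounts(TP=90, TN=94, FP=25, FN=19))
        assert acc == pytest.approx(184 / 228)

    def test_zero_denominator_convention(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            se, sp, acc = compute_metrics(ConfusionCounts(TP=0, TN=10, FP=0, FN=0))
        assert se == 0.0
        assert sp == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ConfusionCounts(TP=-1, TN=0, FP=0, FN=0)

    def test_accuracy_identity_with_class_sizes(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            c = ConfusionCounts(*[int(v) for v in rng.integers(0, 40, size=4)])
            P, N = c.TP + c.FN, c.TN + c.FP
            if P == 0 or N == 0:
                continue
            se, sp, acc = compute_metrics(c)
            assert acc == pytest.approx((se * P + sp * N) / (P + N))


# ---------------------------------------------------------------------------
# tree


def exhaustive_best_gain_ratio(X, y, min_leaf=1):
    """Reference: evaluate every (feature, midpoint) split directly."""

    def entropy(labels):
        if labels.size == 0:
            return 0.0
        p = labels.mean()
        h = 0.0
        for q in (p, 1 - p):
            if q > 0:
                h -= q * np.log2(q)
        return h

    n = y.size
    parent = entropy(y)
    best = -np.inf
    for j in range(X.shape[1]):
        values = np.unique(X[:, j])
        for a, b in zip(values[:-1], values[1:]):
            thr = (a + b) / 2
            mask = X[:, j] <= thr
            nl, nr = int(mask.sum()), int((~mask).sum())
            if nl < min_leaf or nr < min_leaf:
                continue
            gain = parent - (nl * entropy(y[mask]) + nr * entropy(y[~mask])) / n
            si = -(nl / n) * np.log2(nl / n) - (nr / n) * np.log2(nr / n)
            best = max(best, max(gain, 0.0) / si)
    return best


class TestTree:
    def test_separable_1d_gives_depth_one_perfect_tree(self):
        x = np.array([1.0, 2, 3, 4, 10, 11, 12, 13])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        model = train_tree(make_matrix(x, y), min_leaf=1)
        assert model.depth == 1
        assert (model.predict(x[:, None]) == y).all()

    def test_single_class_data_gives_single_leaf(self):
        model = train_tree(make_matrix([1.0, 2.0, 3.0], [1, 1, 1]), min_leaf=1)
        assert model.root.is_leaf
        assert model.predict(np.array([[99.0]]))[0] == 1

    def test_xor_needs_depth_two(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0, 1, 1, 0])
        # brute force: no single split is informative on XOR (best gain 0)
        assert exhaustive_best_gain_ratio(X, y) == pytest.approx(0.0)
        model = train_tree(make_matrix(X, y), min_leaf=1)
        assert model.depth >= 2
        assert (model.predict(X) == y).all()

    def test_leaf_tie_breaks_to_negative_class(self):
        model = train_tree(make_matrix([1.0, 1.0], [0, 1]), min_leaf=1)
        assert model.predict(np.array([[1.0]]))[0] == 0

    def test_root_split_matches_exhaustive_search(self):
        rng = np.random.default_rng(77)
        checked = 0
        for _ in range(300):
            n, p = int(rng.integers(4, 13)), int(rng.integers(1, 4))
            X = np.round(rng.normal(size=(n, p)), 1)
            y = rng.integers(0, 2, size=n)
            want = exhaustive_best_gain_ratio(X, y)
            got = best_split(X, y, range(p), min_leaf=1)
            if want == -np.inf:
                assert got is None
            else:
                assert got is not None
                assert got[2] == pytest.approx(want, rel=1e-9)
                checked += 1
        assert checked > 100


class TestForest:
    def test_reduces_to_single_tree_without_randomness(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] + 0.2 * rng.normal(size=30) > 0).astype(int)
        m = make_matrix(X, y)
        forest = train_forest(m, n_trees=1, mtry=4, bootstrap=False, min_leaf=2)
        tree = train_tree(m, min_leaf=2)
        assert (forest.predict(X) == tree.predict(X)).all()

    def test_separable_data_has_perfect_oob_accuracy(self):
        x = np.concatenate([np.arange(20.0), np.arange(100.0, 120.0)])
        y = np.array([0] * 20 + [1] * 20)
        forest = train_forest(make_matrix(x, y), n_trees=25, seed=4)
        assert forest.oob_accuracy == pytest.approx(1.0)

    def test_same_seed_gives_identical_heldout_predictions(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 5))
        y = rng.integers(0, 2, size=40)
        m = make_matrix(X, y)
        held = rng.normal(size=(15, 5))
        f1 = train_forest(m, n_trees=20, seed=42)
        f2 = train_forest(m, n_trees=20, seed=42)
        assert (f1.predict(held) == f2.predict(held)).all()


# ---------------------------------------------------------------------------
# cross-validation


class TestCrossValidate:
    @staticmethod
    def _separable(n_per_class=20):
        x = np.concatenate([np.arange(float(n_per_class)),
                            np.arange(100.0, 100.0 + n_per_class)])
        y = np.array([0] * n_per_class + [1] * n_per_class)
        return make_matrix(x, y)

    def test_folds_partition_the_samples(self):
        y = np.array([0] * 13 + [1] * 17)
        folds = stratified_folds(y, k=5, seed=0)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx.tolist()) == list(range(30))

    def test_folds_are_stratified(self):
        y = np.array([0] * 50 + [1] * 50)
        for fold in stratified_folds(y, k=10, seed=1):
            assert y[fold].sum() == 5

    @pytest.mark.parametrize("k", [2, 5, 10])
    def test_separable_data_scores_perfectly(self, k):
        report = cross_validate(self._separable(), model="tree", k=k, seed=3)
        assert report.accuracy == pytest.approx(1.0)

    def test_pooled_counts_sum_to_sample_count(self):
        report = cross_validate(self._separable(), model="tree", k=4, seed=5)
        assert report.pooled.n == 40
        total = ConfusionCounts(0, 0, 0, 0)
        for c in report.folds:
            total = total + c
        assert total == report.pooled

    def test_class_smaller_than_k_rejected(self):
        m = make_matrix(np.arange(8.0), [0, 0, 0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="k <="):
            cross_validate(m, k=5, seed=0)

    def test_permuted_labels_give_chance_level_accuracy(self):
        """Label permutation destroys signal: accuracy near 0.5 on average."""
        rng = np.random.default_rng(13)
        x = np.concatenate([np.arange(30.0), np.arange(100.0, 130.0)])
        accs = []
        for _ in range(20):
            y_perm = rng.permutation([0] * 30 + [1] * 30)
            m = make_matrix(x, y_perm)
            accs.append(cross_validate(m, model="tree", k=10, seed=7).accuracy)
        assert 0.35 <= float(np.mean(accs)) <= 0.65

    def test_report_is_seed_reproducible(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, size=40)
        while min(y.sum(), 40 - y.sum()) < 5:
            y = rng.integers(0, 2, size=40)
        m = make_matrix(X, y)
        r1 = cross_validate(m, model="forest", k=5, seed=9, n_trees=10)
        r2 = cross_validate(m, model="forest", k=5, seed=9, n_trees=10)
        assert r1.pooled == r2.pooled
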