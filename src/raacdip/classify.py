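"""Gain-ratio decision trees, a bagged forest, and cross-validated metrics.

The tree is a C4.5-family learner: univariate binary splits on numeric
features, the split chosen to maximize gain ratio (information gain
divided by split information) over midpoint thresholds of the sorted
feature values; growth stops on node purity, the minimum-leaf-size
constraint, or an optional depth cap. Leaves predict the majority class,
with ties going to the negative class. No post-pruning is applied.

The forest bags such trees on bootstrap resamples, restricting each
split to a random subset of mtry features (default round(sqrt(p))), and
predicts by majority vote (ties → negative). All randomness flows from a
single integer seed.

Evaluation reports sensitivity SE = TP/(TP+FN), specificity
SP = TN/(TN+FP) and Accuracy = (TP+TN)/(TP+FN+TN+FP) from pooled
confusion counts over stratified k-fold cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .features import FeatureMatrix

# ---------------------------------------------------------------------------
# Confusion counts and metrics


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion table; positive = class 1."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.TN + other.TN,
            self.FP + other.FP,
            self.FN + other.FN,
        )


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def compute_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(SE, SP, Accuracy) from confusion counts; any 0/0 is defined as 0."""

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name}: zero denominator, defining value as 0")
            return 0.0
        return num / den

    se = _ratio(c.TP, c.TP + c.FN, "sensitivity")
    sp = _ratio(c.TN, c.TN + c.FP, "specificity")
    acc = _ratio(c.TP + c.TN, c.n, "accuracy")
    return se, sp, acc


# ---------------------------------------------------------------------------
# Gain-ratio decision tree


@dataclass
class TreeNode:
    n_neg: int
    n_pos: int
    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def prediction(self) -> int:
        # majority class; ties go to the negative class
        return 1 if self.n_pos > self.n_neg else 0

    @property
    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth, self.right.depth)

    @property
    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves + self.right.n_leaves


def _binary_entropy(pos: np.ndarray, n: np.ndarray) -> np.ndarray:
    p = pos / n
    q = 1.0 - p
    h = np.zeros_like(p, dtype=float)
    m = p > 0
    h[m] -= p[m] * np.log2(p[m])
    m = q > 0
    h[m] -= q[m] * np.log2(q[m])
    return h


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    feature_indices: Sequence[int],
    min_leaf: int = 1,
) -> Optional[tuple[int, float, float]]:
    """Best (feature, threshold, gain_ratio) over midpoint candidate splits.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values; both children must have size >= min_leaf. Zero-gain splits are
    admissible (so parity-structured data such as XOR is still separated
    by deeper levels); growth terminates anyway because every split
    strictly shrinks the node. Ties resolve to the earlier feature in
    ``feature_indices``, then the lower threshold. Returns None only if no
    candidate split exists.
    """
    n = y.size
    pos_total = int(y.sum())
    parent = _binary_entropy(np.array([pos_total], dtype=float), np.array([n], dtype=float))[0]
    best: Optional[tuple[int, float, float]] = None
    best_gr = -np.inf
    for j in feature_indices:
        x = X[:, j]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        ys = y[order]
        cut = np.nonzero(xs[:-1] < xs[1:])[0]
        if cut.size == 0:
            continue
        n_left = cut + 1
        ok = (n_left >= min_leaf) & (n - n_left >= min_leaf)
        cut, n_left = cut[ok], n_left[ok]
        if cut.size == 0:
            continue
        cum_pos = np.cumsum(ys)
        pos_left = cum_pos[cut].astype(float)
        n_right = (n - n_left).astype(float)
        pos_right = pos_total - pos_left
        h_left = _binary_entropy(pos_left, n_left.astype(float))
        h_right = _binary_entropy(pos_right, n_right)
        gain = parent - (n_left * h_left + n_right * h_right) / n
        fl = n_left / n
        fr = n_right / n
        split_info = -(fl * np.log2(fl) + fr * np.log2(fr))
        gr = np.maximum(gain, 0.0) / split_info  # split_info > 0 for any true split
        i = int(np.argmax(gr))  # first max -> lowest threshold within feature
        if gr[i] > best_gr + 1e-12:
            thr = float((xs[cut[i]] + xs[cut[i] + 1]) / 2.0)
            best_gr = float(gr[i])
            best = (int(j), thr, best_gr)
    return best


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    min_leaf: int,
    max_depth: Optional[int],
    depth: int,
    mtry: Optional[int],
    rng: Optional[np.random.Generator],
) -> TreeNode:
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    node = TreeNode(n_neg=n_neg, n_pos=n_pos)
    if n_pos == 0 or n_neg == 0:
        return node
    if max_depth is not None and depth >= max_depth:
        return node
    if y.size < 2 * min_leaf:
        return node
    p = X.shape[1]
    if mtry is not None and mtry < p:
        feats = np.sort(rng.choice(p, size=mtry, replace=False))
    else:
        feats = np.arange(p)
    split = best_split(X, y, feats, min_leaf=min_leaf)
    if split is None:
        return node
    j, thr, _ = split
    mask = X[:, j] <= thr
    node.feature = j
    node.threshold = thr
    node.left = _grow(X[mask], y[mask], min_leaf, max_depth, depth + 1, mtry, rng)
    node.right = _grow(X[~mask], y[~mask], min_leaf, max_depth, depth + 1, mtry, rng)
    return node


@dataclass
class TreeModel:
    """A trained gain-ratio decision tree over named features."""

    root: TreeNode
    feature_names: list[str]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0], dtype=int)
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.prediction
        return out

    @property
    def depth(self) -> int:
        return self.root.depth


def train_tree(
    matrix: FeatureMatrix,
    min_leaf: int = 2,
    max_depth: Optional[int] = None,
) -> TreeModel:
    """Fit a gain-ratio tree; single-class data yields a single-leaf tree."""
    if matrix.labels is None:
        raise ValueError("training requires a labeled matrix")
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    root = _grow(matrix.X, matrix.y, min_leaf, max_depth, 0, None, None)
    return TreeModel(root=root, feature_names=matrix.feature_names)


@dataclass
class ForestModel:
    """Bagged gain-ratio trees with per-split feature subsampling."""

    trees: list[TreeModel]
    feature_names: list[str]
    oob_accuracy: Optional[float] = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        votes = np.sum([t.predict(X) for t in self.trees], axis=0)
        # strict majority required for the positive class (ties -> negative)
        return (2 * votes > len(self.trees)).astype(int)


def train_forest(
    matrix: FeatureMatrix,
    n_trees: int = 100,
    mtry: Optional[int] = None,
    seed: int = 0,
    min_leaf: int = 1,
    max_depth: Optional[int] = None,
    bootstrap: bool = True,
) -> ForestModel:
    """Fit a random forest of gain-ratio trees, fully determined by ``seed``."""
    if matrix.labels is None:
        raise ValueError("training requires a labeled matrix")
    X, y = matrix.X, matrix.y
    n, p = X.shape
    if mtry is None:
        mtry = max(1, round(np.sqrt(p)))
    mtry = min(mtry, p)
    rng = np.random.default_rng(seed)
    trees: list[TreeModel] = []
    oob_votes = np.zeros(n, dtype=int)
    oob_counts = np.zeros(n, dtype=int)
    for _ in range(n_trees):
        if bootstrap:
            idx = rng.integers(0, n, size=n)
        else:
            idx = np.arange(n)
        root = _grow(X[idx], y[idx], min_leaf, max_depth, 0, mtry if mtry < p else None, rng)
        tree = TreeModel(root=root, feature_names=matrix.feature_names)
        trees.append(tree)
        if bootstrap:
            oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
            if oob.size:
                oob_votes[oob] += tree.predict(X[oob])
                oob_counts[oob] += 1
    oob_acc = None
    seen = oob_counts > 0
    if bootstrap and seen.any():
        oob_pred = (2 * oob_votes[seen] > oob_counts[seen]).astype(int)
        oob_acc = float(np.mean(oob_pred == y[seen]))
    return ForestModel(trees=trees, feature_names=matrix.feature_names, oob_accuracy=oob_acc)


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVReport:
    """Per-fold and pooled confusion counts with SE/SP/Accuracy."""

    folds: list[ConfusionCounts]
    pooled: ConfusionCounts
    se: float
    sp: float
    accuracy: float
    k: int
    seed: int


def stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Partition sample indices into k folds, stratified by class.

    Within each class the indices are shuffled with the seeded generator
    and split into k near-equal chunks; chunk-to-fold assignment is
    rotated per class so fold sizes balance. Every sample lands in
    exactly one fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for offset, cls in enumerate(np.unique(y)):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValueError(
                f"class {cls} has only {idx.size} samples; use k <= {idx.size}"
            )
        idx = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(idx, k)):
            folds[(f + offset) % k].extend(chunk.tolist())
    return [np.array(sorted(f), dtype=int) for f in folds]


def _make_trainer(
    model: str, seed: int, **params
) -> Callable[[FeatureMatrix, int], object]:
    if model == "tree":
        return lambda m, fold_seed: train_tree(m, **params)
    if model == "forest":
        return lambda m, fold_seed: train_forest(m, seed=fold_seed, **params)
    raise ValueError(f"unknown model {model!r}; choose 'tree' or 'forest'")


def cross_validate(
    matrix: FeatureMatrix,
    model: str = "tree",
    k: int = 10,
    seed: int = 0,
    **params,
) -> CVReport:
    """Stratified k-fold cross-validation of a tree or forest.

    Fold assignment and any forest bootstraps are fully determined by
    ``seed``; each sample is predicted exactly once.
    """
    if matrix.labels is None:
        raise ValueError("cross-validation requires a labeled matrix")
    y = matrix.y
    folds = stratified_folds(y, k, seed)
    fold_seed_rng = np.random.default_rng(seed + 1)
    fold_seeds = fold_seed_rng.integers(0, 2**31 - 1, size=k)
    trainer = _make_trainer(model, seed, **params)
    data = matrix.data
    counts: list[ConfusionCounts] = []
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(matrix.n_samples, dtype=bool)
        train_mask[test_idx] = False
        train = FeatureMatrix(data.iloc[train_mask], matrix.labels.iloc[train_mask])
        fitted = trainer(train, int(fold_seeds[f]))
        pred = fitted.predict(data.iloc[test_idx].to_numpy(dtype=float))
        counts.append(confusion_from_predictions(y[test_idx], pred))
    pooled = counts[0]
    for c in counts[1:]:
        pooled = pooled + c
    se, sp, acc = compute_metrics(pooled)
    return CVReport(folds=counts, pooled=pooled, se=se, sp=sp, accuracy=acc, k=k, seed=seed)


def cv_accuracy_evaluator(
    model: str = "tree", k: int = 10, seed: int = 0, **params
) -> Callable[[FeatureMatrix], float]:
    """A reusable matrix -> CV-accuracy callback for feature selection."""

    def _eval(matrix: FeatureMatrix) -> float:
        return cross_validate(matrix, model=model, k=k, seed=seed, **params).accuracy

    return _eval
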