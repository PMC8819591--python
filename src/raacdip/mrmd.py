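"""Max-Relevance-Max-Distance (MRMD) feature ranking and subset selection.

Each feature receives two scores: relevance, the absolute Pearson
correlation between the feature column and the binary class vector, and
distance, the mean distance between the (standardized) feature column and
every other feature column — features far from the rest carry less
redundant information. The combined score is

    score_i = w_r · relevance_i + w_d · distance_i / max_j distance_j

with the distance term normalized to [0, 1] so the two terms are
commensurable regardless of sample count. Features are ranked by
descending score; ties break by original column index.

Subset selection evaluates nested prefixes of the ranking (top-1,
top-2, …) with a caller-supplied cross-validation accuracy callback and
returns the smallest prefix whose accuracy is within a tolerance of the
best prefix accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix

METRICS = ("euclidean", "cosine", "tanimoto")


def relevance(column: np.ndarray, labels: np.ndarray) -> float:
    """|Pearson correlation| between a feature column and 0/1 labels.

    Zero-variance columns (or labels) return 0 by convention.
    """
    column = np.asarray(column, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if column.shape != labels.shape:
        raise ValueError("column and labels must have the same length")
    if column.size < 2:
        raise ValueError("need at least 2 samples")
    cd = column - column.mean()
    ld = labels - labels.mean()
    denom = np.sqrt((cd @ cd) * (ld @ ld))
    if denom == 0:
        return 0.0
    return float(abs(cd @ ld) / denom)


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    std = np.where(std == 0, 1.0, std)
    return (X - mean) / std


def _pairwise_distances(Z: np.ndarray, metric: str) -> np.ndarray:
    """Distance matrix between the columns of Z."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    G = Z.T @ Z  # p x p Gram matrix of columns
    sq = np.diag(G)
    if metric == "euclidean":
        d2 = sq[:, None] + sq[None, :] - 2 * G
        return np.sqrt(np.maximum(d2, 0.0))
    if metric == "cosine":
        norms = np.sqrt(sq)
        denom = norms[:, None] * norms[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            sim = np.where(denom > 0, G / np.where(denom > 0, denom, 1.0), 0.0)
        return 1.0 - sim
    # generalized Tanimoto on continuous vectors: x·y / (|x|² + |y|² − x·y)
    denom = sq[:, None] + sq[None, :] - G
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(denom > 0, G / np.where(denom > 0, denom, 1.0), 0.0)
    return 1.0 - sim


def distance(index: int, matrix: FeatureMatrix, metric: str = "euclidean") -> float:
    """Mean distance from feature ``index`` to every other standardized column.

    A single-feature matrix gives 0 by convention.
    """
    p = matrix.n_features
    if p < 2:
        return 0.0
    Z = _standardize_columns(matrix.X)
    D = _pairwise_distances(Z, metric)
    return float((D[index].sum() - D[index, index]) / (p - 1))


@dataclass
class MRMDRanking:
    """Per-feature relevance/distance/score table plus the rank order."""

    table: pd.DataFrame  # columns: feature, relevance, distance, score, rank
    metric: str
    weights: tuple[float, float]

    @property
    def ordered_features(self) -> list[str]:
        return self.table.sort_values("rank")["feature"].tolist()

    def score_of(self, feature: str) -> float:
        row = self.table.loc[self.table["feature"] == feature, "score"]
        if row.empty:
            raise KeyError(feature)
        return float(row.iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def mrmd_rank(
    matrix: FeatureMatrix,
    weights: tuple[float, float] = (1.0, 1.0),
    metric: str = "euclidean",
) -> MRMDRanking:
    """Rank all features by combined relevance + normalized-distance score."""
    if matrix.labels is None:
        raise ValueError("MRMD ranking requires a labeled matrix")
    w_r, w_d = weights
    X = matrix.X
    y = matrix.y
    p = matrix.n_features
    rel = np.array([relevance(X[:, j], y) for j in range(p)])
    if p >= 2:
        Z = _standardize_columns(X)
        D = _pairwise_distances(Z, metric)
        dist = (D.sum(axis=1) - np.diag(D)) / (p - 1)
    else:
        dist = np.zeros(p)
    dmax = dist.max()
    dist_norm = dist / dmax if dmax > 0 else dist
    score = w_r * rel + w_d * dist_norm
    # descending score, ties by original column index (stable sort)
    order = np.argsort(-score, kind="stable")
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    table = pd.DataFrame(
        {
            "feature": matrix.feature_names,
            "relevance": rel,
            "distance": dist,
            "score": score,
            "rank": rank,
        }
    )
    return MRMDRanking(table=table, metric=metric, weights=(w_r, w_d))


@dataclass
class SelectionResult:
    """Outcome of prefix subset selection along an MRMD ranking."""

    features: list[str]
    trajectory: pd.DataFrame  # columns: k, accuracy
    best_accuracy: float
    accuracy: float


def select_subset(
    matrix: FeatureMatrix,
    ranking: MRMDRanking,
    evaluator: Callable[[FeatureMatrix], float],
    k_max: int,
    tolerance: float = 0.005,
) -> SelectionResult:
    """Pick the smallest ranking prefix within ``tolerance`` of the best.

    Evaluates top-1 … top-k_max prefixes with ``evaluator`` (a
    cross-validated accuracy callback) and returns the shortest prefix
    whose accuracy is >= best − tolerance, along with the full accuracy
    trajectory. With tolerance 0 this is the argmax prefix (smallest on
    ties).
    """
    if k_max < 1 or k_max > matrix.n_features:
        raise ValueError("k_max must be in [1, n_features]")
    ordered = ranking.ordered_features
    accs: list[float] = []
    for k in range(1, k_max + 1):
        accs.append(float(evaluator(matrix.subset(ordered[:k]))))
    best = max(accs)
    chosen_k = next(k for k, a in enumerate(accs, start=1) if a >= best - tolerance)
    trajectory = pd.DataFrame({"k": np.arange(1, k_max + 1), "accuracy": accs})
    return SelectionResult(
        features=ordered[:chosen_k],
        trajectory=trajectory,
        best_accuracy=best,
        accuracy=accs[chosen_k - 1],
    )
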