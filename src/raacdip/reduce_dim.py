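"""Greedy single-feature elimination down to a minimal discriminative set.

Starting from a candidate subset (typically the MRMD-selected features),
backward elimination repeatedly removes the one feature whose removal
maximizes cross-validated accuracy. Removal stops when the best
achievable accuracy after removal would fall more than ``tolerance``
below the best accuracy seen so far, or when ``min_features`` is
reached. Ties between equally good removals break toward the feature
with the lower MRMD score (when scores are supplied), then toward the
later column. A forward variant is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import pandas as pd

from .features import FeatureMatrix

Evaluator = Callable[[FeatureMatrix], float]


@dataclass
class EliminationResult:
    """Final subset plus the full step-by-step trajectory."""

    features: list[str]
    accuracy: float
    trajectory: pd.DataFrame  # columns: step, removed_feature, n_features, accuracy


def backward_eliminate(
    matrix: FeatureMatrix,
    evaluator: Evaluator,
    min_features: int = 2,
    tolerance: float = 0.0,
    scores: Optional[Mapping[str, float]] = None,
) -> EliminationResult:
    """Greedily drop features while accuracy stays within ``tolerance``.

    With ``tolerance=float('inf')`` the elimination runs all the way down
    to ``min_features``.
    """
    if matrix.labels is None:
        raise ValueError("elimination requires a labeled matrix")
    if min_features < 1:
        raise ValueError("min_features must be >= 1")
    current = list(matrix.feature_names)
    if min_features > len(current):
        raise ValueError("min_features exceeds the number of features")

    acc = float(evaluator(matrix))
    best_seen = acc
    rows = [{"step": 0, "removed_feature": "", "n_features": len(current), "accuracy": acc}]
    step = 0
    while len(current) > min_features:
        candidates: list[tuple[float, float, int, str]] = []
        for pos, feat in enumerate(current):
            rest = [f for f in current if f != feat]
            a = float(evaluator(matrix.subset(rest)))
            score = scores.get(feat, 0.0) if scores is not None else 0.0
            candidates.append((a, score, pos, feat))
        # highest accuracy; ties -> lowest MRMD score, then latest column
        best_acc = max(a for a, _, _, _ in candidates)
        tied = [c for c in candidates if c[0] == best_acc]
        _, _, _, removed = min(tied, key=lambda c: (c[1], -c[2]))
        if best_acc < best_seen - tolerance:
            break
        current = [f for f in current if f != removed]
        acc = best_acc
        best_seen = max(best_seen, best_acc)
        step += 1
        rows.append(
            {
                "step": step,
                "removed_feature": removed,
                "n_features": len(current),
                "accuracy": best_acc,
            }
        )
    return EliminationResult(
        features=current, accuracy=acc, trajectory=pd.DataFrame(rows)
    )


def forward_select(
    matrix: FeatureMatrix,
    evaluator: Evaluator,
    max_features: int = 2,
    tolerance: float = 0.0,
) -> EliminationResult:
    """Greedy forward counterpart: add the feature that helps most.

    Stops when no addition improves accuracy by more than ``tolerance``
    or ``max_features`` is reached.
    """
    if matrix.labels is None:
        raise ValueError("selection requires a labeled matrix")
    remaining = list(matrix.feature_names)
    current: list[str] = []
    acc = 0.0
    rows: list[dict] = []
    step = 0
    while remaining and len(current) < max_features:
        candidates = []
        for pos, feat in enumerate(remaining):
            a = float(evaluator(matrix.subset(current + [feat])))
            candidates.append((a, pos, feat))
        best_acc = max(a for a, _, _ in candidates)
        if current and best_acc <= acc + tolerance:
            break
        _, _, added = min((c for c in candidates if c[0] == best_acc), key=lambda c: c[1])
        current.append(added)
        remaining.remove(added)
        acc = best_acc
        step += 1
        rows.append(
            {"step": step, "removed_feature": f"+{added}", "n_features": len(current), "accuracy": acc}
        )
    return EliminationResult(features=current, accuracy=acc, trajectory=pd.DataFrame(rows))
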