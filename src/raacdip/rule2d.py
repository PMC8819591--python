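"""Two-feature interpretability: scatter tables and axis-aligned rules.

Working on raw integer gapped-dipeptide counts of two chosen features
(e.g. F-gap-C and G-gap-C at λ=1), this module exports per-sample
scatter tables, fits the best axis-aligned two-threshold rule by
exhaustive search, and summarizes per-class count distributions. The
rule formalizes the visual reading of a 2D scatter: one class occupies
one corner of the count plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import ConfusionCounts, confusion_from_predictions
from .features import (
    GappedDipeptideSpec,
    gapped_dipeptide_counts,
    parse_feature_name,
)
from .io_seq import ProteinRecord
from .raac import ReductionScheme, reduce_sequence

_LABEL_CODE = {"negative": 0, "positive": 1}


def scatter_table(
    records: Sequence[ProteinRecord],
    scheme: ReductionScheme,
    feat_x: str | GappedDipeptideSpec,
    feat_y: str | GappedDipeptideSpec,
) -> pd.DataFrame:
    """Per-sample raw counts of two gapped-dipeptide features.

    Returns a DataFrame with columns (id, x, y, label) in input order;
    label is empty for unlabeled records.
    """
    fx = parse_feature_name(feat_x) if isinstance(feat_x, str) else feat_x
    fy = parse_feature_name(feat_y) if isinstance(feat_y, str) else feat_y
    alphabet = scheme.representatives
    for f in (fx, fy):
        if f.first not in alphabet or f.second not in alphabet:
            raise ValueError(f"feature {f.name!r} uses letters outside the reduced alphabet")
    rows = []
    for rec in records:
        reduced = reduce_sequence(rec.sequence, scheme)
        cx = gapped_dipeptide_counts(reduced, fx.gap, alphabet)[fx.name]
        cy = gapped_dipeptide_counts(reduced, fy.gap, alphabet)[fy.name]
        rows.append({"id": rec.id, "x": cx, "y": cy, "label": rec.label or ""})
    return pd.DataFrame(rows, columns=["id", "x", "y", "label"])


@dataclass(frozen=True)
class ThresholdRule:
    """Axis-aligned rule on two integer count features.

    The two thresholds split the count plane into four quadrants; each
    quadrant carries its own class. A quadrant key is
    (x > x_threshold, y > y_threshold); ``quadrant_classes`` maps each
    of the four keys to 0 (negative) or 1 (positive). This family is
    closed under class complement, so a class-swapped training table
    yields the same thresholds with inverted quadrant labels.
    """

    feature_x: str
    feature_y: str
    x_threshold: int
    y_threshold: int
    quadrant_classes: tuple[tuple[tuple[bool, bool], int], ...]

    def _lookup(self) -> dict[tuple[bool, bool], int]:
        return dict(self.quadrant_classes)

    def predict(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        lut = self._lookup()
        hx = x > self.x_threshold
        hy = y > self.y_threshold
        return np.array([lut[(bool(a), bool(b))] for a, b in zip(hx, hy)], dtype=int)

    def describe(self) -> str:
        lut = self._lookup()
        parts = []
        for (hx, hy), cls in sorted(lut.items(), reverse=True):
            cond_x = f"{self.feature_x} {'>' if hx else '<='} {self.x_threshold}"
            cond_y = f"{self.feature_y} {'>' if hy else '<='} {self.y_threshold}"
            name = "positive" if cls == 1 else "negative"
            parts.append(f"{cond_x} and {cond_y} -> {name}")
        return "; ".join(parts)


def _coded_labels(table: pd.DataFrame) -> np.ndarray:
    labels = table["label"].astype(str)
    if not set(labels.unique()) <= set(_LABEL_CODE):
        raise ValueError("table must be labeled with 'positive'/'negative'")
    return labels.map(_LABEL_CODE).to_numpy(dtype=int)


def fit_rule(
    table: pd.DataFrame,
    feature_x: str = "F*C",
    feature_y: str = "G*C",
) -> tuple[ThresholdRule, ConfusionCounts]:
    """Exhaustive search for the accuracy-maximizing two-threshold rule.

    Thresholds range over the observed integer counts of each axis plus a
    sentinel below the minimum (so pure single-axis rules are reachable);
    for each threshold pair every quadrant takes its training-majority
    class, which is optimal for that pair. Threshold ties prefer smaller
    values; a quadrant with no majority (tied or empty) is labeled
    positive on the high-x side and negative otherwise, matching the
    reading that the positive class lives at high x.
    """
    y_true = _coded_labels(table)
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present to fit a rule")
    xv = table["x"].to_numpy(dtype=int)
    yv = table["y"].to_numpy(dtype=int)
    tx_cands = np.unique(np.concatenate([[xv.min() - 1], np.unique(xv)]))
    ty_cands = np.unique(np.concatenate([[yv.min() - 1], np.unique(yv)]))
    n = y_true.size
    best: tuple[int, ThresholdRule] | None = None
    for tx in tx_cands:
        hx = xv > tx
        for ty in ty_cands:
            hy = yv > ty
            labels = []
            correct = 0
            for qx in (False, True):
                for qy in (False, True):
                    mask = (hx == qx) & (hy == qy)
                    n_pos = int(y_true[mask].sum())
                    n_neg = int(mask.sum()) - n_pos
                    if n_pos > n_neg:
                        cls = 1
                    elif n_neg > n_pos:
                        cls = 0
                    else:  # tied or empty quadrant
                        cls = 1 if qx else 0
                    labels.append(((qx, qy), cls))
                    correct += n_pos if cls == 1 else n_neg
            if best is None or correct > best[0]:
                best = (
                    correct,
                    ThresholdRule(
                        feature_x=feature_x,
                        feature_y=feature_y,
                        x_threshold=int(tx),
                        y_threshold=int(ty),
                        quadrant_classes=tuple(labels),
                    ),
                )
    rule = best[1]
    counts = confusion_from_predictions(y_true, rule.predict(xv, yv))
    return rule, counts


def class_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Per-class, per-feature order statistics of the count distributions.

    Returns rows (label, feature, n, n_zero, min, q25, median, q75, max).
    An absent class simply contributes no rows.
    """
    rows = []
    for label, sub in table.groupby("label", sort=True):
        if label == "":
            continue
        for feat, col in (("x", sub["x"]), ("y", sub["y"])):
            v = col.to_numpy(dtype=float)
            rows.append(
                {
                    "label": label,
                    "feature": feat,
                    "n": v.size,
                    "n_zero": int(np.sum(v == 0)),
                    "min": float(v.min()),
                    "q25": float(np.percentile(v, 25)),
                    "median": float(np.percentile(v, 50)),
                    "q75": float(np.percentile(v, 75)),
                    "max": float(v.max()),
                }
            )
    return pd.DataFrame(
        rows, columns=["label", "feature", "n", "n_zero", "min", "q25", "median", "q75", "max"]
    )
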