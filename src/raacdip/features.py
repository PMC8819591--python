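"""Sequence descriptors: λ-gap dipeptide composition and auto-cross covariance.

A λ-gap dipeptide is an ordered residue pair separated by exactly λ
intervening residues; λ=0 is the ordinary dipeptide. On a reduced
alphabet of k letters there are k² such features per gap. The frequency
of dipeptide type u at gap λ is

    f_u = n_u / Σ_u n_u

where n_u counts occurrences of u over the whole sequence at that gap.
A sequence of length L contributes L−λ−1 dipeptides (0 if L ≤ λ+1, in
which case all frequencies are defined as 0).

Auto-cross covariance (ACC) descriptors turn variable-length sequences
into fixed-length vectors from lagged covariances of per-residue
physicochemical property profiles: the auto covariance AC(j, g) of
property j at lag g, and the cross covariance CC(j, k, g) between
ordered distinct properties j and k. ACC is computed on the original
(unreduced) sequence, since the properties are defined per standard
residue.

Canonical gapped-dipeptide names put the λ asterisks between the
letters ("F*C" for F…C at λ=1); the trailing-star style "FC*" is
accepted as an input alias.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_seq import POSITIVE, STANDARD_AA, ProteinRecord
from .raac import ReductionScheme, default_scheme, reduce_sequence

# ---------------------------------------------------------------------------
# Gapped-dipeptide feature names


@dataclass(frozen=True)
class GappedDipeptideSpec:
    """An ordered letter pair with a gap: ``first`` …(gap residues)… ``second``."""

    first: str
    second: str
    gap: int

    def __post_init__(self) -> None:
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if len(self.first) != 1 or len(self.second) != 1:
            raise ValueError("dipeptide letters must be single characters")

    @property
    def name(self) -> str:
        return f"{self.first}{'*' * self.gap}{self.second}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def parse_feature_name(name: str) -> GappedDipeptideSpec:
    """Parse a gapped-dipeptide name, accepting trailing-star aliases.

    Canonical: stars between the letters, one per gap residue ("G*C").
    Alias: stars after both letters ("GC*" ≡ "G*C", "GC**" ≡ "G**C").
    """
    s = name.strip()
    letters = [c for c in s if c != "*"]
    if len(letters) != 2 or not all(c.isalpha() for c in letters):
        raise ValueError(f"invalid gapped-dipeptide name {name!r}")
    first, second = letters[0].upper(), letters[1].upper()
    stars = s.count("*")
    canonical = f"{first}{'*' * stars}{second}"
    alias = f"{first}{second}{'*' * stars}"
    if s.upper() not in (canonical, alias):
        raise ValueError(f"invalid gapped-dipeptide name {name!r}")
    return GappedDipeptideSpec(first=first, second=second, gap=stars)


# ---------------------------------------------------------------------------
# Gapped-dipeptide counting


def gapped_dipeptide_counts(
    reduced_seq: str, gap: int, alphabet: Sequence[str]
) -> dict[str, int]:
    """Count every λ-gap dipeptide over ``alphabet``² in one sequence.

    The count of pair (a, b) is the number of positions i with
    seq[i] == a and seq[i + gap + 1] == b; the counts sum to
    max(0, L − gap − 1). Sequences shorter than gap + 2 give all zeros.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    k = len(alphabet)
    index = {ch: i for i, ch in enumerate(alphabet)}
    mat = np.zeros((k, k), dtype=np.int64)
    n = len(reduced_seq) - gap - 1
    if n > 0:
        codes = np.fromiter((index[c] for c in reduced_seq), dtype=np.int64)
        np.add.at(mat, (codes[:n], codes[gap + 1 :]), 1)
    return {
        GappedDipeptideSpec(a, b, gap).name: int(mat[i, j])
        for i, a in enumerate(alphabet)
        for j, b in enumerate(alphabet)
    }


def gapped_dipeptide_frequencies(
    reduced_seq: str, gap: int, alphabet: Sequence[str]
) -> dict[str, float]:
    """Normalized λ-gap dipeptide composition; all zeros for degenerate lengths."""
    counts = gapped_dipeptide_counts(reduced_seq, gap, alphabet)
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: v / total for k, v in counts.items()}


# ---------------------------------------------------------------------------
# Physicochemical property profiles and ACC

# Kyte–Doolittle hydrophobicity
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
# Hopp–Woods hydrophilicity
_HW = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2, "E": 3.0,
    "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5,
    "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}
# Side-chain mass (Da)
_MASS = {
    "A": 15.0, "R": 101.0, "N": 58.0, "D": 59.0, "C": 47.0, "Q": 72.0,
    "E": 73.0, "G": 1.0, "H": 82.0, "I": 57.0, "L": 57.0, "K": 73.0,
    "M": 75.0, "F": 91.0, "P": 42.0, "S": 31.0, "T": 45.0, "W": 130.0,
    "Y": 107.0, "V": 43.0,
}


def default_property_table() -> pd.DataFrame:
    """Hydrophobicity / hydrophilicity / side-chain mass, standardized.

    Each column is shifted and scaled to mean 0, variance 1 over the
    20 standard residues so the three scales are commensurable.
    """
    raw = pd.DataFrame(
        {"hydrophobicity": _KD, "hydrophilicity": _HW, "mass": _MASS},
        index=list(STANDARD_AA),
    ).loc[list(STANDARD_AA)]
    return standardize_property_table(raw)


def standardize_property_table(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize each property column to mean 0, variance 1 (ddof=0)."""
    _validate_property_table(table)
    mean = table.mean(axis=0)
    std = table.std(axis=0, ddof=0)
    if (std == 0).any():
        bad = list(table.columns[std == 0])
        raise ValueError(f"constant property column(s): {bad}")
    return (table - mean) / std


def read_property_table(path: str | Path, standardize: bool = True) -> pd.DataFrame:
    """Read a property TSV (rows = amino acids, columns = named properties)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    table = table.loc[list(STANDARD_AA)]
    return standardize_property_table(table) if standardize else table


def _validate_property_table(table: pd.DataFrame) -> None:
    if sorted(table.index) != sorted(STANDARD_AA):
        raise ValueError("property table must have exactly the 20 standard residues as rows")


def acc_features(
    seq: str, props: pd.DataFrame, maxlag: int = 2
) -> dict[str, float]:
    """Auto and cross covariance descriptors of a property-profile matrix.

    For property j with per-residue profile P_j and sequence mean P̄_j:

        AC(j, g)    = (1/(L−g)) Σ_{i=1}^{L−g} (P_j(i)−P̄_j)(P_j(i+g)−P̄_j)
        CC(j, k, g) = (1/(L−g)) Σ_{i=1}^{L−g} (P_j(i)−P̄_j)(P_k(i+g)−P̄_k)

    for lags g = 1..maxlag and ordered pairs j ≠ k, giving
    p·maxlag + p·(p−1)·maxlag values (18 for p=3, maxlag=2).

    Raises if the sequence is not longer than ``maxlag``.
    """
    if maxlag < 1:
        raise ValueError("maxlag must be >= 1")
    L = len(seq)
    if L <= maxlag:
        raise ValueError(f"sequence length {L} must exceed maxlag {maxlag}")
    profile = props.loc[list(seq)].to_numpy(dtype=float)  # L x p
    dev = profile - profile.mean(axis=0)
    names = list(props.columns)
    out: dict[str, float] = {}
    for j, pj in enumerate(names):
        for g in range(1, maxlag + 1):
            out[f"AC.{pj}.lag{g}"] = float(dev[:-g, j] @ dev[g:, j] / (L - g))
    for j, pj in enumerate(names):
        for k, pk in enumerate(names):
            if j == k:
                continue
            for g in range(1, maxlag + 1):
                out[f"CC.{pj}.{pk}.lag{g}"] = float(dev[:-g, j] @ dev[g:, k] / (L - g))
    return out


# ---------------------------------------------------------------------------
# Feature matrix

LABEL_CODE = {"negative": 0, "positive": 1}


@dataclass
class FeatureMatrix:
    """Samples × named features with optional binary labels.

    ``data`` is indexed by sample id with unique feature-name columns;
    ``labels`` (if present) is aligned to the index and coded
    {0: negative, 1: positive}.
    """

    data: pd.DataFrame
    labels: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dup}")
        if self.data.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.labels is not None:
            self.labels = pd.Series(self.labels, index=self.data.index).astype(int)
            if not set(self.labels.unique()) <= {0, 1}:
                raise ValueError("labels must be coded 0/1")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("feature matrix has no labels")
        return self.labels.to_numpy(dtype=int)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset(self, features: Sequence[str]) -> "FeatureMatrix":
        missing = [f for f in features if f not in self.data.columns]
        if missing:
            raise KeyError(f"unknown feature(s): {missing}")
        return FeatureMatrix(self.data.loc[:, list(features)], self.labels)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "label", self.labels if self.labels is not None else "")
        out.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id")
        labels = None
        if "label" in df.columns:
            col = df.pop("label")
            if col.notna().all() and (col.astype(str) != "").all():
                labels = col.astype(int)
        return cls(df, labels)


def dipeptide_feature_names(alphabet: Sequence[str], gaps: Sequence[int]) -> list[str]:
    """Deterministic column order: per gap, alphabet² in row-major order."""
    return [
        GappedDipeptideSpec(a, b, g).name
        for g in gaps
        for a in alphabet
        for b in alphabet
    ]


def extract_feature_matrix(
    records: Sequence[ProteinRecord],
    scheme: Optional[ReductionScheme] = None,
    gaps: Sequence[int] = (0, 1, 2),
    props: Optional[pd.DataFrame] = None,
    maxlag: int = 2,
    values: str = "frequency",
    include_acc: bool = True,
) -> FeatureMatrix:
    """Assemble the full descriptor matrix for a set of records.

    Columns are, in order: all gapped-dipeptide features for each λ in
    ``gaps`` (alphabet² row-major within each gap), then AC features
    (property-major, lag-minor), then CC features. With the default
    5-letter scheme, gaps (0, 1, 2) and the 3-property table at maxlag 2
    this yields 75 dipeptide columns + 18 ACC columns = 93 features.

    ``values`` selects "frequency" (normalized composition) or "count"
    (raw integer counts) for the dipeptide block.
    """
    if not records:
        raise ValueError("no records")
    if values not in ("frequency", "count"):
        raise ValueError("values must be 'frequency' or 'count'")
    scheme = scheme if scheme is not None else default_scheme()
    alphabet = scheme.representatives
    if include_acc and props is None:
        props = default_property_table()

    fn = gapped_dipeptide_frequencies if values == "frequency" else gapped_dipeptide_counts
    rows: list[dict[str, float]] = []
    for rec in records:
        reduced = reduce_sequence(rec.sequence, scheme)
        row: dict[str, float] = {}
        for g in gaps:
            row.update(fn(reduced, g, alphabet))
        if include_acc:
            row.update(acc_features(rec.sequence, props, maxlag))
        rows.append(row)

    columns = dipeptide_feature_names(alphabet, gaps)
    if include_acc:
        columns += _acc_feature_names(list(props.columns), maxlag)
    data = pd.DataFrame(rows, index=[r.id for r in records])[columns]

    labels = None
    if all(r.label is not None for r in records):
        labels = pd.Series(
            [LABEL_CODE[r.label] for r in records], index=data.index
        )
    return FeatureMatrix(data, labels)


def _acc_feature_names(prop_names: Sequence[str], maxlag: int) -> list[str]:
    names = [f"AC.{p}.lag{g}" for p in prop_names for g in range(1, maxlag + 1)]
    names += [
        f"CC.{p}.{q}.lag{g}"
        for p in prop_names
        for q in prop_names
        if p != q
        for g in range(1, maxlag + 1)
    ]
    return names
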