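"""Exact and Hamming-tolerant motif scanning, and motif-to-feature attribution.

Motif discovery itself (PWM/EM methods) is out of scope; a motif is a
known amino-acid string. Scanning slides the motif along each sequence
and counts windows whose Hamming distance is at most ``max_mismatches``
(overlapping windows all count). Attribution answers the
interpretability question "how much of a reduced gapped-dipeptide
feature does this motif itself contribute?" by reducing the motif and
counting the feature inside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .features import GappedDipeptideSpec, gapped_dipeptide_counts, parse_feature_name
from .io_seq import ProteinRecord
from .raac import ReductionScheme, reduce_sequence


@dataclass
class MotifScanResult:
    """Per-record occurrence table plus the number of records hit."""

    table: pd.DataFrame  # columns: id, occurrences, best_position
    records_hit: int
    motif: str
    max_mismatches: int


def _scan_one(seq: str, motif: np.ndarray, max_mismatches: int) -> tuple[int, int]:
    """(occurrence count, best position) for one sequence; best = -1 if none.

    The best position is the window with the fewest mismatches, earliest
    on ties.
    """
    m = motif.size
    s = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if s.size < m:
        return 0, -1
    n_win = s.size - m + 1
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    mism = np.count_nonzero(windows != motif, axis=1)
    hits = mism <= max_mismatches
    count = int(hits.sum())
    best = int(np.argmin(mism)) if count else -1
    return count, best


def scan_motif(
    records: Sequence[ProteinRecord],
    motif: str,
    max_mismatches: int = 0,
) -> MotifScanResult:
    """Count motif occurrences per record with a mismatch budget.

    A motif longer than the sequence yields 0 occurrences (not an error).
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    mvec = np.frombuffer(motif.upper().encode("ascii"), dtype=np.uint8)
    rows = []
    hit = 0
    for rec in records:
        count, best = _scan_one(rec.sequence, mvec, max_mismatches)
        hit += count > 0
        rows.append({"id": rec.id, "occurrences": count, "best_position": best})
    table = pd.DataFrame(rows, columns=["id", "occurrences", "best_position"])
    return MotifScanResult(
        table=table, records_hit=hit, motif=motif.upper(), max_mismatches=max_mismatches
    )


def motif_feature_contribution(
    motif: str,
    scheme: ReductionScheme,
    feature: str | GappedDipeptideSpec,
) -> int:
    """Gapped-dipeptide count of ``feature`` within the reduced motif.

    This is the quantitative link between a conserved motif and a
    discriminative reduced-alphabet feature: every inserted copy of the
    motif adds at least this many counts to a sequence's feature value.
    Motifs shorter than gap + 2 contribute 0.
    """
    spec = parse_feature_name(feature) if isinstance(feature, str) else feature
    reduced = reduce_sequence(motif.upper(), scheme)
    counts = gapped_dipeptide_counts(reduced, spec.gap, scheme.representatives)
    return counts[spec.name]
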