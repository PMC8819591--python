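"""FASTA input/output and sequence canonicalization.

Every downstream descriptor is defined over the 20 standard one-letter
amino acid codes, so sequences are canonicalized on input: uppercased,
alignment gaps and terminal stops stripped, ambiguity codes resolved to
their nearest standard residue, and anything unresolvable dropped with a
warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

POSITIVE = "positive"
NEGATIVE = "negative"

# Ambiguity / rare codes mapped to the chemically closest standard residue.
_AMBIGUITY = {"B": "D", "Z": "E", "U": "C", "J": "L", "O": "K"}
_GAP_CHARS = set("-.")


@dataclass
class ProteinRecord:
    """A named protein sequence with an optional binary class label."""

    id: str
    sequence: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label not in (None, POSITIVE, NEGATIVE):
            raise ValueError(
                f"label must be {POSITIVE!r}, {NEGATIVE!r} or None, got {self.label!r}"
            )


def canonicalize(seq: str, record_id: str = "?") -> str:
    """Uppercase, strip gaps and a terminal '*', resolve ambiguity codes.

    Residues that cannot be mapped onto the 20-letter alphabet (X and any
    other character) are removed with a logged warning.
    """
    s = seq.upper()
    if s.endswith("*"):
        s = s[:-1]
    out = []
    dropped: list[str] = []
    for ch in s:
        if ch in _GAP_CHARS:
            continue
        ch = _AMBIGUITY.get(ch, ch)
        if ch in STANDARD_AA:
            out.append(ch)
        else:
            dropped.append(ch)
    if dropped:
        logger.warning(
            "record %s: dropped %d non-standard residue(s): %s",
            record_id,
            len(dropped),
            "".join(sorted(set(dropped))),
        )
    return "".join(out)


def read_fasta(path: str | Path, label: Optional[str] = None) -> list[ProteinRecord]:
    """Read a FASTA file into canonicalized :class:`ProteinRecord` objects.

    Parameters
    ----------
    path
        FASTA file; multi-line sequences are allowed.
    label
        Optional class tag ("positive" / "negative") applied to every record.

    Raises
    ------
    ValueError
        On an empty file, sequence data before the first header, a duplicate
        record id, or a record that is empty after canonicalization.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: sequence data before first FASTA header"
                )
            break
        else:
            raise ValueError(f"{path}: empty FASTA file")

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = canonicalize(str(rec.seq), rec.id)
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} empty after canonicalization")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=seq, label=label))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with `width`-column wrapped sequences."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (id, label); no header row required.

    A first row reading exactly ``id<TAB>label`` is treated as a header.
    """
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated columns")
            rid, lab = parts[0].strip(), parts[1].strip()
            if lineno == 1 and (rid, lab) == ("id", "label"):
                continue
            if lab not in (POSITIVE, NEGATIVE):
                raise ValueError(
                    f"{path}: line {lineno}: label must be {POSITIVE!r} or {NEGATIVE!r}"
                )
            labels[rid] = lab
    return labels


def apply_labels(records: Sequence[ProteinRecord], labels: dict[str, str]) -> list[ProteinRecord]:
    """Return records with labels assigned from an id->label mapping."""
    out = []
    for rec in records:
        if rec.id not in labels:
            raise ValueError(f"no label for record {rec.id!r}")
        out.append(ProteinRecord(id=rec.id, sequence=rec.sequence, label=labels[rec.id]))
    return out
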