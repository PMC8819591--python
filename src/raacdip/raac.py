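"""Reduced amino acid cluster (RAAC) schemes.

A reduction scheme partitions the 20 standard amino acids into clusters,
each written as a single representative letter. Reducing a sequence maps
every residue to its cluster representative, shrinking the alphabet while
preserving positional structure — conserved regions become easier to see
and downstream k-mer feature spaces become tractable.

The built-in scheme ``gfvcw5`` groups the amino acids into five clusters
by broad physicochemical character: the large polar/small group
GPHNDERQKAST (written G), the aromatics FY (written F), the aliphatic
hydrophobics VMIL (written V), and the singletons C and W.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from .io_seq import STANDARD_AA

_DEFAULT_SPEC = "GPHNDERQKAST-FY-VMIL-C-W"


@dataclass(frozen=True)
class ReductionScheme:
    """An ordered partition of the 20 amino acids into represented clusters.

    ``clusters`` is a tuple of (members, representative) pairs; members are
    strings of amino-acid letters. Invariants: clusters are pairwise
    disjoint, cover exactly the 20 standard letters, each representative
    belongs to its own cluster, and representatives are pairwise distinct.
    """

    clusters: Tuple[Tuple[str, str], ...]
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        reps: set[str] = set()
        for members, rep in self.clusters:
            if not members:
                raise ValueError("empty cluster")
            for ch in members:
                if ch not in STANDARD_AA:
                    raise ValueError(f"non-amino-acid character {ch!r} in cluster")
                if ch in seen:
                    raise ValueError(f"duplicate letter {ch!r} across clusters")
                seen.add(ch)
            if rep not in members:
                raise ValueError(f"representative {rep!r} not a member of its cluster")
            if rep in reps:
                raise ValueError(f"duplicate representative {rep!r}")
            reps.add(rep)
        missing = sorted(set(STANDARD_AA) - seen)
        if missing:
            raise ValueError(f"scheme does not cover letters: {''.join(missing)}")

    @property
    def representatives(self) -> tuple[str, ...]:
        """Cluster representatives in cluster order (the reduced alphabet)."""
        return tuple(rep for _, rep in self.clusters)

    @property
    def mapping(self) -> dict[str, str]:
        """Residue -> representative lookup over all 20 letters."""
        return {ch: rep for members, rep in self.clusters for ch in members}

    def __len__(self) -> int:
        return len(self.clusters)

    def to_spec(self) -> str:
        """Dash-delimited cluster string (representative-first per cluster)."""
        parts = []
        for members, rep in self.clusters:
            if members[0] == rep:
                parts.append(members)
            else:
                parts.append(f"{members}:{rep}")
        return "-".join(parts)


def default_scheme() -> ReductionScheme:
    """The five-letter scheme {GPHNDERQKAST→G, FY→F, VMIL→V, C→C, W→W}."""
    return parse_scheme(_DEFAULT_SPEC, name="gfvcw5")


def identity_scheme() -> ReductionScheme:
    """Twenty singleton clusters; reduction is the identity map."""
    return ReductionScheme(
        clusters=tuple((ch, ch) for ch in STANDARD_AA), name="identity"
    )


def parse_scheme(spec: str, name: str = "") -> ReductionScheme:
    """Parse a dash-delimited cluster string into a :class:`ReductionScheme`.

    Each dash-separated token is one cluster; its representative defaults to
    the first listed letter, or may be given explicitly as ``MEMBERS:REP``.

    >>> parse_scheme("GPHNDERQKAST-FY-VMIL-C-W").representatives
    ('G', 'F', 'V', 'C', 'W')
    """
    if not spec or not spec.strip():
        raise ValueError("empty scheme specification")
    clusters: list[tuple[str, str]] = []
    for token in spec.strip().split("-"):
        if not token:
            raise ValueError(f"empty cluster in scheme spec {spec!r}")
        if ":" in token:
            members, _, rep = token.partition(":")
            if len(rep) != 1:
                raise ValueError(f"representative must be a single letter: {token!r}")
        else:
            members, rep = token, token[0]
        clusters.append((members.upper(), rep.upper()))
    return ReductionScheme(clusters=tuple(clusters), name=name or spec)


_BUILTIN = {"gfvcw5": default_scheme, "default": default_scheme, "identity": identity_scheme}


def get_scheme(spec_or_name: str) -> ReductionScheme:
    """Resolve a built-in scheme name or parse a cluster-string spec."""
    key = spec_or_name.strip().lower()
    if key in _BUILTIN:
        return _BUILTIN[key]()
    return parse_scheme(spec_or_name)


def reduce_sequence(seq: str, scheme: ReductionScheme) -> str:
    """Map every residue of ``seq`` to its cluster representative.

    Length-preserving; raises if a letter is not covered by the scheme.
    """
    table = scheme.mapping
    try:
        return "".join(table[ch] for ch in seq)
    except KeyError as exc:
        raise ValueError(f"letter {exc.args[0]!r} not covered by scheme {scheme.name!r}")
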