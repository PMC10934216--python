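"""Motif algebra: rotations, reverse complements, canonical labels.

Cyclic rotations of a motif (AAG / AGA / GAA) describe the same repeat read
from different start points, so rotation equivalence defines which SSRs can
belong to one cross-sample group.  Reverse complements (AG vs CT) are a
strictly *reporting-level* equivalence: classification never folds them,
mirroring how the source tallies keep AG, GA and TC separate.
"""

from __future__ import annotations

from ._segment import is_primitive

__all__ = [
    "is_primitive",
    "rotations",
    "are_rotation_equivalent",
    "canonical_rotation",
    "reverse_complement",
    "complement_pair_key",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def rotations(motif: str) -> list[str]:
    """All cyclic rotations of *motif*, in offset order (may repeat)."""
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def are_rotation_equivalent(a: str, b: str) -> bool:
    return len(a) == len(b) and b in rotations(a)


def canonical_rotation(motif: str) -> str:
    """Lexicographically smallest rotation — a stable group label."""
    return min(rotations(motif))


def reverse_complement(motif: str) -> str:
    return motif.translate(_COMPLEMENT)[::-1]


def complement_pair_key(motif: str) -> str:
    """The smaller of motif / reverse complement (complement-aware reports)."""
    return min(motif, reverse_complement(motif))
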