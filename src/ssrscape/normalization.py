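"""Compound-SSR normalization and cross-sample phase consensus.

Raw repeat-finder output can describe one repetitive region in several ways,
two of which need systematic correction when repeats are compared across
samples:

* overlap-style compound descriptions (shared nucleotides between adjacent
  units) are re-segmented into plain adjacent perfect runs — fewest
  components, then longest first component;
* when a fragment starts or ends inside a repeat, the motif's phase
  (rotation) is ambiguous; the rotation observed in the majority of samples
  whose repeat is *not* cut by a fragment edge is taken as the consensus and
  edge-cut repeats are relabeled to it.

A truncation flag records repeats touching fragment ends so that apparent
repeat-count "polymorphism" caused by incomplete fragments can be
discounted downstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Sequence

from ._segment import segment
from .alignment_io import SampleSequence
from .mining import (
    DEFAULT_THRESHOLDS,
    CompoundSSR,
    MotifClassThresholds,
    PerfectSSR,
)
from .motifs import are_rotation_equivalent


@dataclass(frozen=True)
class PhaseConsensus:
    """Chosen motif rotation for one cross-sample repeat interval."""

    locus_id: str
    aln_start: int
    aln_end: int
    candidates: tuple[str, ...]
    chosen: str
    support: tuple[tuple[str, int], ...]  # (rotation, n_samples), all members


def normalize_compound(
    raw_sequence_segment: str,
    thresholds: MotifClassThresholds = DEFAULT_THRESHOLDS,
) -> CompoundSSR | PerfectSSR | None:
    """Re-segment a maximal repetitive region into adjacent perfect runs.

    Returns the segmentation with the fewest components (ties: longest
    earliest component), as a PerfectSSR (one run) or CompoundSSR (several),
    with 1-based coordinates relative to the segment.  Returns ``None`` when
    no segmentation into qualifying runs tiles the segment exactly — the
    segment is then not an SSR and is left unchanged by callers.
    """
    s = raw_sequence_segment.upper()
    pieces = segment(s, thresholds.as_dict(), require_exact=True)
    if not pieces:
        return None
    n = len(s)
    ssrs = []
    for start0, motif, r in pieces:
        end0 = start0 + len(motif) * r - 1
        ssrs.append(
            PerfectSSR(
                sample_id="",
                locus_id="",
                motif=motif,
                repeats=r,
                start=start0 + 1,
                end=end0 + 1,
                aln_start=start0 + 1,
                aln_end=end0 + 1,
                at_edge=(start0 == 0 or end0 == n - 1),
            )
        )
    if len(ssrs) == 1:
        return ssrs[0]
    return CompoundSSR(tuple(ssrs))


def consensus_phase(
    group: Sequence[PerfectSSR],
) -> tuple[PhaseConsensus, list[PerfectSSR]]:
    """Majority-vote motif rotation for rotation-equivalent SSRs.

    Votes come from members not at a fragment edge (edge members owe their
    phase to missing sequence); ties break to the lexicographically smallest
    rotation.  Edge members are relabeled to the chosen rotation; internal
    members keep their observed rotation.  Repeat counts never change.
    """
    if not group:
        raise ValueError("empty group")
    reference = group[0].motif
    for ssr in group[1:]:
        if not are_rotation_equivalent(reference, ssr.motif):
            raise ValueError(
                f"motifs '{reference}' and '{ssr.motif}' are not cyclic rotations "
                "of one another (mis-formed group)"
            )
    voters = [s for s in group if not s.at_edge] or list(group)
    counts = Counter(s.motif for s in voters)
    top = max(counts.values())
    chosen = min(m for m, c in counts.items() if c == top)

    relabeled = [
        replace(s, motif=chosen) if s.at_edge and s.motif != chosen else s
        for s in group
    ]
    consensus = PhaseConsensus(
        locus_id=group[0].locus_id,
        aln_start=min(s.aln_start for s in group),
        aln_end=max(s.aln_end for s in group),
        candidates=tuple(sorted(set(s.motif for s in group))),
        chosen=chosen,
        support=tuple(sorted(Counter(s.motif for s in group).items())),
    )
    return consensus, relabeled


def flag_truncation(ssr: PerfectSSR, seq: SampleSequence) -> PerfectSSR:
    """Set ``truncated`` when the SSR touches the fragment's first/last residue."""
    truncated = ssr.start == 1 or ssr.end == len(seq.residues)
    return replace(ssr, truncated=truncated, at_edge=truncated or ssr.at_edge)


def flag_truncations(
    ssrs: Sequence[PerfectSSR], seq: SampleSequence
) -> list[PerfectSSR]:
    return [flag_truncation(s, seq) for s in ssrs]
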