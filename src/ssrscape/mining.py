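"""Perfect and compound SSR detection on degapped sequences.

The miner reports every maximal run of a primitive 1-6 bp motif that meets
its per-class minimum repeat count (defaults: 12 for mononucleotides, 6 for
dinucleotides, 4 for trinucleotides, 3 for tetra-, penta- and
hexanucleotides).  Runs are broken by 'N' and by sequence ends; partial
trailing units do not count towards the repeat number; a run is reported
under its primitive (shortest-period) motif, phased as it occurs at run
start.

Where qualifying runs of different motifs overlap — the situation MISA
renders with shared-nucleotide notation — the overlapping region is
re-segmented into plain adjacent runs (fewest components, longest first), so
e.g. three GTAT units followed by twelve GT units always come out as
(GTAT)3 + (GT)12.  Strictly adjacent runs (zero interspersed nucleotides)
are then merged into compound SSRs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._segment import MAX_MOTIF_LEN, is_primitive, segment
from .alignment_io import SampleSequence


class MiningError(ValueError):
    pass


@dataclass(frozen=True)
class MotifClassThresholds:
    """Minimum repeat count per motif class (1..6)."""

    min_repeats: tuple[int, ...]  # index 0 -> class 1

    def __post_init__(self) -> None:
        if len(self.min_repeats) != MAX_MOTIF_LEN:
            raise ValueError("thresholds must cover motif classes 1..6")
        if any(v < 2 for v in self.min_repeats):
            raise ValueError("minimum repeat counts must all be >= 2")

    @classmethod
    def from_dict(cls, d: Mapping[int, int]) -> "MotifClassThresholds":
        if set(d) != set(range(1, MAX_MOTIF_LEN + 1)):
            raise ValueError("thresholds must define classes 1..6 exactly")
        return cls(tuple(int(d[k]) for k in range(1, MAX_MOTIF_LEN + 1)))

    def __getitem__(self, motif_class: int) -> int:
        return self.min_repeats[motif_class - 1]

    def as_dict(self) -> dict[int, int]:
        return {k + 1: v for k, v in enumerate(self.min_repeats)}


#: MISA-style defaults used throughout: {1:12, 2:6, 3:4, 4:3, 5:3, 6:3}
DEFAULT_THRESHOLDS = MotifClassThresholds((12, 6, 4, 3, 3, 3))


@dataclass(frozen=True)
class PerfectSSR:
    """A perfect repeat: motif, count, degapped and alignment coordinates.

    All coordinates are 1-based inclusive.  ``at_edge`` marks runs touching
    the first or last residue of the fragment; ``truncated`` is the
    classification-facing alias set by the normalization step.
    """

    sample_id: str
    locus_id: str
    motif: str
    repeats: int
    start: int
    end: int
    aln_start: int
    aln_end: int
    at_edge: bool = False
    truncated: bool = False

    def __post_init__(self) -> None:
        if not (1 <= len(self.motif) <= MAX_MOTIF_LEN):
            raise ValueError(f"motif length {len(self.motif)} outside 1..{MAX_MOTIF_LEN}")
        if not is_primitive(self.motif):
            raise ValueError(f"motif '{self.motif}' is not primitive")
        if self.end - self.start + 1 != len(self.motif) * self.repeats:
            raise ValueError("length_bp must equal class x repeats")

    @property
    def motif_class(self) -> int:
        return len(self.motif)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def label(self) -> str:
        return f"({self.motif}){self.repeats}"


@dataclass(frozen=True)
class CompoundSSR:
    """Two or more perfect SSRs directly adjacent, no interspersed bases."""

    components: tuple[PerfectSSR, ...]

    def __post_init__(self) -> None:
        if len(self.components) < 2:
            raise ValueError("a compound SSR needs at least two components")
        for prev, nxt in zip(self.components, self.components[1:]):
            if nxt.start != prev.end + 1:
                raise ValueError("compound components must be strictly adjacent")
            if nxt.motif == prev.motif:
                raise ValueError("adjacent compound components must differ in motif")

    @property
    def sample_id(self) -> str:
        return self.components[0].sample_id

    @property
    def locus_id(self) -> str:
        return self.components[0].locus_id

    @property
    def start(self) -> int:
        return self.components[0].start

    @property
    def end(self) -> int:
        return self.components[-1].end

    @property
    def aln_start(self) -> int:
        return self.components[0].aln_start

    @property
    def aln_end(self) -> int:
        return self.components[-1].aln_end

    @property
    def total_length_bp(self) -> int:
        return sum(c.length_bp for c in self.components)

    @property
    def at_edge(self) -> bool:
        return self.components[0].at_edge or self.components[-1].at_edge

    @property
    def label(self) -> str:
        return "".join(c.label for c in self.components)


def _chunks_without_n(residues: str) -> Iterable[tuple[int, str]]:
    """Maximal N-free chunks as (offset, chunk)."""
    start = None
    for i, ch in enumerate(residues):
        if ch == "N":
            if start is not None:
                yield start, residues[start:i]
                start = None
        elif start is None:
            start = i
    if start is not None:
        yield start, residues[start:]


def _maximal_runs(chunk: str) -> Iterable[tuple[int, int, int]]:
    """Maximal period-k runs as (span_start0, span_end0, k), k in 1..6."""
    n = len(chunk)
    for k in range(1, MAX_MOTIF_LEN + 1):
        j = k
        while j < n:
            if chunk[j] == chunk[j - k]:
                e = j
                while e < n and chunk[e] == chunk[e - k]:
                    e += 1
                yield j - k, e - 1, k
                j = e + 1
            else:
                j += 1


def find_perfect_ssrs(
    seq: SampleSequence | str,
    thresholds: MotifClassThresholds = DEFAULT_THRESHOLDS,
) -> list[PerfectSSR]:
    """All perfect SSRs of *seq*, sorted by start, non-overlapping."""
    if isinstance(seq, str):
        seq = SampleSequence.from_raw(seq)
    residues = seq.residues
    n = len(residues)
    if n == 0:
        return []

    # Qualifying candidates: (cov_start0, cov_end0, span_start0, span_end0, motif, r)
    cands = []
    for off, chunk in _chunks_without_n(residues):
        for a, b, k in _maximal_runs(chunk):
            motif = chunk[a : a + k]
            if not is_primitive(motif):
                continue
            r = (b - a + 1) // k
            if r < thresholds[k]:
                continue
            cands.append((off + a, off + a + r * k - 1, off + a, off + b, motif, r))
    cands.sort()

    # Resolve clusters of candidates whose covered intervals overlap.
    runs: list[tuple[int, str, int]] = []  # (start0, motif, repeats)
    cluster: list[tuple] = []
    max_cov_end = -1
    for cand in cands:
        if cluster and cand[0] <= max_cov_end:
            cluster.append(cand)
        else:
            runs.extend(_resolve_cluster(cluster, residues, thresholds))
            cluster = [cand]
        max_cov_end = max(max_cov_end, cand[1])
    runs.extend(_resolve_cluster(cluster, residues, thresholds))

    out = []
    for start0, motif, r in sorted(runs):
        end0 = start0 + len(motif) * r - 1
        out.append(
            PerfectSSR(
                sample_id=seq.sample_id,
                locus_id=seq.locus_id,
                motif=motif,
                repeats=r,
                start=start0 + 1,
                end=end0 + 1,
                aln_start=seq.colmap[start0],
                aln_end=seq.colmap[end0],
                at_edge=(start0 == 0 or end0 == n - 1),
            )
        )
    return out


def _resolve_cluster(cluster, residues, thresholds):
    if not cluster:
        return []
    if len(cluster) == 1:
        c = cluster[0]
        return [(c[0], c[4], c[5])]
    region_start = min(c[2] for c in cluster)
    region_end = max(c[3] for c in cluster)
    pieces = segment(residues[region_start : region_end + 1], thresholds.as_dict())
    return [(region_start + i, motif, r) for i, motif, r in pieces]


def merge_compound(
    ssrs: Sequence[PerfectSSR],
) -> tuple[list[CompoundSSR], list[PerfectSSR]]:
    """Merge maximal chains of strictly adjacent SSRs into compound SSRs.

    Input must come from one sample/locus and be non-overlapping.  Returns
    (compounds, remaining simple SSRs); every input appears in exactly one.
    """
    ordered = sorted(ssrs, key=lambda s: s.start)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start <= prev.end:
            raise MiningError(
                f"overlapping SSRs {prev.label}@{prev.start} and {nxt.label}@{nxt.start}"
            )
    compounds: list[CompoundSSR] = []
    simples: list[PerfectSSR] = []
    chain: list[PerfectSSR] = []
    for ssr in ordered:
        if chain and ssr.start == chain[-1].end + 1:
            chain.append(ssr)
        else:
            _flush_chain(chain, compounds, simples)
            chain = [ssr]
    _flush_chain(chain, compounds, simples)
    return compounds, simples


def _flush_chain(chain, compounds, simples):
    if len(chain) >= 2:
        compounds.append(CompoundSSR(tuple(chain)))
    elif chain:
        simples.append(chain[0])


def split_compound(compound: CompoundSSR) -> list[PerfectSSR]:
    """Components of a compound SSR, for component-wise tallies."""
    return list(compound.components)


def subtract_exon_ssrs(
    full: Sequence[PerfectSSR],
    exon_detections: Sequence[PerfectSSR],
    exon_intervals: Mapping[str, tuple[int, int]] | None = None,
) -> list[PerfectSSR]:
    """Remove from *full* every SSR also detected in the exon-only dataset.

    Identity is (sample, locus, motif, repeats, position in the exon
    coordinate frame).  ``exon_intervals`` maps locus_id to the exon's
    alignment-column interval within the full alignment; without it the two
    coordinate frames are assumed to coincide.
    """

    def offset(locus_id: str) -> int:
        if exon_intervals and locus_id in exon_intervals:
            return exon_intervals[locus_id][0] - 1
        return 0

    exon_keys = {
        (s.sample_id, s.locus_id, s.motif, s.repeats, s.aln_start)
        for s in exon_detections
    }
    return [
        s
        for s in full
        if (s.sample_id, s.locus_id, s.motif, s.repeats, s.aln_start - offset(s.locus_id))
        not in exon_keys
    ]


# ---------------------------------------------------------------------------
# MISA-style TSV output (1-based inclusive coordinates)

_SSR_COLUMNS = [
    "ID",
    "SSR nr.",
    "type",
    "SSR",
    "size",
    "start",
    "end",
    "aln_start",
    "aln_end",
    "at_edge",
    "truncated",
]


def write_ssr_table(
    simples: Sequence[PerfectSSR],
    compounds: Sequence[CompoundSSR],
    path: str | Path,
) -> None:
    """MISA-like table: one row per simple SSR or compound (type p1..p6 / c)."""
    import pandas as pd

    rows = []
    items: list[tuple[str, object]] = [("p", s) for s in simples] + [
        ("c", c) for c in compounds
    ]
    items.sort(key=lambda t: (t[1].sample_id, t[1].locus_id, t[1].start))
    counter: dict[tuple[str, str], int] = {}
    for kind, item in items:
        key = (item.sample_id, item.locus_id)
        counter[key] = counter.get(key, 0) + 1
        if kind == "p":
            typ = f"p{item.motif_class}"
            size = item.length_bp
            truncated = item.truncated
        else:
            typ = "c"
            size = item.total_length_bp
            truncated = any(c.truncated for c in item.components)
        rows.append(
            {
                "ID": f"{item.sample_id}|{item.locus_id}",
                "SSR nr.": counter[key],
                "type": typ,
                "SSR": item.label,
                "size": size,
                "start": item.start,
                "end": item.end,
                "aln_start": item.aln_start,
                "aln_end": item.aln_end,
                "at_edge": int(item.at_edge),
                "truncated": int(truncated),
            }
        )
    pd.DataFrame(rows, columns=_SSR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ssr_table(path: str | Path) -> tuple[list[PerfectSSR], list[CompoundSSR]]:
    """Parse a table written by :func:`write_ssr_table` (lossless for rows)."""
    import re

    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype={"ID": str, "SSR": str})
    simples: list[PerfectSSR] = []
    compounds: list[CompoundSSR] = []
    for row in frame.to_dict("records"):
        sample_id, locus_id = str(row["ID"]).split("|", 1)
        parts = re.findall(r"\(([ACGTN]+)\)(\d+)", str(row["SSR"]))
        start = int(row["start"])
        aln_start = int(row["aln_start"])
        aln_span = int(row["aln_end"]) - aln_start + 1
        comps = []
        pos, aln_pos = start, aln_start
        total = sum(len(m) * int(r) for m, r in parts)
        for motif, r_str in parts:
            r = int(r_str)
            length = len(motif) * r
            # alignment span can exceed degapped length (internal gap columns);
            # apportioning it across components is only exact for simple SSRs,
            # so component alignment ends are reconstructed proportionally.
            aln_len = round(aln_span * length / total) if total else length
            comps.append(
                PerfectSSR(
                    sample_id=sample_id,
                    locus_id=locus_id,
                    motif=motif,
                    repeats=r,
                    start=pos,
                    end=pos + length - 1,
                    aln_start=aln_pos,
                    aln_end=aln_pos + aln_len - 1,
                    at_edge=bool(int(row["at_edge"])),
                    truncated=bool(int(row["truncated"])),
                )
            )
            pos += length
            aln_pos += aln_len
        if row["type"] == "c":
            # fix the final component's alignment end to the recorded value
            last = comps[-1]
            comps[-1] = replace(last, aln_end=int(row["aln_end"]))
            compounds.append(CompoundSSR(tuple(comps)))
        else:
            simples.append(replace(comps[0], aln_end=int(row["aln_end"])))
    return simples, compounds
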