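"""Synthetic multi-sample alignments with planted SSRs and a truth ledger.

The generator emulates the structure of fragmented target-enrichment
alignment data: a few hundred loci of 159-2228 bp, 20-30 samples spanning
several genera, heavy per-sample missing data realized as leading/trailing
gap blocks, repeat-count differences realized as alignment gap columns in
the shorter samples, repeats truncated by fragment edges, and an exon
column interval per locus so the exon-only / exon+flank dataset pair can be
reproduced.

Background sequence is i.i.d. bases rejection-sampled until the miner —
run as its own oracle — detects exactly the planted repeats and nothing
else, which makes the truth ledger exact rather than probabilistic.  Every
draw comes from a single seeded generator, so outputs are byte-identical
for a given configuration.

What is deliberately not emulated: substitution variation between samples
(backgrounds are shared), evolutionary SSR mutation processes, and
alignment errors.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment_io import (
    LocusAlignment,
    TaxonRow,
    TaxonTable,
    degap,
    write_taxonomy,
)
from .mining import DEFAULT_THRESHOLDS, MotifClassThresholds, find_perfect_ssrs

_BASES = np.array(list("ACGT"))
_SPACER = 12


class SimulationError(ValueError):
    pass


@dataclass
class PlantedSSR:
    """One planted repeat: who carries it, with how many units."""

    motif: str
    repeats_by_sample: dict[str, int]
    category: str  # unique | shared | polymorphic (intended, pre-truncation)
    tier: str
    locus_index: int
    truncate: dict[str, int] = field(default_factory=dict)  # sample -> cut units
    compound_group: int | None = None
    compound_order: int = 0
    in_exon: bool = False

    @property
    def motif_class(self) -> int:
        return len(self.motif)

    @property
    def max_repeats(self) -> int:
        return max(self.repeats_by_sample.values())

    def observed_repeats(self) -> dict[str, int]:
        """Per-sample repeat counts after edge truncation."""
        return {
            s: r - self.truncate.get(s, 0) for s, r in self.repeats_by_sample.items()
        }


@dataclass
class SimulationConfig:
    taxonomy: dict[str, dict[str, list[str]]]  # genus -> species -> sample ids
    n_loci: int
    seed: int
    planted: list[PlantedSSR] = field(default_factory=list)
    locus_length_range: tuple[int, int] = (159, 2228)
    missing_frac_range: tuple[float, float] = (0.05, 0.7)
    gap_rate: float = 0.005
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    thresholds: MotifClassThresholds = DEFAULT_THRESHOLDS
    with_exons: bool = False
    exon_frac: float = 0.4


@dataclass(frozen=True)
class LedgerRecord:
    """Ground truth for one planted SSR (or compound component)."""

    record_id: str
    locus_id: str
    motif: str
    motif_class: int
    category: str
    tier: str
    observed_category: str
    observed_tier: str
    repeats_by_sample: tuple[tuple[str, int], ...]
    observed_repeats_by_sample: tuple[tuple[str, int], ...]
    truncated_samples: tuple[str, ...]
    compound_group: int | None
    in_exon: bool
    aln_start: int  # 1-based alignment column of the repeat block
    aln_end: int  # last column of the widest sample's repeat


@dataclass
class TruthLedger:
    records: list[LedgerRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "record_id": r.record_id,
                    "locus_id": r.locus_id,
                    "motif": r.motif,
                    "motif_class": r.motif_class,
                    "category": r.category,
                    "tier": r.tier,
                    "observed_category": r.observed_category,
                    "observed_tier": r.observed_tier,
                    "samples": ";".join(f"{s}:{n}" for s, n in r.repeats_by_sample),
                    "observed": ";".join(
                        f"{s}:{n}" for s, n in r.observed_repeats_by_sample
                    ),
                    "truncated_samples": ";".join(r.truncated_samples),
                    "compound_group": "" if r.compound_group is None else r.compound_group,
                    "in_exon": int(r.in_exon),
                    "aln_start": r.aln_start,
                    "aln_end": r.aln_end,
                }
                for r in self.records
            ]
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SimulationResult:
    full: list[LocusAlignment]
    exon: list[LocusAlignment] | None
    taxonomy: TaxonTable
    ledger: TruthLedger
    exon_intervals: dict[str, tuple[int, int]] | None


def _flatten_samples(taxonomy: Mapping[str, Mapping[str, Sequence[str]]]) -> list[str]:
    out = []
    for genus in taxonomy.values():
        for samples in genus.values():
            out.extend(samples)
    return out


def _taxon_table(taxonomy: Mapping[str, Mapping[str, Sequence[str]]]) -> TaxonTable:
    rows = []
    i = 0
    for genus, species_map in taxonomy.items():
        for species, samples in species_map.items():
            for s in samples:
                i += 1
                rows.append(TaxonRow(s, species, genus, f"V{i:03d}", f"SEQ{i:03d}"))
    return TaxonTable(tuple(rows))


def infer_category_tier(
    repeats_by_sample: Mapping[str, int], taxonomy: TaxonTable
) -> tuple[str, str]:
    """Intended category/tier implied by a per-sample repeat map."""
    samples = list(repeats_by_sample)
    counts = set(repeats_by_sample.values())
    if len(samples) == 1:
        return "unique", "not_applicable"

    def narrowest(ids):
        sp = {taxonomy.species_of(s) for s in ids}
        if len(sp) == 1:
            return "within_species"
        ge = {taxonomy.genus_of(s) for s in ids}
        return "within_genus" if len(ge) == 1 else "across_genera"

    if len(counts) == 1:
        return "shared", narrowest(samples)
    sp_counts: dict[str, set[int]] = {}
    ge_counts: dict[str, set[int]] = {}
    for s, r in repeats_by_sample.items():
        sp_counts.setdefault(taxonomy.species_of(s), set()).add(r)
        ge_counts.setdefault(taxonomy.genus_of(s), set()).add(r)
    if any(len(c) > 1 for c in sp_counts.values()):
        return "polymorphic", "within_species"
    if any(len(c) > 1 for c in ge_counts.values()):
        return "polymorphic", "within_genus"
    return "polymorphic", "across_genera"


def _validate_config(config: SimulationConfig, taxonomy: TaxonTable) -> None:
    known = set(taxonomy.sample_ids)
    groups: dict[int, set[frozenset]] = {}
    for p in config.planted:
        if not (0 <= p.locus_index < config.n_loci):
            raise SimulationError(f"planted SSR locus_index {p.locus_index} out of range")
        unknown = set(p.repeats_by_sample) - known
        if unknown:
            raise SimulationError(f"planted SSR references unknown samples {sorted(unknown)}")
        cat, tier = infer_category_tier(p.repeats_by_sample, taxonomy)
        if (cat, tier) != (p.category, p.tier):
            raise SimulationError(
                f"planted ({p.motif}) at locus {p.locus_index}: intended "
                f"{p.category}/{p.tier} inconsistent with repeats (implies {cat}/{tier})"
            )
        thr = config.thresholds[p.motif_class]
        for s, r in p.repeats_by_sample.items():
            if r < thr:
                raise SimulationError(
                    f"planted ({p.motif}){r} below class threshold {thr}"
                )
            cut = p.truncate.get(s, 0)
            if cut and not (1 <= cut <= r - thr):
                raise SimulationError(
                    f"truncation cut {cut} for ({p.motif}){r} must leave >= {thr} units"
                )
        if p.compound_group is not None:
            groups.setdefault(p.compound_group, set()).add(
                frozenset(p.repeats_by_sample)
            )
    for gid, sample_sets in groups.items():
        if len(sample_sets) > 1:
            raise SimulationError(
                f"compound group {gid}: all components must share one sample set"
            )


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate alignments, a taxonomy table and the truth ledger."""
    taxonomy = _taxon_table(config.taxonomy)
    _validate_config(config, taxonomy)
    rng = np.random.default_rng(config.seed)
    samples = list(taxonomy.sample_ids)

    lo, hi = config.missing_frac_range
    missing = {s: float(rng.uniform(lo, hi)) for s in samples}

    by_locus: dict[int, list[PlantedSSR]] = {}
    for p in config.planted:
        by_locus.setdefault(p.locus_index, []).append(p)

    full: list[LocusAlignment] = []
    exon: list[LocusAlignment] = []
    exon_intervals: dict[str, tuple[int, int]] = {}
    records: list[LedgerRecord] = []
    rec_no = 0

    for locus_index in range(config.n_loci):
        locus_id = f"L{locus_index + 1}"
        specs = sorted(
            by_locus.get(locus_index, []),
            key=lambda p: (p.compound_group if p.compound_group is not None else -1, p.compound_order),
        )
        aln, layout, exon_iv = _build_locus(
            locus_id, specs, samples, missing, config, rng
        )
        full.append(aln)
        if config.with_exons:
            exon_intervals[locus_id] = exon_iv
            exon.append(aln.slice_columns(*exon_iv))
        for p in specs:
            rec_no += 1
            bstart0 = layout[id(p)]
            obs = p.observed_repeats()
            ocat, otier = infer_category_tier(obs, taxonomy)
            records.append(
                LedgerRecord(
                    record_id=f"P{rec_no:03d}",
                    locus_id=locus_id,
                    motif=p.motif,
                    motif_class=p.motif_class,
                    category=p.category,
                    tier=p.tier,
                    observed_category=ocat,
                    observed_tier=otier,
                    repeats_by_sample=tuple(sorted(p.repeats_by_sample.items())),
                    observed_repeats_by_sample=tuple(sorted(obs.items())),
                    truncated_samples=tuple(sorted(p.truncate)),
                    compound_group=p.compound_group,
                    in_exon=p.in_exon,
                    aln_start=bstart0 + 1,
                    aln_end=bstart0 + p.max_repeats * p.motif_class,
                )
            )

    return SimulationResult(
        full=full,
        exon=exon if config.with_exons else None,
        taxonomy=taxonomy,
        ledger=TruthLedger(records),
        exon_intervals=exon_intervals if config.with_exons else None,
    )


def _block_groups(specs: list[PlantedSSR]) -> list[list[PlantedSSR]]:
    groups: dict[object, list[PlantedSSR]] = {}
    order: list[object] = []
    for p in specs:
        key = ("c", p.compound_group) if p.compound_group is not None else ("s", id(p))
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(p)
    return [sorted(groups[k], key=lambda p: p.compound_order) for k in order]


def _place_in_region(groups, region_start, region_len, rng):
    """Left-to-right placement with >= _SPACER background between/around blocks."""
    widths = [sum(p.max_repeats * p.motif_class for p in g) for g in groups]
    n_slots = len(groups) + 1
    extra = region_len - sum(widths) - n_slots * _SPACER
    if extra < 0:
        return None
    cuts = rng.multinomial(extra, [1.0 / n_slots] * n_slots) if n_slots else []
    starts = []
    pos = region_start
    for g, w, cut in zip(groups, widths, cuts):
        pos += _SPACER + int(cut)
        starts.append(pos)
        pos += w
    return starts


def _required_len(groups) -> int:
    widths = sum(sum(p.max_repeats * p.motif_class for p in g) for g in groups)
    return widths + (len(groups) + 1) * _SPACER


def _build_locus(locus_id, specs, samples, missing, config, rng):
    lo, hi = config.locus_length_range
    groups = _block_groups(specs)

    if config.with_exons:
        exon_groups = [g for g in groups if g[0].in_exon]
        flank_groups = [g for g in groups if not g[0].in_exon]
        left_flank = flank_groups[::2]
        right_flank = flank_groups[1::2]
    else:
        exon_groups, left_flank, right_flank = [], groups, []

    # minimum length so every region has capacity
    if config.with_exons:
        need = max(
            int(np.ceil(_required_len(exon_groups) / config.exon_frac)),
            int(
                np.ceil(
                    (_required_len(left_flank) + _required_len(right_flank))
                    / (1 - config.exon_frac)
                )
            ),
            lo,
        )
    else:
        need = max(_required_len(left_flank), lo)
    if need > hi:
        raise SimulationError(
            f"locus {locus_id}: planted SSRs need {need} bp but the maximum "
            f"locus length is {hi} (unplaceable SSR)"
        )
    L = int(rng.integers(lo, hi + 1))
    if L < need:
        L = int(rng.integers(need, hi + 1))

    # region layout and block placement (fixed across attempts)
    for _ in range(50):  # placement retries (multinomial slack may not fit a side)
        if config.with_exons:
            exon_len = int(round(L * config.exon_frac))
            exon_start = (L - exon_len) // 2
            exon_iv = (exon_start + 1, exon_start + exon_len)
            s1 = _place_in_region(left_flank, 0, exon_start, rng)
            s2 = _place_in_region(exon_groups, exon_start, exon_len, rng)
            s3 = _place_in_region(right_flank, exon_start + exon_len, L - exon_start - exon_len, rng)
            if s1 is None or s2 is None or s3 is None:
                continue
            placed = list(zip(left_flank, s1)) + list(zip(exon_groups, s2)) + list(
                zip(right_flank, s3)
            )
        else:
            exon_iv = (1, L)
            s1 = _place_in_region(left_flank, 0, L, rng)
            if s1 is None:
                continue
            placed = list(zip(left_flank, s1))
        break
    else:
        raise SimulationError(f"locus {locus_id}: could not place planted SSRs")

    layout: dict[int, int] = {}
    block_regions = []  # (gstart0, gend0) whole block group extents
    for group, gstart in placed:
        pos = gstart
        for p in group:
            layout[id(p)] = pos
            pos += p.max_repeats * p.motif_class
        block_regions.append((gstart, pos - 1))

    aln = _assemble_with_rejection(
        locus_id, L, placed, layout, block_regions, samples, missing, config, rng
    )
    return aln, layout, exon_iv


def _assemble_with_rejection(
    locus_id, L, placed, layout, block_regions, samples, missing, config, rng
):
    thresholds = config.thresholds
    probs = np.asarray(config.base_composition, dtype=float)
    probs = probs / probs.sum()

    for _attempt in range(200):
        background = rng.choice(_BASES, size=L, p=probs)
        # juncture bases must not extend a planted run by one unit
        for group, gstart in placed:
            first, last = group[0], group[-1]
            gend = layout[id(last)] + last.max_repeats * last.motif_class - 1
            if gstart - 1 >= 0:
                background[gstart - 1] = rng.choice(
                    [b for b in "ACGT" if b != first.motif[-1]]
                )
            if gend + 1 < L:
                background[gend + 1] = rng.choice(
                    [b for b in "ACGT" if b != last.motif[0]]
                )

        rows: dict[str, str] = {}
        expected: dict[str, set] = {}
        ok = True
        for s in samples:
            row = background.copy()
            carried = []
            for group, _gstart in placed:
                carrier = s in group[0].repeats_by_sample
                for p in group:
                    b0 = layout[id(p)]
                    width = p.max_repeats * p.motif_class
                    if carrier:
                        r = p.repeats_by_sample[s]
                        content = p.motif * r + "-" * ((p.max_repeats - r) * p.motif_class)
                        row[b0 : b0 + width] = list(content)
                        carried.append(p)
                    else:
                        row[b0 : b0 + width] = ["-"] * width
            a, b = _sample_window(s, L, carried, layout, missing[s], rng)
            if a is not None:
                row[:a] = "-"
                row[b + 1 :] = "-"
            else:
                row[:] = "-"

            # sparse internal gaps in background positions only
            if config.gap_rate > 0 and a is not None:
                eligible = _eligible_gap_positions(L, a, b, block_regions)
                if eligible.size:
                    n_gaps = rng.binomial(eligible.size, config.gap_rate)
                    if n_gaps:
                        for pos in rng.choice(eligible, size=n_gaps, replace=False):
                            row[pos] = "-"

            rows[s] = "".join(row)
            exp = set()
            for p in carried:
                b0 = layout[id(p)]
                cut = p.truncate.get(s, 0)
                exp.add((b0 + cut * p.motif_class + 1, p.motif, p.repeats_by_sample[s] - cut))
            expected[s] = exp

        for s in samples:
            seq = degap(rows[s], sample_id=s, locus_id=locus_id)
            if not len(seq):
                if expected[s]:
                    ok = False
                    break
                continue
            found = {
                (ssr.aln_start, ssr.motif, ssr.repeats)
                for ssr in find_perfect_ssrs(seq, thresholds)
            }
            if found != expected[s]:
                ok = False
                break
        if ok:
            return LocusAlignment(locus_id, tuple((s, rows[s]) for s in samples))
    raise SimulationError(
        f"locus {locus_id}: could not generate an SSR-clean background in 200 attempts"
    )


def _sample_window(sample, L, carried, layout, missing_frac, rng):
    """Contiguous kept interval [a, b] (0-based) or (None, None) if absent."""
    keep = float(np.clip(1.0 - missing_frac + rng.normal(0, 0.05), 0.02, 1.0))
    w = int(round(keep * L))
    if not carried:
        if w <= 0:
            return None, None
        a = int(rng.integers(0, L - w + 1))
        return a, a + w - 1

    span_lo = min(layout[id(p)] for p in carried)
    span_hi = max(
        layout[id(p)] + p.max_repeats * p.motif_class - 1 for p in carried
    )
    truncated = [p for p in carried if sample in p.truncate]
    if truncated:
        p = truncated[0]
        a = layout[id(p)] + p.truncate[sample] * p.motif_class
        b = min(L - 1, max(a + w - 1, span_hi + 1))
        return a, b

    need = span_hi + 1 - (span_lo - 1) + 1
    w = min(L, max(w, need))
    slack = w - need
    left_extra = int(rng.integers(0, slack + 1)) if slack > 0 else 0
    a = max(0, span_lo - 1 - left_extra)
    b = min(L - 1, max(a + w - 1, span_hi + 1))
    return a, b


def _eligible_gap_positions(L, a, b, block_regions):
    mask = np.zeros(L, dtype=bool)
    mask[a : b + 1] = True
    for gs, ge in block_regions:
        mask[max(0, gs - 1) : min(L, ge + 2)] = False
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# Plans: realistic planted-SSR mixes


_MOTIF_POOL = {
    1: ["A", "T", "C"],
    2: ["AG", "GA", "TC", "AC", "TA", "GT", "CT"],
    3: ["AAG", "ATG", "GAT", "TGC", "TTG"],
    4: ["GCAT", "TTTG", "GGGT", "TTTA", "GAGG"],
    5: ["TCTCC", "AAAAG"],
    6: ["TTTCTT", "AATGGC"],
}
_CLASS_WEIGHTS = [0.09, 0.53, 0.12, 0.17, 0.02, 0.07]
_REPEAT_RANGE = {1: (12, 18), 2: (6, 15), 3: (4, 8), 4: (3, 6), 5: (3, 5), 6: (3, 5)}
# compound partners verified to re-segment into themselves when adjacent
_COMPOUND_PAIRS = [("GTAT", "GT"), ("AAG", "TG"), ("TC", "GATA"), ("AC", "TTG")]
_COMPOUND_TRIPLE = ("AAG", "TG", "CT")


def _species_with_multiple(taxonomy) -> list[tuple[str, str, list[str]]]:
    return [
        (g, sp, list(ss))
        for g, sps in taxonomy.items()
        for sp, ss in sps.items()
        if len(ss) >= 2
    ]


def _pick_samples_for_tier(taxonomy, tier, n, rng) -> list[str]:
    genera = list(taxonomy)
    if tier == "within_species":
        g, sp, ss = _species_with_multiple(taxonomy)[
            rng.integers(0, len(_species_with_multiple(taxonomy)))
        ]
        return list(ss[:2])
    if tier == "within_genus":
        candidates = [g for g in genera if len(taxonomy[g]) >= 2]
        g = candidates[int(rng.integers(0, len(candidates)))]
        species = list(taxonomy[g])
        k = min(max(2, n), len(species))
        chosen = list(rng.choice(len(species), size=k, replace=False))
        return [taxonomy[g][species[i]][0] for i in chosen]
    # across_genera
    k = min(max(2, n), len(genera))
    chosen = list(rng.choice(len(genera), size=k, replace=False))
    out = []
    for i in chosen:
        g = genera[i]
        sp = list(taxonomy[g])[int(rng.integers(0, len(taxonomy[g])))]
        out.append(taxonomy[g][sp][0])
    return out


def _draw_motif(rng, classes=None) -> tuple[str, int]:
    if classes is None:
        cls = int(rng.choice(np.arange(1, 7), p=_CLASS_WEIGHTS))
    else:
        cls = int(classes[int(rng.integers(0, len(classes)))])
    pool = _MOTIF_POOL[cls]
    motif = pool[int(rng.integers(0, len(pool)))]
    lo, hi = _REPEAT_RANGE[cls]
    return motif, int(rng.integers(lo, hi + 1))


def standard_plan(
    taxonomy: Mapping[str, Mapping[str, Sequence[str]]],
    n_loci: int,
    seed: int,
    n_unique: int = 6,
    n_shared: int = 10,
    n_polymorphic: int = 20,
    n_compound: int = 3,
    n_truncated: int = 4,
    with_exons: bool = False,
    n_exon_shared: int = 2,
) -> list[PlantedSSR]:
    """A planted-SSR mix echoing real flanking-region data: polymorphic
    repeats dominate, then shared, then unique, with a few compounds and
    edge truncations."""
    rng = np.random.default_rng(seed)
    n_specs = n_unique + n_shared + n_polymorphic + n_compound + (
        n_exon_shared if with_exons else 0
    )
    if n_specs > n_loci:
        raise SimulationError(f"need >= {n_specs} loci for the requested plan")
    loci = list(rng.permutation(n_loci))
    all_samples = _flatten_samples(taxonomy)
    tiers = ["within_species", "within_genus", "across_genera"]
    planted: list[PlantedSSR] = []
    taxon_table = _taxon_table({g: dict(sps) for g, sps in taxonomy.items()})

    def next_locus() -> int:
        return int(loci.pop())

    for _ in range(n_unique):
        motif, r = _draw_motif(rng)
        s = all_samples[int(rng.integers(0, len(all_samples)))]
        planted.append(
            PlantedSSR(motif, {s: r}, "unique", "not_applicable", next_locus())
        )

    for i in range(n_shared):
        tier = tiers[i % 3]
        motif, r = _draw_motif(rng)
        ss = _pick_samples_for_tier(taxonomy, tier, int(rng.integers(2, 7)), rng)
        planted.append(
            PlantedSSR(motif, {s: r for s in ss}, "shared", tier, next_locus())
        )

    for i in range(n_polymorphic):
        tier = tiers[i % 3]
        motif, r = _draw_motif(rng)
        ss = _pick_samples_for_tier(taxonomy, tier, int(rng.integers(2, 6)), rng)
        repeats = _polymorphic_counts(ss, r, tier, taxon_table, rng)
        planted.append(PlantedSSR(motif, repeats, "polymorphic", tier, next_locus()))

    for i in range(n_compound):
        motifs = _COMPOUND_TRIPLE if i == 0 else _COMPOUND_PAIRS[i % len(_COMPOUND_PAIRS)]
        tier = tiers[i % 3]
        ss = _pick_samples_for_tier(taxonomy, tier, 3, rng)
        locus = next_locus()
        polymorphic = i % 2 == 1
        for order, motif in enumerate(motifs):
            lo_r, hi_r = _REPEAT_RANGE[len(motif)]
            base = int(rng.integers(lo_r, hi_r + 1))
            if polymorphic and order == 0:
                repeats = _polymorphic_counts(ss, base, tier, taxon_table, rng)
                cat = "polymorphic"
            else:
                repeats = {s: base for s in ss}
                cat, _ = infer_category_tier(repeats, taxon_table)
            planted.append(
                PlantedSSR(
                    motif,
                    repeats,
                    cat,
                    tier if cat != "unique" else "not_applicable",
                    locus,
                    compound_group=i,
                    compound_order=order,
                )
            )

    if with_exons:
        for _ in range(n_exon_shared):
            motif, _ = _draw_motif(rng, classes=[2, 3, 4])
            r = DEFAULT_THRESHOLDS[len(motif)]  # exon SSRs sit at threshold length
            ss = _pick_samples_for_tier(taxonomy, "across_genera", 3, rng)
            planted.append(
                PlantedSSR(
                    motif,
                    {s: r for s in ss},
                    "shared",
                    "across_genera",
                    next_locus(),
                    in_exon=True,
                )
            )

    # edge truncations on shared, non-compound specs with headroom
    eligible = [
        p
        for p in planted
        if p.category == "shared"
        and p.compound_group is None
        and not p.in_exon
        and p.max_repeats >= DEFAULT_THRESHOLDS[p.motif_class] + 1
    ]
    for p in eligible[:n_truncated]:
        victim = sorted(p.repeats_by_sample)[0]
        r = p.repeats_by_sample[victim]
        max_cut = r - DEFAULT_THRESHOLDS[p.motif_class]
        p.truncate[victim] = int(min(max_cut, 1 + int(rng.integers(0, 2))))
    return planted


def _polymorphic_counts(samples, base, tier, taxon_table, rng):
    """Repeat counts realizing polymorphism at exactly the requested tier."""
    if tier == "within_species":
        return {samples[0]: base, samples[1]: base + 1 + int(rng.integers(0, 3))}
    if tier == "within_genus":
        # differing counts between species of one genus; one count per species
        counts = {}
        for i, s in enumerate(samples):
            counts[s] = base + (i % 2) * (1 + int(rng.integers(0, 3)))
        if len(set(counts.values())) == 1:
            counts[samples[-1]] = base + 2
        return counts
    # across_genera: one count per genus, differing between genera
    counts = {}
    genus_offset: dict[str, int] = {}
    for s in samples:
        g = taxon_table.genus_of(s)
        if g not in genus_offset:
            genus_offset[g] = len(genus_offset) * (1 + int(rng.integers(0, 2)))
        counts[s] = base + genus_offset[g]
    if len(set(counts.values())) == 1:
        last = samples[-1]
        counts[last] = base + 2
    return counts


def example_taxonomy(n_samples: int = 24) -> dict[str, dict[str, list[str]]]:
    """A 4-genus taxonomy with several multi-sample species, 24 samples."""
    tax = {
        "Genus1": {
            "Genus1 alpha": ["S01", "S02"],
            "Genus1 beta": ["S03", "S04"],
            "Genus1 gamma": ["S05"],
            "Genus1 delta": ["S06"],
            "Genus1 epsilon": ["S07"],
        },
        "Genus2": {
            "Genus2 alpha": ["S08", "S09"],
            "Genus2 beta": ["S10"],
            "Genus2 gamma": ["S11"],
            "Genus2 sp.": ["S12", "S13"],
        },
        "Genus3": {
            "Genus3 alpha": ["S14", "S15", "S16"],
            "Genus3 beta": ["S17"],
            "Genus3 gamma": ["S18"],
            "Genus3 delta": ["S19"],
        },
        "Genus4": {
            "Genus4 alpha": ["S20", "S21"],
            "Genus4 beta": ["S22"],
            "Genus4 gamma": ["S23"],
            "Genus4 delta": ["S24"],
        },
    }
    flat = _flatten_samples(tax)
    if n_samples > len(flat):
        raise ValueError(f"example taxonomy holds at most {len(flat)} samples")
    if n_samples < len(flat):
        keep = set(flat[:n_samples])
        tax = {
            g: {
                sp: [s for s in ss if s in keep]
                for sp, ss in sps.items()
                if any(s in keep for s in ss)
            }
            for g, sps in tax.items()
        }
        tax = {g: sps for g, sps in tax.items() if sps}
    return tax


def fixture_small(seed: int = 11) -> SimulationResult:
    """Deterministic 5-sample, 10-locus miniature dataset.

    Hand-checkable planted truth: one unique, two shared, two polymorphic,
    one three-way compound pair and one edge-truncated shared repeat.
    """
    taxonomy = {
        "GenusA": {
            "GenusA one": ["SA1a", "SA1b"],
            "GenusA two": ["SA2"],
        },
        "GenusB": {
            "GenusB one": ["SB1"],
            "GenusB two": ["SB2"],
        },
    }
    planted = [
        PlantedSSR("AG", {"SA2": 7}, "unique", "not_applicable", 0),
        PlantedSSR("GCAT", {"SA1a": 3, "SA1b": 3}, "shared", "within_species", 1),
        PlantedSSR("AG", {"SA2": 6, "SB1": 6}, "shared", "across_genera", 2),
        PlantedSSR("TGC", {"SA1a": 4, "SA2": 6}, "polymorphic", "within_genus", 3),
        PlantedSSR("AC", {"SA1b": 8, "SB2": 11}, "polymorphic", "across_genera", 4),
        PlantedSSR(
            "GTAT", {"SB1": 3, "SB2": 3}, "shared", "within_genus", 5,
            compound_group=0, compound_order=0,
        ),
        PlantedSSR(
            "GT", {"SB1": 12, "SB2": 12}, "shared", "within_genus", 5,
            compound_group=0, compound_order=1,
        ),
        PlantedSSR(
            "TTTG", {"SA1a": 4, "SA1b": 4}, "shared", "within_species", 6,
            truncate={"SA1b": 1},
        ),
    ]
    config = SimulationConfig(
        taxonomy=taxonomy,
        n_loci=10,
        seed=seed,
        planted=planted,
        locus_length_range=(159, 600),
        missing_frac_range=(0.0, 0.3),
        gap_rate=0.005,
    )
    return simulate(config)


def write_simulation(result: SimulationResult, outdir: str | Path) -> None:
    """Write FASTA alignments, taxonomy, ledger and exon intervals to disk."""
    outdir = Path(outdir)
    (outdir / "full").mkdir(parents=True, exist_ok=True)
    for aln in result.full:
        _write_fasta(aln, outdir / "full" / f"{aln.locus_id}.fasta")
    if result.exon is not None:
        (outdir / "exon").mkdir(parents=True, exist_ok=True)
        for aln in result.exon:
            _write_fasta(aln, outdir / "exon" / f"{aln.locus_id}.fasta")
        pd.DataFrame(
            [
                {"locus_id": k, "exon_aln_start": a, "exon_aln_end": b}
                for k, (a, b) in sorted(result.exon_intervals.items())
            ]
        ).to_csv(outdir / "exon_intervals.tsv", sep="\t", index=False)
    write_taxonomy(result.taxonomy, outdir / "taxonomy.tsv")
    result.ledger.write(outdir / "ledger.tsv")


def _write_fasta(aln: LocusAlignment, path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sample_id, seq in aln.records:
            fh.write(f">{sample_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
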