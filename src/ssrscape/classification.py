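"""Cross-sample SSR grouping and unique/shared/polymorphic classification.

Two SSRs from different samples belong to the same locus group when their
alignment-column intervals overlap by at least one column and their motifs
are cyclic rotations of each other (equal class); transitive closure defines
the groups.  Reverse complements are *not* equated.  Each group is then:

* unique       — one sample only (taxonomic tier not applicable);
* shared       — >= 2 samples, all with the same repeat count;
* polymorphic  — >= 2 samples with differing repeat counts;

with the tier being the narrowest taxonomic rank (species < genus < across
genera) containing all members (shared) or at least two members with
differing repeat counts (polymorphic).  Groups whose apparent polymorphism
vanishes once edge-truncated members are ignored are flagged
``edge_artifact`` rather than silently re-categorized.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .alignment_io import TaxonTable
from .mining import PerfectSSR
from .motifs import canonical_rotation

CATEGORIES = ("unique", "shared", "polymorphic")
TIERS = ("within_species", "within_genus", "across_genera", "not_applicable")


@dataclass(frozen=True)
class GroupMember:
    sample_id: str
    motif: str
    repeats: int
    truncated: bool
    aln_start: int
    aln_end: int


@dataclass(frozen=True)
class SSRLocusGroup:
    """SSRs from different samples at one alignment interval, one motif family."""

    locus_id: str
    aln_start: int
    aln_end: int
    motif_key: str  # canonical rotation of the member motifs
    members: tuple[GroupMember, ...]
    multi_hit: bool = False  # a sample contributed more than one SSR

    @property
    def n_samples(self) -> int:
        return len({m.sample_id for m in self.members})

    @property
    def motif_class(self) -> int:
        return len(self.motif_key)

    def min_overlap_fraction(self) -> float:
        """Weakest pairwise member overlap (audit aid: lets users re-filter
        groups joined on very few shared columns)."""
        if len(self.members) == 1:
            return 1.0
        fracs = []
        for i, a in enumerate(self.members):
            for b in self.members[i + 1 :]:
                overlap = min(a.aln_end, b.aln_end) - max(a.aln_start, b.aln_start) + 1
                if overlap > 0:
                    shorter = min(
                        a.aln_end - a.aln_start + 1, b.aln_end - b.aln_start + 1
                    )
                    fracs.append(overlap / shorter)
        return min(fracs) if fracs else 0.0


@dataclass(frozen=True)
class Classification:
    category: str
    tier: str
    n_samples: int
    n_distinct_repeat_counts: int
    edge_artifact: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category '{self.category}'")
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier '{self.tier}'")


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def group_by_locus(ssrs: Sequence[PerfectSSR]) -> list[SSRLocusGroup]:
    """Group one locus's SSRs (all samples) by interval overlap + rotation.

    Non-equivalent motifs occupying the same columns form separate groups.
    """
    if not ssrs:
        return []
    locus_ids = {s.locus_id for s in ssrs}
    if len(locus_ids) > 1:
        raise ValueError(f"group_by_locus expects one locus, got {sorted(locus_ids)}")

    items = sorted(ssrs, key=lambda s: (s.aln_start, s.aln_end))
    uf = _UnionFind(len(items))
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if items[j].aln_start > items[i].aln_end:
                break
            if canonical_rotation(items[i].motif) == canonical_rotation(items[j].motif):
                uf.union(i, j)

    clusters: dict[int, list[PerfectSSR]] = defaultdict(list)
    for i, ssr in enumerate(items):
        clusters[uf.find(i)].append(ssr)

    groups = []
    for members in clusters.values():
        samples = [m.sample_id for m in members]
        groups.append(
            SSRLocusGroup(
                locus_id=members[0].locus_id,
                aln_start=min(m.aln_start for m in members),
                aln_end=max(m.aln_end for m in members),
                motif_key=canonical_rotation(members[0].motif),
                members=tuple(
                    GroupMember(
                        m.sample_id, m.motif, m.repeats, m.truncated, m.aln_start, m.aln_end
                    )
                    for m in members
                ),
                multi_hit=len(samples) != len(set(samples)),
            )
        )
    groups.sort(key=lambda g: (g.aln_start, g.motif_key))
    return groups


def group_dataset(ssrs: Sequence[PerfectSSR]) -> list[SSRLocusGroup]:
    """Group SSRs locus by locus over a whole dataset."""
    by_locus: dict[str, list[PerfectSSR]] = defaultdict(list)
    for s in ssrs:
        by_locus[s.locus_id].append(s)
    out: list[SSRLocusGroup] = []
    for locus_id in sorted(by_locus, key=_locus_sort_key):
        out.extend(group_by_locus(by_locus[locus_id]))
    return out


def _locus_sort_key(locus_id: str):
    digits = "".join(ch for ch in locus_id if ch.isdigit())
    return (int(digits) if digits else 0, locus_id)


def _narrowest_rank(samples: Iterable[str], taxonomy: TaxonTable) -> str:
    samples = list(samples)
    species = {taxonomy.species_of(s) for s in samples}
    if len(species) == 1:
        return "within_species"
    genera = {taxonomy.genus_of(s) for s in samples}
    if len(genera) == 1:
        return "within_genus"
    return "across_genera"


def classify_group(group: SSRLocusGroup, taxonomy: TaxonTable) -> Classification:
    """Category and taxonomic tier of one locus group."""
    for m in group.members:
        if m.sample_id not in taxonomy:
            raise KeyError(f"sample '{m.sample_id}' missing from taxonomy")

    repeat_counts = {m.repeats for m in group.members}
    n_samples = group.n_samples

    if n_samples == 1:
        return Classification("unique", "not_applicable", 1, len(repeat_counts))

    if len(repeat_counts) == 1:
        tier = _narrowest_rank((m.sample_id for m in group.members), taxonomy)
        return Classification("shared", tier, n_samples, 1)

    # polymorphic: narrowest rank containing >= 2 members with differing counts
    tier = "across_genera"
    by_species: dict[str, set[int]] = defaultdict(set)
    by_genus: dict[str, set[int]] = defaultdict(set)
    for m in group.members:
        by_species[taxonomy.species_of(m.sample_id)].add(m.repeats)
        by_genus[taxonomy.genus_of(m.sample_id)].add(m.repeats)
    if any(len(c) > 1 for c in by_species.values()):
        tier = "within_species"
    elif any(len(c) > 1 for c in by_genus.values()):
        tier = "within_genus"

    non_truncated_counts = {m.repeats for m in group.members if not m.truncated}
    edge_artifact = (
        any(m.truncated for m in group.members) and len(non_truncated_counts) <= 1
    )
    return Classification(
        "polymorphic", tier, n_samples, len(repeat_counts), edge_artifact
    )


def classify_dataset(
    groups: Sequence[SSRLocusGroup], taxonomy: TaxonTable
) -> list[tuple[SSRLocusGroup, Classification]]:
    return [(g, classify_group(g, taxonomy)) for g in groups]


def classification_report(
    classified: Sequence[tuple[SSRLocusGroup, Classification]],
) -> dict[str, pd.DataFrame]:
    """Tallies of SSRs, groups (loci) and samples per category/tier/class.

    SSR-level counts over the three categories always sum to the total
    number of member SSRs (the categories partition the dataset).
    """
    rows = []
    for group, cls in classified:
        rows.append(
            {
                "category": cls.category,
                "tier": cls.tier,
                "motif_class": group.motif_class,
                "locus_id": group.locus_id,
                "n_ssrs": len(group.members),
                "samples": {m.sample_id for m in group.members},
            }
        )
    frame = pd.DataFrame(rows)

    def tally(by: list[str]) -> pd.DataFrame:
        if frame.empty:
            return pd.DataFrame(columns=by + ["n_ssrs", "n_groups", "n_loci", "n_samples"])
        grouped = frame.groupby(by, sort=True)
        out = grouped.agg(
            n_ssrs=("n_ssrs", "sum"),
            n_groups=("n_ssrs", "size"),
            n_loci=("locus_id", "nunique"),
        ).reset_index()
        out["n_samples"] = [
            len(set().union(*sub["samples"]))
            for _, sub in grouped
        ]
        return out

    return {
        "by_category": tally(["category"]),
        "by_category_tier": tally(["category", "tier"]),
        "by_category_class": tally(["category", "motif_class"]),
    }


def write_groups_table(
    classified: Sequence[tuple[SSRLocusGroup, Classification]],
    path: str | Path,
) -> None:
    """One row per group: interval, members, category, tier, flags."""
    rows = []
    for group, cls in classified:
        rows.append(
            {
                "locus_id": group.locus_id,
                "aln_start": group.aln_start,
                "aln_end": group.aln_end,
                "motif_key": group.motif_key,
                "motif_class": group.motif_class,
                "category": cls.category,
                "tier": cls.tier,
                "n_samples": cls.n_samples,
                "n_distinct_repeat_counts": cls.n_distinct_repeat_counts,
                "edge_artifact": int(cls.edge_artifact),
                "multi_hit": int(group.multi_hit),
                "min_overlap_fraction": f"{group.min_overlap_fraction():.3f}",
                "members": ";".join(
                    f"{m.sample_id}:({m.motif}){m.repeats}"
                    + ("[trunc]" if m.truncated else "")
                    for m in group.members
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Whole-compound view (secondary report; components are classified above)


def group_compounds(compounds) -> list[list]:
    """Group whole compounds by locus, interval overlap and component motifs.

    Compounds group together when their component canonical-rotation motif
    sequences are identical; differing component counts form separate groups
    (motif variation across samples is reported, not folded).
    """
    by_key: dict[tuple, list] = defaultdict(list)
    for c in compounds:
        key = (c.locus_id, tuple(canonical_rotation(p.motif) for p in c.components))
        by_key[key].append(c)
    out = []
    for members in by_key.values():
        members.sort(key=lambda c: c.aln_start)
        cluster: list = []
        max_end = -1
        for c in members:
            if cluster and c.aln_start <= max_end:
                cluster.append(c)
            else:
                if cluster:
                    out.append(cluster)
                cluster = [c]
            max_end = max(max_end, c.aln_end)
        if cluster:
            out.append(cluster)
    return out


def classify_compound_group(cluster, taxonomy: TaxonTable) -> Classification:
    samples = {c.sample_id for c in cluster}
    repeat_vectors = {tuple(p.repeats for p in c.components) for c in cluster}
    if len(samples) == 1:
        return Classification("unique", "not_applicable", 1, len(repeat_vectors))
    if len(repeat_vectors) == 1:
        return Classification(
            "shared", _narrowest_rank(samples, taxonomy), len(samples), 1
        )
    truncated = [any(p.truncated for p in c.components) for c in cluster]
    non_trunc = {
        tuple(p.repeats for p in c.components)
        for c, t in zip(cluster, truncated)
        if not t
    }
    return Classification(
        "polymorphic",
        _narrowest_rank(samples, taxonomy),
        len(samples),
        len(repeat_vectors),
        edge_artifact=any(truncated) and len(non_trunc) <= 1,
    )
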