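"""From a gapped alignment to unique / shared / polymorphic calls.

Builds a tiny three-sample alignment of one locus in which every sample
carries an AG repeat at the same columns, but one sample has two fewer
units (shown as gap columns, as a real alignment would).  The pipeline
strips gaps, mines each sample, groups the repeats by alignment interval
and classifies the group.
"""

from ssrscape import (
    LocusAlignment,
    TaxonTable,
    classify_group,
    degap,
    find_perfect_ssrs,
    group_by_locus,
)
from ssrscape.alignment_io import TaxonRow

flank_l, flank_r = "CCTTGACTGA", "TGACCTTGCA"
aln = LocusAlignment(
    "L1",
    (
        ("botr1", flank_l + "AG" * 8 + flank_r),
        ("botr2", flank_l + "AG" * 8 + flank_r),
        ("scep1", flank_l + "AG" * 6 + "----" + flank_r),  # two units fewer
    ),
)
taxonomy = TaxonTable(
    (
        TaxonRow("botr1", "B. alpha", "Botrychium"),
        TaxonRow("botr2", "B. beta", "Botrychium"),
        TaxonRow("scep1", "S. alpha", "Sceptridium"),
    )
)

ssrs = []
for sample_id, row in aln.records:
    seq = degap(row, sample_id=sample_id, locus_id=aln.locus_id)
    ssrs.extend(find_perfect_ssrs(seq))
    print(f"{sample_id}: {[s.label for s in find_perfect_ssrs(seq)]}")

(group,) = group_by_locus(ssrs)
result = classify_group(group, taxonomy)
print(
    f"group {group.motif_key} @ columns {group.aln_start}..{group.aln_end}: "
    f"{result.category} ({result.tier}), {result.n_samples} samples, "
    f"{result.n_distinct_repeat_counts} distinct repeat counts"
)
# Repeat counts 8 vs 6 across two genera -> polymorphic, across_genera.
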