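# ssrscape

Microsatellite (SSR) mining and cross-sample repeat classification for
per-locus multiple sequence alignments, built for fragmented
target-enrichment datasets: a few hundred nuclear exon (+ flanking region)
loci across a few dozen samples spanning several genera, with heavy
per-sample missing data.

## The problem

Microsatellites are tandem repeats of 1–6 bp motifs. In alignment-based
comparative datasets they are useful markers only once three questions are
answered per repeat:

1. **Is it there?** Perfect SSRs are mined per sample on *gap-stripped*
   sequences (a repeat interrupted by alignment gaps is still one repeat),
   under per-class minimum repeat counts — by default 12 for
   mononucleotides, 6 for dinucleotides, 4 for trinucleotides and 3 for
   tetra-, penta- and hexanucleotides, so every reported SSR is ≥ 12 bp.
   Two or more perfect SSRs directly adjacent, with zero interspersed
   nucleotides, form a *compound* SSR; ambiguous overlap-style
   descriptions (e.g. `(GTAT)2(GTA<T>G)(TG)12`) are re-segmented into the
   simplest adjacent runs (`(GTAT)3(GT)12`).
2. **Is it the same repeat in other samples?** An invertible degapped
   position ↔ alignment column map carries each detection back onto
   alignment coordinates; repeats from different samples that overlap in
   columns and whose motifs are cyclic rotations of each other (AAG / AGA /
   GAA) form one locus group.
3. **How does it vary?** Each group is classified as **unique** (one
   sample), **shared** (≥ 2 samples, one repeat count) or **polymorphic**
   (≥ 2 samples, differing counts), at the narrowest taxonomic tier —
   within species, within genus, or across genera. Repeats cut by fragment
   ends are flagged, and groups whose "polymorphism" vanishes once
   truncated members are ignored are marked as edge artifacts.

On top of this the package computes per-sample summary tables (class
counts, SSR density = n/bp × 1000, missing-data percentages), motif and
length distributions (optionally merging reverse-complement pairs),
primer-design templates with flank-based eligibility (Boulder-IO output
for Primer3), and — because real read data is not needed to test any of
this — a synthetic-alignment generator that plants SSRs of known category,
tier, compounding and truncation and records them in an exact truth
ledger.

## Worked example

```python
from ssrscape import find_perfect_ssrs, merge_compound

seq = "GTAT" * 3 + "GT" * 12           # 36 nt repetitive region
compounds, simples = merge_compound(find_perfect_ssrs(seq))
print(compounds[0].label)               # (GTAT)3(GT)12
print(compounds[0].components[1].repeats)  # 12
```

Running `python examples/02_alignment_to_classification.py` mines a
three-sample gapped alignment and prints

```
botr1: ['(AG)8']
botr2: ['(AG)8']
scep1: ['(AG)6']
group AG @ columns 11..26: polymorphic (across_genera), 3 samples, 2 distinct repeat counts
```

— the two-unit deficit in the *Sceptridium* sample appears as gap columns
in the alignment, survives gap stripping with correct column coordinates,
and makes the group polymorphic across genera. The other scripts under
`examples/` walk through mining, end-to-end recovery against the truth
ledger, summaries and primer eligibility; each prints what its numbers
mean.

There is also a thin CLI mirroring the stage order
(`ssrscape mine|classify|summarize|primers|simulate --config cfg.yaml`);
see `ssrscape --help`.

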