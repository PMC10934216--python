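# Methods

## Coordinates and gap handling

All coordinates are 1-based inclusive, in two frames: degapped positions
within one sample's fragment, and alignment columns shared across samples.
`degap` strips `-` characters and records, for every retained residue, its
alignment column (`colmap`); the map is strictly increasing and invertible
(`reinsert_gaps` reconstructs the row exactly). `N` is kept as a residue —
it occupies a position and a column — but terminates repeat runs in the
miner and does not count toward per-sample nucleotide totals. Leading,
trailing and internal gaps are treated identically.

Per-sample missing data is `(1 − total_bp / alignment_total_bp) × 100`,
where the baseline is the concatenated alignment length over all loci in
the dataset and a sample absent from a locus contributes 0 bp there.

## Repeat mining

A perfect SSR is a maximal run of a primitive motif (one that is not a
whole-number repetition of a shorter string) of 1–6 bp, meeting a
per-class minimum repeat count. Defaults:

| class | 1 (mono) | 2 (di) | 3 (tri) | 4 (tetra) | 5 (penta) | 6 (hexa) |
|---|---|---|---|---|---|---|
| min repeats | 12 | 6 | 4 | 3 | 3 | 3 |
| min length (bp) | 12 | 12 | 12 | 12 | 15 | 18 |

Runs are broken by `N` and sequence ends; partial trailing units are not
counted. A run is reported under its shortest-period motif, phased as it
reads at run start (a run read `GAGA…` is `(GA)n`); reverse complements
are never folded at mining or classification time.

Where qualifying runs of different motifs overlap — the situation a
repeat finder renders with shared-nucleotide notation — the union of the
overlapping runs is treated as one repetitive region and re-segmented by
dynamic programming into plain adjacent perfect runs. The objective is
lexicographic: maximize covered length, then minimize the number of runs,
then prefer the longest earliest run (reconstruction walks left to right,
taking the longest optimal piece at the earliest possible position). The
same program backs `normalize_compound`, which requires the runs to tile
the segment exactly (lossless re-segmentation) and otherwise declares the
segment a non-SSR. "Fewest components, then longest first" is this
package's formalization of choosing the *simpler* reading of an ambiguous
region; it reproduces the canonical `(GTAT)3(GT)12` case and is validated
against an exhaustive segmentation enumerator in the tests.

Compounding uses a strict zero-interruption rule: runs merge into a
compound SSR only when directly adjacent with no interspersed nucleotides
(deliberately stricter than the common 100 bp interruption default, and
part of this pipeline's definition of a compound). Components of
compounds are additionally split and counted as single SSRs in all
tallies. For exon + flank datasets, the whole alignment is mined and
detections identical to exon-only detections (same sample, locus, motif,
repeat count and position mapped into the exon frame via a per-locus exon
column interval) are subtracted to give the flanking set.

## Phase consensus and truncation

When a fragment starts or ends inside a repeat the motif's rotation is
ambiguous (AAG vs AGA vs GAA). `consensus_phase` takes the rotation
observed in the most samples whose repeat does not touch a fragment edge
(edge repeats owe their phase to missing sequence, so they do not vote;
if every member is at an edge, all vote), breaking ties to the
lexicographically smallest rotation, and relabels edge members only.
Repeat counts and coordinates never change.

Any repeat touching the first or last residue of its fragment is flagged
`truncated`. Classification carries the flag through: a group that is
polymorphic, but whose non-truncated members share a single repeat count,
is flagged `edge_artifact` — reported as polymorphic, never silently
re-categorized, so users can discount truncation-induced "polymorphism".

## Grouping and classification

Two SSRs join one locus group iff their alignment intervals overlap by at
least one column and their motifs are cyclic rotations of each other (and
hence of equal class); transitive closure defines groups, and
non-equivalent motifs at the same columns stay separate. One overlapping
column is the weakest testable version of "same locus"; the weakest
pairwise overlap fraction is emitted per group so stricter re-filtering
is possible downstream. Under transitive closure one sample can in
principle contribute two SSRs to a group (bridged by a third sample's
longer repeat); such groups keep both members and are flagged
`multi_hit` rather than silently deduplicated.

Categories partition all SSRs: unique (n_samples = 1, tier not
applicable), shared (≥ 2 samples, one distinct repeat count), polymorphic
(≥ 2 distinct counts). The tier of a shared group is the narrowest rank
— species < genus < across genera — containing all members; for a
polymorphic group, the narrowest rank containing at least two members
with differing counts. Samples identified only to genus ("sp.") are
distinct species for tier purposes. Whole compounds are also grouped and
classified in a secondary report, keyed by their ordered
canonical-rotation motif sequence; compounds with differing component
counts form separate groups there (motif variation is reported, not
folded — including the judgment call of treating e.g. an (AAGA)n vs
(AAG)n contrast as variation within a polymorphism rather than a phase
error).

## Summaries

SSR density is `(n_ssrs / sequence_bp) × 1000` (SSRs per kb), rounded
half-up to 4 decimals in tables (2-decimal views are rounded from the
same quotient); percentages round half-up to 2 decimals. Rounding is
decimal, not binary-float, so printed table values are reproducible
exactly. All distribution views (per-class, per-motif, per-length) count
compound components individually and conserve the total SSR count.
Complement-aware motif reports merge each motif with its reverse
complement under the lexicographically smaller label; merging conserves
counts and is never used for classification.

## Primer templates

Each SSR yields a template of the repeat ± `flank` bp (default 200),
clipped to fragment bounds; it is eligible for primer design when both
clipped flanks reach `min_flank` (default 50 bp — enough for a primer
plus product headroom; the threshold is configurable because no single
value is canonical). Eligibility is monotone in the threshold. Eligible
templates are emitted as Boulder-IO records (`SEQUENCE_ID`,
`SEQUENCE_TEMPLATE`, `SEQUENCE_TARGET` with 0-based start, record
terminator `=`) for any Primer3-compatible picker; thermodynamics, dimer
checks and in-silico PCR are out of scope.

## Synthetic data

The generator emulates the structure of fragmented target-enrichment
alignments: 159–2228 bp loci, samples spanning several genera with
multi-sample species, per-sample missing data as leading/trailing gap
blocks (fractions drawn per sample from a configurable range), sparse
internal gap columns, repeat-count differences realized as gap columns in
the shorter samples, deliberate edge truncations (the kept window starts
mid-repeat, on a unit boundary, leaving at least the class minimum), and
a central exon column interval so the exon-only dataset is an exact
column slice of the full one.

Background sequence is i.i.d. bases at a configurable composition,
rejection-sampled per locus until the miner — run as its own oracle over
every sample — detects exactly the planted repeats and nothing else; the
bases adjacent to each planted block are constrained not to extend the
run by one unit, which makes rejection cheap (a handful of attempts per
locus at most). This makes the truth ledger exact: recovery tests can
demand byte-exact positions, motifs and repeat counts rather than
statistical agreement. The ledger records intended and post-truncation
(observed) repeat maps, categories and tiers per planted SSR.

What passing recovery tests therefore shows: the degap/colmap path,
miner, compounding, subtraction and classifier are exact on data whose
repeats are unambiguous. What they do not show: behavior under
substitution variation between samples (backgrounds are shared),
alignment error, or realistic SSR mutation processes — none of which the
generator attempts to model.

Default plan proportions follow what fragmented flanking-region data
looks like: polymorphic groups dominate, then shared, then unique, with
di- and tetranucleotide motifs most frequent, a few compound groups
(pairs and one triple, using partner motifs verified to re-segment into
themselves when adjacent) and a few edge truncations planted on shared
repeats so the edge-artifact path is exercised.

## Problem sizes and determinism

The bundled miniature dataset is 5 samples × 10 loci (159–600 bp); the
end-to-end recovery dataset used in tests is 24 samples × 55 loci at the
full 159–2228 bp length range with 45 planted records — large enough to
cover every category × tier × compounding × truncation combination while
keeping the whole suite fast. All randomness flows from one seeded
generator per simulation; the same configuration and seed give
byte-identical FASTA output. Mining, classification and summaries are
fully deterministic.

## Known limitations

- Imperfect/interrupted SSRs and motifs longer than 6 bp are out of scope.
- The miner's resolution of overlapping candidate runs is this package's
  normative choice (validated against a brute-force enumerator), not a
  re-implementation of any particular repeat finder's undocumented
  tie-breaking.
- Exon subtraction assumes the exon-only alignment is a column slice of
  the full alignment up to a per-locus offset; independently re-aligned
  exon datasets may need their own interval table.
- The whole-compound report does not align compounds with differing
  component counts, which real data occasionally shows.
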