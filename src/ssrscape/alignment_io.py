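"""Per-locus alignment input, gap stripping, and per-sample statistics.

Coordinate conventions (used throughout the package, and by every writer):
degapped positions and alignment columns are both 1-based and inclusive.
Stripping gaps keeps an invertible column map so any repeat found on the
degapped sequence can be placed back onto alignment columns, which is what
lets repeats be compared across samples.

'N' is a residue (it occupies a degapped position) but is treated as missing
for the per-sample nucleotide totals, and it terminates repeat runs in the
miner.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

ALLOWED = frozenset("ACGTN-")
GAP = "-"
_LOCUS_RE = re.compile(r"(L\d+)")


class AlignmentError(ValueError):
    """Malformed alignment input (ragged records, bad characters, ...)."""


@dataclass(frozen=True)
class LocusAlignment:
    """One locus's aligned sequences across samples.

    records preserve input order; all sequences are upper-case and of equal
    length (``n_columns``).
    """

    locus_id: str
    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError(f"locus {self.locus_id}: no records")
        width = len(self.records[0][1])
        for sample_id, seq in self.records:
            if len(seq) != width:
                raise AlignmentError(
                    f"locus {self.locus_id}: record '{sample_id}' has length "
                    f"{len(seq)}, expected {width} (ragged alignment)"
                )
            bad = set(seq) - ALLOWED
            if bad:
                raise AlignmentError(
                    f"locus {self.locus_id}: record '{sample_id}' contains "
                    f"invalid characters {sorted(bad)}"
                )

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.records)

    def get(self, sample_id: str) -> str | None:
        for s, seq in self.records:
            if s == sample_id:
                return seq
        return None

    def slice_columns(self, start: int, end: int) -> "LocusAlignment":
        """Sub-alignment of columns start..end (1-based inclusive)."""
        if not (1 <= start <= end <= self.n_columns):
            raise ValueError(f"invalid column slice {start}..{end}")
        recs = tuple((s, seq[start - 1 : end]) for s, seq in self.records)
        return LocusAlignment(self.locus_id, recs)


@dataclass(frozen=True)
class SampleSequence:
    """A degapped sequence plus its map back to alignment columns.

    ``colmap[i-1]`` is the 1-based alignment column of the i-th residue.
    """

    sample_id: str
    locus_id: str
    residues: str
    colmap: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.colmap):
            raise ValueError("residues and colmap length mismatch")
        if any(b <= a for a, b in zip(self.colmap, self.colmap[1:])):
            raise ValueError("colmap must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @classmethod
    def from_raw(
        cls, residues: str, sample_id: str = "", locus_id: str = ""
    ) -> "SampleSequence":
        """Wrap an already-ungapped sequence with an identity column map."""
        residues = residues.upper()
        return cls(sample_id, locus_id, residues, tuple(range(1, len(residues) + 1)))


@dataclass(frozen=True)
class TaxonRow:
    sample_id: str
    species: str
    genus: str
    voucher: str = ""
    sequencing_id: str = ""


@dataclass(frozen=True)
class TaxonTable:
    """Sample-to-taxonomy mapping; sample_id unique, species/genus non-empty."""

    rows: tuple[TaxonRow, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for row in self.rows:
            if row.sample_id in seen:
                raise ValueError(f"duplicate sample_id '{row.sample_id}'")
            seen.add(row.sample_id)
            if not row.species or not row.genus:
                raise ValueError(
                    f"sample '{row.sample_id}': species and genus must be non-empty"
                )

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(r.sample_id for r in self.rows)

    def species_of(self, sample_id: str) -> str:
        return self._lookup(sample_id).species

    def genus_of(self, sample_id: str) -> str:
        return self._lookup(sample_id).genus

    def _lookup(self, sample_id: str) -> TaxonRow:
        for row in self.rows:
            if row.sample_id == sample_id:
                return row
        raise KeyError(f"sample '{sample_id}' not in taxonomy table")

    def __contains__(self, sample_id: str) -> bool:
        return any(r.sample_id == sample_id for r in self.rows)


@dataclass(frozen=True)
class SampleStats:
    sample_id: str
    total_bp: int
    alignment_total_bp: int
    missing_pct: float


def locus_id_from_path(path: str | Path) -> str:
    """Locus label parsed from the filename (pattern ``L<digits>``)."""
    m = _LOCUS_RE.search(Path(path).stem)
    if m is None:
        raise AlignmentError(
            f"cannot parse a locus id (pattern L<digits>) from '{Path(path).name}'"
        )
    return m.group(1)


def read_locus_alignments(paths: Iterable[str | Path]) -> list[LocusAlignment]:
    """Read one FASTA alignment per path; locus ids come from filenames."""
    out = []
    seen: set[str] = set()
    for path in sorted(Path(p) for p in paths):
        locus_id = locus_id_from_path(path)
        if locus_id in seen:
            raise AlignmentError(f"duplicate locus id '{locus_id}' ({path})")
        seen.add(locus_id)
        records = tuple(
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
        )
        if not records:
            raise AlignmentError(f"{path}: empty FASTA file")
        try:
            out.append(LocusAlignment(locus_id, records))
        except AlignmentError as exc:
            raise AlignmentError(f"{path}: {exc}") from exc
    return out


def read_alignment_dir(directory: str | Path, pattern: str = "*.fasta") -> list[LocusAlignment]:
    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise AlignmentError(f"no loci found under {directory} (pattern {pattern})")
    return read_locus_alignments(paths)


def degap(aligned_sequence: str, sample_id: str = "", locus_id: str = "") -> SampleSequence:
    """Strip gaps, recording each retained residue's alignment column."""
    aligned_sequence = aligned_sequence.upper()
    residues = []
    colmap = []
    for col, ch in enumerate(aligned_sequence, start=1):
        if ch == GAP:
            continue
        if ch not in ALLOWED:
            raise AlignmentError(
                f"unknown character '{ch}' at alignment column {col}"
                + (f" (sample '{sample_id}')" if sample_id else "")
            )
        residues.append(ch)
        colmap.append(col)
    return SampleSequence(sample_id, locus_id, "".join(residues), tuple(colmap))


def reinsert_gaps(seq: SampleSequence, n_columns: int) -> str:
    """Inverse of :func:`degap`: rebuild the aligned row of width n_columns."""
    row = [GAP] * n_columns
    for residue, col in zip(seq.residues, seq.colmap):
        row[col - 1] = residue
    return "".join(row)


def degap_dataset(dataset: Sequence[LocusAlignment]) -> list[SampleSequence]:
    """Degap every record of every locus (skipping all-gap rows)."""
    out = []
    for aln in dataset:
        for sample_id, seq in aln.records:
            ss = degap(seq, sample_id=sample_id, locus_id=aln.locus_id)
            if len(ss):
                out.append(ss)
    return out


def round_half_up(x: float | Decimal, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def missing_percentage(total_bp: int, alignment_total_bp: int) -> float:
    """(1 - total_bp/alignment_total_bp) x 100, half-up to 2 decimals."""
    if alignment_total_bp <= 0:
        raise ValueError("alignment_total_bp must be positive")
    pct = (
        (Decimal(alignment_total_bp) - Decimal(total_bp))
        * 100
        / Decimal(alignment_total_bp)
    )
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def sample_stats(
    dataset: Sequence[LocusAlignment], samples: Sequence[str] | None = None
) -> list[SampleStats]:
    """Per-sample nucleotide totals and missing-data percentages.

    The baseline is the concatenated alignment length over all loci; a sample
    absent from a locus contributes 0 bp there.  'N' does not count towards
    total_bp.
    """
    if not dataset:
        raise ValueError("empty dataset")
    if samples is None:
        ordered: list[str] = []
        for aln in dataset:
            for s in aln.sample_ids:
                if s not in ordered:
                    ordered.append(s)
        samples = ordered
    alignment_total = sum(aln.n_columns for aln in dataset)
    totals = dict.fromkeys(samples, 0)
    for aln in dataset:
        for sample_id, seq in aln.records:
            if sample_id in totals:
                totals[sample_id] += sum(seq.count(b) for b in "ACGT")
    return [
        SampleStats(s, totals[s], alignment_total, missing_percentage(totals[s], alignment_total))
        for s in samples
    ]


def write_stats_table(stats: Sequence[SampleStats], path: str | Path) -> None:
    import pandas as pd

    frame = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "total_bp": s.total_bp,
                "alignment_total_bp": s.alignment_total_bp,
                "missing_pct": f"{s.missing_pct:.2f}",
            }
            for s in stats
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> TaxonTable:
    """TSV with header sample_id/species/genus[/voucher/sequencing_id]."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "species", "genus"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"taxonomy table missing columns: {sorted(missing)}")
    rows = tuple(
        TaxonRow(
            sample_id=row["sample_id"],
            species=row["species"],
            genus=row["genus"],
            voucher=row.get("voucher", ""),
            sequencing_id=row.get("sequencing_id", ""),
        )
        for row in frame.to_dict("records")
    )
    return TaxonTable(rows)


def write_taxonomy(table: TaxonTable, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "species": r.species,
                "genus": r.genus,
                "voucher": r.voucher,
                "sequencing_id": r.sequencing_id,
            }
            for r in table.rows
        ]
    ).to_csv(path, sep="\t", index=False)
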