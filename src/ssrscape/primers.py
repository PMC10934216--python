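"""Primer-design template extraction and Boulder-IO emission.

For each SSR, a template of the repeat plus up to ``flank`` bp of sequence
on each side is cut from the degapped fragment.  A template is eligible for
primer design only when both clipped flanks reach a configurable minimum
(default 50 bp) — repeats at fragment ends therefore come out ineligible,
which is exactly why many repeats in fragmented target-enrichment data
cannot be turned into markers.  Primer picking itself is delegated to any
Primer3-compatible tool via Boulder-IO records; thermodynamics are out of
scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .alignment_io import SampleSequence
from .mining import CompoundSSR, PerfectSSR

DEFAULT_FLANK = 200
DEFAULT_MIN_FLANK = 50


@dataclass(frozen=True)
class PrimerTemplate:
    ssr: PerfectSSR | CompoundSSR
    template: str
    target_start: int  # 1-based position of the SSR within the template
    target_length: int
    left_flank: int
    right_flank: int
    eligible: bool
    reason: str = ""

    @property
    def sequence_id(self) -> str:
        s = self.ssr
        return f"{s.sample_id}|{s.locus_id}|{s.start}"


def extract_template(
    ssr: PerfectSSR | CompoundSSR,
    seq: SampleSequence,
    flank: int = DEFAULT_FLANK,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> PrimerTemplate:
    """Template of SSR +/- flank, clipped to fragment bounds.

    Eligibility is monotone in ``min_flank``: lowering the minimum never
    makes an eligible SSR ineligible.
    """
    n = len(seq.residues)
    if not (1 <= ssr.start <= ssr.end <= n):
        raise ValueError(f"SSR {ssr.start}..{ssr.end} outside fragment of length {n}")
    t_start = max(1, ssr.start - flank)
    t_end = min(n, ssr.end + flank)
    left = ssr.start - t_start
    right = t_end - ssr.end
    eligible = left >= min_flank and right >= min_flank
    reason = ""
    if not eligible:
        sides = [s for s, v in (("left", left), ("right", right)) if v < min_flank]
        reason = f"{'/'.join(sides)} flank < {min_flank} bp"
    return PrimerTemplate(
        ssr=ssr,
        template=seq.residues[t_start - 1 : t_end],
        target_start=left + 1,
        target_length=ssr.end - ssr.start + 1,
        left_flank=left,
        right_flank=right,
        eligible=eligible,
        reason=reason,
    )


def write_primer_input(templates: Sequence[PrimerTemplate], path: str | Path) -> None:
    """Boulder-IO records for eligible templates (KEY=value, '=' terminator).

    SEQUENCE_TARGET uses Primer3's 0-based start,length convention.
    """
    with open(path, "w") as fh:
        for t in templates:
            if not t.eligible:
                continue
            fh.write(f"SEQUENCE_ID={t.sequence_id}\n")
            fh.write(f"SEQUENCE_TEMPLATE={t.template}\n")
            fh.write(f"SEQUENCE_TARGET={t.target_start - 1},{t.target_length}\n")
            fh.write("=\n")


def parse_boulder(text: str) -> list[dict[str, str]]:
    """Parse Boulder-IO text back into a list of key->value records."""
    records: list[dict[str, str]] = []
    current: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line == "=":
            if current:
                records.append(current)
            current = {}
            continue
        if "=" not in line:
            raise ValueError(f"malformed Boulder-IO line: '{line}'")
        key, value = line.split("=", 1)
        current[key] = value
    if current:
        raise ValueError("Boulder-IO input missing final '=' record terminator")
    return records


def eligibility_report(templates: Sequence[PrimerTemplate], path: str | Path) -> None:
    rows = [
        {
            "sequence_id": t.sequence_id,
            "ssr": t.ssr.label,
            "left_flank": t.left_flank,
            "right_flank": t.right_flank,
            "eligible": int(t.eligible),
            "reason": t.reason,
        }
        for t in templates
    ]
    pd.DataFrame(
        rows,
        columns=["sequence_id", "ssr", "left_flank", "right_flank", "eligible", "reason"],
    ).to_csv(path, sep="\t", index=False)
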