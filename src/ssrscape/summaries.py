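"""Density, composition and length summaries (per sample and overall).

SSR density is the number of SSRs per kb: (n_ssrs / sequence_bp) x 1000,
rounded half-up to 4 decimals to match per-sample table precision.
Compound components are always counted individually in these tallies, so
every distribution view conserves the total SSR count.
"""

from __future__ import annotations

from collections import Counter
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .alignment_io import SampleStats
from .mining import CompoundSSR, PerfectSSR
from .motifs import complement_pair_key

ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI"}


def density(n_ssrs: int, sequence_bp: int, decimals: int = 4) -> float:
    """SSRs per kb, rounded half-up."""
    if sequence_bp <= 0:
        raise ValueError("sequence_bp must be positive")
    if n_ssrs < 0:
        raise ValueError("n_ssrs must be non-negative")
    d = Decimal(n_ssrs) * 1000 / Decimal(sequence_bp)
    return float(d.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def percentage(part: int | float, whole: int | float, decimals: int = 2) -> float:
    """part/whole as a percentage, rounded half-up."""
    if whole == 0:
        raise ValueError("whole must be non-zero")
    d = Decimal(str(part)) * 100 / Decimal(str(whole))
    return float(d.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def _as_components(ssrs: Sequence[PerfectSSR | CompoundSSR]) -> list[PerfectSSR]:
    out: list[PerfectSSR] = []
    for s in ssrs:
        if isinstance(s, CompoundSSR):
            out.extend(s.components)
        else:
            out.append(s)
    return out


def category_distribution(
    ssrs: Sequence[PerfectSSR | CompoundSSR],
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Per-sample and overall counts per motif class (I..VI).

    Returns (per-sample frame indexed by sample_id with columns I..VI,
    overall dict class -> count).  Per-sample rows sum to the overall row.
    """
    comps = _as_components(ssrs)
    per_sample: dict[str, Counter] = {}
    for s in comps:
        per_sample.setdefault(s.sample_id, Counter())[s.motif_class] += 1
    rows = {
        sample: {ROMAN[k]: counts.get(k, 0) for k in range(1, 7)}
        for sample, counts in per_sample.items()
    }
    frame = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    frame = frame.reindex(columns=[ROMAN[k] for k in range(1, 7)], fill_value=0)
    overall = Counter(s.motif_class for s in comps)
    return frame, {k: overall.get(k, 0) for k in range(1, 7)}


def motif_frequency(
    ssrs: Sequence[PerfectSSR | CompoundSSR],
    complement_aware: bool = False,
) -> pd.DataFrame:
    """Occurrences per (motif, repeats) and per motif.

    Literal mode keys by the motif as reported; complement-aware mode merges
    each motif with its reverse complement under the lexicographically
    smaller of the pair.  Merging conserves total counts.
    """
    comps = _as_components(ssrs)
    key = complement_pair_key if complement_aware else (lambda m: m)
    pair_counts = Counter((key(s.motif), s.repeats) for s in comps)
    motif_totals = Counter(key(s.motif) for s in comps)
    rows = [
        {
            "motif": m,
            "repeats": r,
            "count": c,
            "motif_total": motif_totals[m],
            "length_bp": len(m.split("/")[0]) * r,
        }
        for (m, r), c in sorted(pair_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["motif", "repeats", "count", "motif_total", "length_bp"])


def top_motifs(freq: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    return freq.sort_values(["count", "motif"], ascending=[False, True]).head(k)


def length_distribution(
    ssrs: Sequence[PerfectSSR | CompoundSSR],
) -> tuple[dict[int, int], int | None, float | None]:
    """Histogram over SSR length (bp), plus modal length and its share (%).

    Histogram counts sum to the number of (component) SSRs.
    """
    comps = _as_components(ssrs)
    hist = Counter(s.length_bp for s in comps)
    if not hist:
        return {}, None, None
    modal = max(hist, key=lambda L: (hist[L], -L))
    share = percentage(hist[modal], sum(hist.values()))
    return dict(sorted(hist.items())), modal, share


def build_sample_table(
    stats: Sequence[SampleStats],
    simples: Sequence[PerfectSSR],
    compounds: Sequence[CompoundSSR] = (),
) -> pd.DataFrame:
    """Per-sample summary: class counts, totals, compound count, density.

    One row per sample in input order plus a 'Total' footer of per-class
    sums.  ``total_simple`` counts compound components individually (they
    are also analyzed as single SSRs); ``density`` is per-kb over the
    sample's non-gap sequence length.
    """
    comps = _as_components(list(simples) + list(compounds))
    per_class: dict[str, Counter] = {}
    for s in comps:
        per_class.setdefault(s.sample_id, Counter())[s.motif_class] += 1
    n_compound = Counter(c.sample_id for c in compounds)

    rows = []
    for st in stats:
        counts = per_class.get(st.sample_id, Counter())
        total = sum(counts.values())
        rows.append(
            {
                "sample_id": st.sample_id,
                **{ROMAN[k]: counts.get(k, 0) for k in range(1, 7)},
                "total_simple": total,
                "n_compound": n_compound.get(st.sample_id, 0),
                "sequence_bp": st.total_bp,
                "density": density(total, st.total_bp) if st.total_bp else 0.0,
            }
        )
    frame = pd.DataFrame(rows)
    footer = {
        "sample_id": "Total",
        **{ROMAN[k]: int(frame[ROMAN[k]].sum()) for k in range(1, 7)},
        "total_simple": int(frame["total_simple"].sum()),
        "n_compound": int(frame["n_compound"].sum()),
        "sequence_bp": int(frame["sequence_bp"].sum()),
        "density": density(int(frame["total_simple"].sum()), int(frame["sequence_bp"].sum()))
        if frame["sequence_bp"].sum()
        else 0.0,
    }
    return pd.concat([frame, pd.DataFrame([footer])], ignore_index=True)


def combined_sample_table(
    exon_table: pd.DataFrame, flank_table: pd.DataFrame
) -> pd.DataFrame:
    """Combined-dataset view: summed counts over exon+flank sequence length."""
    merged = exon_table.set_index("sample_id").add(
        flank_table.set_index("sample_id"), fill_value=0
    )
    merged = merged.drop(columns=["density"])
    merged["density"] = [
        density(int(t), int(bp)) if bp else 0.0
        for t, bp in zip(merged["total_simple"], merged["sequence_bp"])
    ]
    return merged.reset_index()


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def plot_category_stacked(table: pd.DataFrame, path: str | Path) -> None:
    """Stacked per-sample bars of class counts (per-sample figure analog)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    body = table[table["sample_id"] != "Total"]
    ax = body.set_index("sample_id")[[ROMAN[k] for k in range(1, 7)]].plot(
        kind="bar", stacked=True, figsize=(max(6, 0.4 * len(body)), 4)
    )
    ax.set_ylabel("SSR count")
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=150)
    plt.close(ax.figure)


def plot_length_histogram(hist: Mapping[int, int], path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    lengths = sorted(hist)
    ax.bar([str(L) for L in lengths], [hist[L] for L in lengths])
    ax.set_xlabel("SSR length (bp)")
    ax.set_ylabel("occurrences")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
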