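"""End-to-end orchestration: mine -> classify -> summarize -> primers.

Each stage is a plain function over library objects; the CLI wraps these.
Stage outputs are TSV so any stage can be re-run or audited independently.
The whole pipeline is deterministic given its inputs and configuration.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import alignment_io as aio
from . import classification as cls
from . import mining
from . import normalization as norm
from . import primers as prm
from . import summaries as summ
from .simulate import (
    SimulationConfig,
    SimulationResult,
    example_taxonomy,
    simulate as _simulate,
    standard_plan,
    write_simulation,
)

log = logging.getLogger("ssrscape")


@dataclass
class PipelineConfig:
    out_dir: Path
    full_dir: Path | None = None
    exon_dir: Path | None = None
    taxonomy_path: Path | None = None
    exon_intervals_path: Path | None = None
    thresholds: mining.MotifClassThresholds = mining.DEFAULT_THRESHOLDS
    complement_aware: bool = False
    plots: bool = False
    flank: int = prm.DEFAULT_FLANK
    flank_min: int = prm.DEFAULT_MIN_FLANK
    fasta_pattern: str = "*.fasta"
    simulate: dict = field(default_factory=dict)
    seed: int | None = None


def load_config(path: str | Path, out_dir: str | Path | None = None) -> PipelineConfig:
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    base = Path(path).parent

    def _p(key):
        return (base / data[key]).resolve() if key in data and data[key] else None

    cfg = PipelineConfig(
        out_dir=Path(out_dir) if out_dir else (base / data.get("out", "ssrscape_out")),
        full_dir=_p("full"),
        exon_dir=_p("exon"),
        taxonomy_path=_p("taxonomy"),
        exon_intervals_path=_p("exon_intervals"),
        thresholds=mining.MotifClassThresholds.from_dict(
            {int(k): int(v) for k, v in data["thresholds"].items()}
        )
        if "thresholds" in data
        else mining.DEFAULT_THRESHOLDS,
        complement_aware=bool(data.get("complement_aware", False)),
        plots=bool(data.get("plots", False)),
        flank=int(data.get("flank", prm.DEFAULT_FLANK)),
        flank_min=int(data.get("flank_min", prm.DEFAULT_MIN_FLANK)),
        fasta_pattern=data.get("fasta_pattern", "*.fasta"),
        simulate=data.get("simulate", {}) or {},
        seed=data.get("seed"),
    )
    log.info("config %s (sha256 %s)", path, hashlib.sha256(raw.encode()).hexdigest()[:12])
    return cfg


@dataclass
class MinedDataset:
    """Mining products for one dataset variant (exon-only or exon+flank)."""

    alignments: list[aio.LocusAlignment]
    sequences: dict[tuple[str, str], aio.SampleSequence]  # (sample, locus)
    simples: list[mining.PerfectSSR]
    compounds: list[mining.CompoundSSR]

    @property
    def components(self) -> list[mining.PerfectSSR]:
        """All simple SSRs with compound components split out individually."""
        out = list(self.simples)
        for c in self.compounds:
            out.extend(mining.split_compound(c))
        return out


def mine_alignments(
    alignments: Sequence[aio.LocusAlignment],
    thresholds: mining.MotifClassThresholds = mining.DEFAULT_THRESHOLDS,
) -> MinedDataset:
    """Degap every record, mine perfect SSRs, flag truncations, compound."""
    sequences: dict[tuple[str, str], aio.SampleSequence] = {}
    simples: list[mining.PerfectSSR] = []
    compounds: list[mining.CompoundSSR] = []
    for aln in alignments:
        for sample_id, row in aln.records:
            seq = aio.degap(row, sample_id=sample_id, locus_id=aln.locus_id)
            if not len(seq):
                continue
            sequences[(sample_id, aln.locus_id)] = seq
            ssrs = mining.find_perfect_ssrs(seq, thresholds)
            ssrs = norm.flag_truncations(ssrs, seq)
            cc, ss = mining.merge_compound(ssrs)
            simples.extend(ss)
            compounds.extend(cc)
    return MinedDataset(list(alignments), sequences, simples, compounds)


def read_exon_intervals(path: str | Path) -> dict[str, tuple[int, int]]:
    import pandas as pd

    frame = pd.read_csv(path, sep="\t")
    return {
        str(r["locus_id"]): (int(r["exon_aln_start"]), int(r["exon_aln_end"]))
        for r in frame.to_dict("records")
    }


def _load_datasets(cfg: PipelineConfig):
    if cfg.full_dir is None:
        raise ValueError("configuration must point at a 'full' alignment directory")
    full = aio.read_alignment_dir(cfg.full_dir, cfg.fasta_pattern)
    exon = (
        aio.read_alignment_dir(cfg.exon_dir, cfg.fasta_pattern) if cfg.exon_dir else None
    )
    intervals = (
        read_exon_intervals(cfg.exon_intervals_path)
        if cfg.exon_intervals_path
        else None
    )
    return full, exon, intervals


def run_mine(cfg: PipelineConfig) -> dict[str, MinedDataset]:
    """Mine each dataset variant; write SSR tables and the flanking set."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    full_aln, exon_aln, intervals = _load_datasets(cfg)
    out: dict[str, MinedDataset] = {}
    out["full"] = mine_alignments(full_aln, cfg.thresholds)
    mining.write_ssr_table(
        out["full"].simples, out["full"].compounds, cfg.out_dir / "full_ssrs.tsv"
    )
    if exon_aln is not None:
        out["exon"] = mine_alignments(exon_aln, cfg.thresholds)
        mining.write_ssr_table(
            out["exon"].simples, out["exon"].compounds, cfg.out_dir / "exon_ssrs.tsv"
        )
        flanking = mining.subtract_exon_ssrs(
            out["full"].components, out["exon"].components, intervals
        )
        mining.write_ssr_table(flanking, [], cfg.out_dir / "flank_ssrs.tsv")
    log.info(
        "mined %d simple + %d compound SSRs over %d loci",
        len(out["full"].simples),
        len(out["full"].compounds),
        len(full_aln),
    )
    return out


def flanking_components(
    mined: Mapping[str, MinedDataset],
    intervals: Mapping[str, tuple[int, int]] | None,
) -> list[mining.PerfectSSR]:
    """Component SSRs attributed to flanking regions (exon detections removed)."""
    if "exon" in mined:
        return mining.subtract_exon_ssrs(
            mined["full"].components, mined["exon"].components, intervals
        )
    return mined["full"].components


def run_classify(cfg: PipelineConfig) -> dict:
    """Group and classify SSRs; write group table and tallies."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    if cfg.taxonomy_path is None:
        raise ValueError("classification requires a taxonomy table")
    taxonomy = aio.read_taxonomy(cfg.taxonomy_path)
    full_aln, exon_aln, intervals = _load_datasets(cfg)
    mined = {"full": mine_alignments(full_aln, cfg.thresholds)}
    if exon_aln is not None:
        mined["exon"] = mine_alignments(exon_aln, cfg.thresholds)
    components = flanking_components(mined, intervals)
    groups = cls.group_dataset(components)
    classified = cls.classify_dataset(groups, taxonomy)
    cls.write_groups_table(classified, cfg.out_dir / "groups.tsv")
    report = cls.classification_report(classified)
    for name, frame in report.items():
        frame.to_csv(cfg.out_dir / f"tally_{name}.tsv", sep="\t", index=False)
    compound_clusters = cls.group_compounds(mined["full"].compounds)
    compound_rows = [
        (cluster, cls.classify_compound_group(cluster, taxonomy))
        for cluster in compound_clusters
    ]
    _write_compound_report(compound_rows, cfg.out_dir / "compound_groups.tsv")
    return {"groups": groups, "classified": classified, "report": report}


def _write_compound_report(rows, path):
    import pandas as pd

    pd.DataFrame(
        [
            {
                "locus_id": cluster[0].locus_id,
                "motifs": cluster[0].label,
                "n_samples": c.n_samples,
                "category": c.category,
                "tier": c.tier,
                "edge_artifact": int(c.edge_artifact),
            }
            for cluster, c in rows
        ]
    ).to_csv(path, sep="\t", index=False)


def run_summarize(cfg: PipelineConfig) -> dict:
    """Per-sample summary tables, distributions, missing-data report."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    full_aln, exon_aln, intervals = _load_datasets(cfg)
    mined = {"full": mine_alignments(full_aln, cfg.thresholds)}
    datasets = {"full": full_aln}
    if exon_aln is not None:
        mined["exon"] = mine_alignments(exon_aln, cfg.thresholds)
        datasets["exon"] = exon_aln

    out = {}
    for name, aln_set in datasets.items():
        stats = aio.sample_stats(aln_set)
        aio.write_stats_table(stats, cfg.out_dir / f"{name}_missing_data.tsv")
        table = summ.build_sample_table(
            stats, mined[name].simples, mined[name].compounds
        )
        summ.write_table(table, cfg.out_dir / f"{name}_sample_summary.tsv")
        freq = summ.motif_frequency(mined[name].components, cfg.complement_aware)
        summ.write_table(freq, cfg.out_dir / f"{name}_motif_frequency.tsv")
        hist, modal, share = summ.length_distribution(mined[name].components)
        summ.write_table(
            _hist_frame(hist, modal, share), cfg.out_dir / f"{name}_length_distribution.tsv"
        )
        if cfg.plots:
            summ.plot_category_stacked(table, cfg.out_dir / f"{name}_categories.png")
            if hist:
                summ.plot_length_histogram(hist, cfg.out_dir / f"{name}_lengths.png")
        out[name] = table
    return out


def _hist_frame(hist, modal, share):
    import pandas as pd

    frame = pd.DataFrame(
        [{"length_bp": k, "count": v} for k, v in sorted(hist.items())]
    )
    frame["is_modal"] = [int(k == modal) for k in frame.get("length_bp", [])]
    if share is not None and len(frame):
        frame["modal_share_pct"] = [share if k == modal else "" for k in frame["length_bp"]]
    return frame


def run_primers(cfg: PipelineConfig) -> list[prm.PrimerTemplate]:
    """Extract primer templates; write Boulder-IO input + eligibility report."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    full_aln, _, _ = _load_datasets(cfg)
    mined = mine_alignments(full_aln, cfg.thresholds)
    templates = []
    for item in list(mined.simples) + list(mined.compounds):
        seq = mined.sequences[(item.sample_id, item.locus_id)]
        templates.append(
            prm.extract_template(item, seq, flank=cfg.flank, min_flank=cfg.flank_min)
        )
    prm.write_primer_input(templates, cfg.out_dir / "primer3_input.boulder")
    prm.eligibility_report(templates, cfg.out_dir / "primer_eligibility.tsv")
    log.info(
        "primer templates: %d eligible / %d total",
        sum(t.eligible for t in templates),
        len(templates),
    )
    return templates


def run_simulate(cfg: PipelineConfig) -> SimulationResult:
    """Generate a synthetic dataset under cfg.simulate and write it to out."""
    params = dict(cfg.simulate)
    seed = cfg.seed if cfg.seed is not None else params.pop("seed", None)
    params.pop("seed", None)
    if seed is None:
        raise ValueError("simulation requires a seed")
    n_samples = int(params.pop("n_samples", 24))
    n_loci = int(params.pop("n_loci", 40))
    with_exons = bool(params.pop("with_exons", False))
    plan_args = {
        k: int(params.pop(k))
        for k in list(params)
        if k in {"n_unique", "n_shared", "n_polymorphic", "n_compound", "n_truncated"}
    }
    taxonomy = example_taxonomy(n_samples)
    planted = standard_plan(
        taxonomy, n_loci, seed=seed, with_exons=with_exons, **plan_args
    )
    config = SimulationConfig(
        taxonomy=taxonomy,
        n_loci=n_loci,
        seed=seed,
        planted=planted,
        with_exons=with_exons,
        **{
            k: v
            for k, v in params.items()
            if k in {"locus_length_range", "missing_frac_range", "gap_rate", "exon_frac"}
        },
    )
    result = _simulate(config)
    write_simulation(result, cfg.out_dir)
    log.info(
        "simulated %d loci x %d samples (%d planted SSRs)",
        n_loci,
        n_samples,
        len(planted),
    )
    return result
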