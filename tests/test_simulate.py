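"""Synthetic-data generator: determinism, ledger consistency, recovery."""

import pytest

from ssrscape import example_taxonomy, fixture_small, simulate, standard_plan
from ssrscape.alignment_io import degap
from ssrscape.mining import find_perfect_ssrs
from ssrscape.motifs import canonical_rotation
from ssrscape.pipeline import flanking_components, mine_alignments
from ssrscape.simulate import (
    PlantedSSR,
    SimulationConfig,
    SimulationError,
    infer_category_tier,
)
from ssrscape import classification as cls


def _mini_config(**kwargs):
    taxonomy = {
        "GenusA": {"A one": ["a1", "a2"], "A two": ["a3"]},
        "GenusB": {"B one": ["b1"]},
    }
    defaults = dict(
        taxonomy=taxonomy,
        n_loci=3,
        seed=3,
        planted=[
            PlantedSSR("AG", {"a1": 6, "b1": 8}, "polymorphic", "across_genera", 0)
        ],
        locus_length_range=(159, 400),
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestSimulate:
    def test_same_seed_byte_identical(self):
        r1, r2 = simulate(_mini_config()), simulate(_mini_config())
        assert [a.records for a in r1.full] == [a.records for a in r2.full]

    def test_different_seed_differs(self):
        r1 = simulate(_mini_config())
        r2 = simulate(_mini_config(seed=4))
        assert [a.records for a in r1.full] != [a.records for a in r2.full]

    def test_planted_polymorphic_recovered(self):
        result = simulate(_mini_config())
        rec = result.ledger.records[0]
        mined = mine_alignments(result.full)
        groups = cls.group_dataset(
            [s for s in mined.components if s.locus_id == rec.locus_id]
        )
        (group,) = groups
        c = cls.classify_group(group, result.taxonomy)
        assert (c.category, c.tier) == ("polymorphic", "across_genera")

    def test_carriers_and_noncarriers(self):
        result = simulate(_mini_config())
        rec = result.ledger.records[0]
        aln = next(a for a in result.full if a.locus_id == rec.locus_id)
        for sample_id, row in aln.records:
            seq = degap(row, sample_id=sample_id, locus_id=aln.locus_id)
            found = find_perfect_ssrs(seq) if len(seq) else []
            expected = dict(rec.repeats_by_sample)
            if sample_id in expected:
                (hit,) = found
                assert (hit.motif, hit.repeats, hit.aln_start) == (
                    "AG", expected[sample_id], rec.aln_start
                )
            else:
                assert found == []

    def test_repeat_difference_realized_as_gap_columns(self):
        result = simulate(_mini_config())
        rec = result.ledger.records[0]
        aln = next(a for a in result.full if a.locus_id == rec.locus_id)
        short = dict(aln.records)["a1"]
        # a1 carries 6 of max 8 units: 4 gap columns inside the block
        block = short[rec.aln_start - 1 : rec.aln_end]
        assert block == "AG" * 6 + "-" * 4

    def test_unplaceable_ssr_raises_with_locus_name(self):
        config = _mini_config(
            planted=[
                PlantedSSR("AG", {"a1": 100, "b1": 100}, "shared", "across_genera", 1)
            ],
            locus_length_range=(159, 180),
        )
        with pytest.raises(SimulationError, match="L2"):
            simulate(config)

    def test_inconsistent_intent_rejected(self):
        config = _mini_config(
            planted=[PlantedSSR("AG", {"a1": 6, "b1": 8}, "shared", "across_genera", 0)]
        )
        with pytest.raises(SimulationError, match="inconsistent"):
            simulate(config)


class TestInferCategoryTier:
    def test_forced_by_definitions(self, small_sim):
        tax = small_sim.taxonomy
        assert infer_category_tier({"SA2": 6}, tax) == ("unique", "not_applicable")
        assert infer_category_tier({"SA2": 6, "SB1": 6}, tax) == ("shared", "across_genera")
        assert infer_category_tier({"SA1a": 6, "SA1b": 8}, tax) == (
            "polymorphic", "within_species",
        )


class TestFixtureSmall:
    def test_ledger_structure(self, small_sim):
        ledger = small_sim.ledger.to_frame()
        assert len(ledger) == 8
        assert set(ledger["category"]) == {"unique", "shared", "polymorphic"}

    def test_expected_tables_match_stored(self, small_sim, tmp_path):
        from ssrscape.mining import write_ssr_table
        from pathlib import Path

        mined = mine_alignments(small_sim.full)
        out = tmp_path / "ssrs.tsv"
        write_ssr_table(mined.simples, mined.compounds, out)
        expected = Path(__file__).parent / "data" / "fixture_small_expected_ssrs.tsv"
        assert out.read_text() == expected.read_text()

    def test_densities_recompute_from_stored_table(self, small_sim):
        import pandas as pd
        from pathlib import Path
        from ssrscape.summaries import density

        table = pd.read_csv(
            Path(__file__).parent / "data" / "fixture_small_expected_summary.tsv",
            sep="\t",
        )
        for row in table.to_dict("records"):
            if row["sequence_bp"]:
                assert row["density"] == density(
                    int(row["total_simple"]), int(row["sequence_bp"])
                )


class TestEndToEndRecovery:
    def test_every_planted_ssr_recovered_exactly(self, recovery_sim):
        """Mining recovers every planted occurrence (position, motif, repeat
        count) and nothing else; truncated occurrences appear with their cut
        repeat count at the shifted start."""
        mined = mine_alignments(recovery_sim.full)
        detected = {}
        for s in mined.components:
            detected.setdefault(
                (s.locus_id, s.aln_start, s.motif, s.repeats), []
            ).append(s)
        n_expected = 0
        for rec in recovery_sim.ledger.records:
            intended = dict(rec.repeats_by_sample)
            for sample, r in rec.observed_repeats_by_sample:
                n_expected += 1
                cut = intended[sample] - r
                a = rec.aln_start + cut * rec.motif_class
                hits = [
                    d
                    for d in detected.get((rec.locus_id, a, rec.motif, r), [])
                    if d.sample_id == sample
                ]
                assert len(hits) == 1, (rec.record_id, sample)
                if cut:
                    assert hits[0].truncated
        assert len(mined.components) == n_expected  # nothing spurious

    def test_classification_matches_ledger(self, recovery_sim):
        """Recovered groups reproduce ledger categories and tiers; truncated
        cases are flagged edge-artifact instead."""
        mined = {
            "full": mine_alignments(recovery_sim.full),
            "exon": mine_alignments(recovery_sim.exon),
        }
        components = mined["full"].components
        classified = cls.classify_dataset(
            cls.group_dataset(components), recovery_sim.taxonomy
        )
        for rec in recovery_sim.ledger.records:
            matches = [
                (g, c)
                for g, c in classified
                if g.locus_id == rec.locus_id
                and g.motif_key == canonical_rotation(rec.motif)
                and not (g.aln_end < rec.aln_start or g.aln_start > rec.aln_end)
            ]
            assert len(matches) == 1, rec.record_id
            group, c = matches[0]
            if rec.truncated_samples:
                assert c.category == rec.observed_category
                assert c.edge_artifact
            else:
                assert (c.category, c.tier) == (rec.category, rec.tier)
                assert not c.edge_artifact

    def test_exon_subtraction_leaves_planted_flank_set(self, recovery_sim):
        mined = {
            "full": mine_alignments(recovery_sim.full),
            "exon": mine_alignments(recovery_sim.exon),
        }
        flank = flanking_components(mined, recovery_sim.exon_intervals)
        n_exon_occurrences = sum(
            len(rec.observed_repeats_by_sample)
            for rec in recovery_sim.ledger.records
            if rec.in_exon
        )
        assert n_exon_occurrences > 0
        assert len(mined["exon"].components) == n_exon_occurrences
        assert len(flank) == len(mined["full"].components) - n_exon_occurrences
        flank_keys = {(s.locus_id, s.sample_id, s.motif, s.aln_start) for s in flank}
        for rec in recovery_sim.ledger.records:
            if rec.in_exon:
                for sample, _ in rec.observed_repeats_by_sample:
                    assert (rec.locus_id, sample, rec.motif, rec.aln_start) not in flank_keys

    def test_compound_components_adjacent(self, recovery_sim):
        mined = mine_alignments(recovery_sim.full)
        compound_records = [
            r for r in recovery_sim.ledger.records if r.compound_group is not None
        ]
        assert compound_records
        loci_with_compounds = {r.locus_id for r in compound_records}
        found_loci = {c.locus_id for c in mined.compounds}
        assert loci_with_compounds <= found_loci
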