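"""Cross-sample grouping and unique/shared/polymorphic classification."""

import pytest

from ssrscape.alignment_io import TaxonRow, TaxonTable
from ssrscape.classification import (
    Classification,
    classification_report,
    classify_dataset,
    classify_group,
    group_by_locus,
    group_dataset,
)
from ssrscape.mining import PerfectSSR

TAXONOMY = TaxonTable(
    (
        TaxonRow("b1", "B. alpha", "Botrychium"),
        TaxonRow("b2", "B. alpha", "Botrychium"),
        TaxonRow("b3", "B. beta", "Botrychium"),
        TaxonRow("b4", "B. gamma", "Botrychium"),
        TaxonRow("s1", "S. alpha", "Sceptridium"),
        TaxonRow("s2", "S. beta", "Sceptridium"),
    )
)


def _ssr(sample, motif, repeats, aln_start, truncated=False, locus="L1"):
    length = len(motif) * repeats
    return PerfectSSR(
        sample, locus, motif, repeats,
        start=5, end=5 + length - 1,
        aln_start=aln_start, aln_end=aln_start + length - 1,
        truncated=truncated,
    )


class TestGrouping:
    def test_different_motifs_same_interval_form_separate_groups(self):
        # (CA)9 in one genus and (TA)9 in another at the same columns
        groups = group_by_locus([_ssr("s1", "CA", 9, 100), _ssr("b1", "TA", 9, 100)])
        assert len(groups) == 2

    def test_identical_columns_many_samples_one_group(self):
        ssrs = [_ssr(f"x{i}", "AG", 6, 50) for i in range(16)]
        (group,) = group_by_locus(ssrs)
        assert group.n_samples == 16

    def test_rotations_join_one_group(self):
        groups = group_by_locus([_ssr("b1", "AAG", 5, 30), _ssr("b2", "AGA", 5, 31)])
        assert len(groups) == 1

    def test_no_overlap_separate_groups(self):
        groups = group_by_locus([_ssr("b1", "AG", 6, 10), _ssr("b2", "AG", 6, 40)])
        assert len(groups) == 2

    def test_single_column_overlap_joins(self):
        groups = group_by_locus([_ssr("b1", "AG", 6, 10), _ssr("b2", "AG", 6, 21)])
        assert len(groups) == 1
        assert groups[0].min_overlap_fraction() == pytest.approx(1 / 12)

    def test_loci_kept_separate(self):
        groups = group_dataset(
            [_ssr("b1", "AG", 6, 10, locus="L1"), _ssr("b2", "AG", 6, 10, locus="L2")]
        )
        assert len(groups) == 2

    def test_mixed_locus_input_rejected(self):
        with pytest.raises(ValueError):
            group_by_locus(
                [_ssr("b1", "AG", 6, 10, locus="L1"), _ssr("b2", "AG", 6, 10, locus="L2")]
            )


class TestClassify:
    def _classify(self, ssrs):
        (group,) = group_by_locus(ssrs)
        return classify_group(group, TAXONOMY)

    def test_single_sample_unique(self):
        c = self._classify([_ssr("b1", "AG", 6, 10)])
        assert (c.category, c.tier) == ("unique", "not_applicable")

    def test_shared_within_genus(self):
        c = self._classify([_ssr(s, "AG", 6, 10) for s in ("b1", "b3", "b4")])
        assert (c.category, c.tier) == ("shared", "within_genus")

    def test_shared_within_species_and_across_genera(self):
        c = self._classify([_ssr("b1", "AG", 6, 10), _ssr("b2", "AG", 6, 10)])
        assert (c.category, c.tier) == ("shared", "within_species")
        c = self._classify([_ssr("b1", "AG", 6, 10), _ssr("s1", "AG", 6, 10)])
        assert (c.category, c.tier) == ("shared", "across_genera")

    def test_polymorphic_across_genera(self):
        c = self._classify([_ssr("b1", "AG", 6, 10), _ssr("s1", "AG", 8, 10)])
        assert (c.category, c.tier) == ("polymorphic", "across_genera")
        assert not c.edge_artifact

    def test_polymorphic_tier_is_narrowest_differing_pair(self):
        # two same-species samples differ: within_species even though a third
        # genus is present with yet another count
        c = self._classify(
            [_ssr("b1", "AG", 6, 10), _ssr("b2", "AG", 8, 10), _ssr("s1", "AG", 9, 10)]
        )
        assert (c.category, c.tier) == ("polymorphic", "within_species")

    def test_truncation_only_difference_flagged_edge_artifact(self):
        c = self._classify(
            [_ssr("b1", "AG", 8, 10), _ssr("b2", "AG", 6, 14, truncated=True)]
        )
        assert (c.category, c.tier) == ("polymorphic", "within_species")
        assert c.edge_artifact

    def test_genuine_polymorphism_not_flagged(self):
        c = self._classify(
            [_ssr("b1", "AG", 8, 10), _ssr("b3", "AG", 6, 10), _ssr("b4", "AG", 7, 10, truncated=True)]
        )
        assert c.category == "polymorphic"
        assert not c.edge_artifact

    def test_missing_taxonomy_sample_rejected(self):
        with pytest.raises(KeyError, match="zz"):
            self._classify([_ssr("zz", "AG", 6, 10)])

    def test_invariant_under_sample_order_and_rotation(self):
        base = [_ssr("b1", "AAG", 5, 10), _ssr("s1", "AAG", 7, 10)]
        rotated = [_ssr("s1", "AGA", 7, 10), _ssr("b1", "GAA", 5, 10)]
        assert self._classify(base) == self._classify(rotated)


class TestReport:
    def test_single_unique_tally(self):
        classified = classify_dataset(group_by_locus([_ssr("b1", "AG", 6, 10)]), TAXONOMY)
        report = classification_report(classified)
        by_cat = report["by_category"].set_index("category")
        assert by_cat.loc["unique", "n_ssrs"] == 1

    def test_categories_partition_total(self):
        ssrs = (
            [_ssr("b1", "AG", 6, 10)]
            + [_ssr(s, "TC", 7, 50) for s in ("b1", "b3")]
            + [_ssr("b1", "GAT", 4, 90), _ssr("s1", "GAT", 6, 90)]
        )
        classified = classify_dataset(group_by_locus(ssrs), TAXONOMY)
        report = classification_report(classified)
        assert report["by_category"]["n_ssrs"].sum() == len(ssrs)
        assert set(report["by_category"]["category"]) == {"unique", "shared", "polymorphic"}

    def test_class_tally_conserves_counts(self):
        ssrs = [_ssr("b1", "AG", 6, 10), _ssr("b1", "GAT", 4, 60), _ssr("s1", "GAT", 4, 60)]
        classified = classify_dataset(group_by_locus(ssrs), TAXONOMY)
        report = classification_report(classified)
        assert report["by_category_class"]["n_ssrs"].sum() == 3


def test_classification_invariants_enforced():
    with pytest.raises(ValueError):
        Classification("sometimes", "within_genus", 2, 1)
    with pytest.raises(ValueError):
        Classification("shared", "nearby", 2, 1)
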