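"""Perfect-SSR mining, compound merging and exon subtraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssrscape.alignment_io import degap
from ssrscape.mining import (
    DEFAULT_THRESHOLDS,
    CompoundSSR,
    MiningError,
    MotifClassThresholds,
    PerfectSSR,
    find_perfect_ssrs,
    merge_compound,
    read_ssr_table,
    split_compound,
    subtract_exon_ssrs,
    write_ssr_table,
)

from oracles import brute_force_ssrs

MIN_LEN = {1: 12, 2: 12, 3: 12, 4: 12, 5: 15, 6: 18}


def _runs(seq, thresholds=DEFAULT_THRESHOLDS):
    return [(s.start, s.motif, s.repeats) for s in find_perfect_ssrs(seq, thresholds)]


class TestFindPerfect:
    def test_mono_below_threshold_excluded(self):
        assert _runs("T" * 10) == []
        assert _runs("T" * 11) == []
        assert _runs("T" * 12) == [(1, "T", 12)]

    def test_dinucleotide_in_flanks(self):
        seq = "CCTTAAC" + "AG" * 6 + "TTCCATG"
        (hit,) = find_perfect_ssrs(seq)
        assert (hit.motif, hit.repeats, hit.length_bp) == ("AG", 6, 12)
        assert not hit.at_edge

    def test_primitive_motif_rule(self):
        # a (AGAG)n description of an AG run must never be produced
        assert _runs("AGAGAGAGAGAG") == [(1, "AG", 6)]

    def test_partial_trailing_unit_not_counted(self):
        seq = "CCG" + "GAT" * 4 + "GA" + "CCT"
        (hit,) = find_perfect_ssrs(seq)
        assert (hit.motif, hit.repeats) == ("GAT", 4)

    def test_n_breaks_runs(self):
        assert _runs("AG" * 3 + "N" + "AG" * 3) == []
        assert _runs("AG" * 6 + "N" + "AG" * 6) == [(1, "AG", 6), (14, "AG", 6)]

    def test_empty_sequence(self):
        assert find_perfect_ssrs("") == []

    def test_alignment_coordinates_follow_colmap(self):
        seq = degap("--AG-AGAGAG--AGAG--", sample_id="s", locus_id="L1")
        (hit,) = find_perfect_ssrs(seq)
        assert (hit.start, hit.end) == (1, 12)
        assert (hit.aln_start, hit.aln_end) == (3, 17)

    def test_at_edge_flags(self):
        left = find_perfect_ssrs("AG" * 6 + "CCTTCAT")[0]
        right = find_perfect_ssrs("CCTTCAT" + "AG" * 6)[0]
        assert left.at_edge and right.at_edge

    def test_overlap_resolved_to_adjacent_runs(self):
        # the shared-nucleotide situation: GTAT x3 then GT x12
        assert _runs("GTAT" * 3 + "GT" * 12) == [(1, "GTAT", 3), (13, "GT", 12)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            n = int(rng.integers(50, 800))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            mined = [(s.start - 1, s.motif, s.repeats) for s in find_perfect_ssrs(seq)]
            assert sorted(mined) == brute_force_ssrs(seq)

    def test_matches_brute_force_on_repeat_dense_sequences(self):
        rng = np.random.default_rng(99)
        motifs = ["A", "AG", "GA", "AAG", "GTAT", "GT", "TTTG"]
        for _ in range(60):
            parts = []
            for _ in range(int(rng.integers(2, 6))):
                m = motifs[int(rng.integers(0, len(motifs)))]
                r = int(rng.integers(2, 15))
                parts.append(m * r)
                parts.append("".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 6)))))
            seq = "".join(parts)
            mined = [(s.start - 1, s.motif, s.repeats) for s in find_perfect_ssrs(seq)]
            assert sorted(mined) == brute_force_ssrs(seq)


class TestProperties:
    @settings(max_examples=150, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=400))
    def test_maximality_no_overlap_min_length(self, seq):
        ssrs = find_perfect_ssrs(seq)
        for a, b in zip(ssrs, ssrs[1:]):
            assert b.start > a.end  # never overlapping
        for s in ssrs:
            assert s.length_bp >= MIN_LEN[s.motif_class]
            assert seq[s.start - 1 : s.end] == s.motif * s.repeats
            # not extendable by one motif copy on either side
            left = seq[s.start - 1 - s.motif_class : s.start - 1]
            right = seq[s.end : s.end + s.motif_class]
            assert left != s.motif
            assert right != s.motif


class TestThresholds:
    def test_defaults(self):
        assert DEFAULT_THRESHOLDS.as_dict() == {1: 12, 2: 6, 3: 4, 4: 3, 5: 3, 6: 3}

    def test_validation(self):
        with pytest.raises(ValueError):
            MotifClassThresholds.from_dict({1: 12, 2: 6})
        with pytest.raises(ValueError):
            MotifClassThresholds.from_dict({1: 12, 2: 6, 3: 4, 4: 3, 5: 3, 6: 1})

    def test_custom_thresholds_change_detection(self):
        loose = MotifClassThresholds.from_dict({1: 10, 2: 6, 3: 4, 4: 3, 5: 3, 6: 3})
        assert _runs("T" * 10, loose) == [(1, "T", 10)]


def _ssr(motif, repeats, start, sample="s", locus="L1"):
    end = start + len(motif) * repeats - 1
    return PerfectSSR(sample, locus, motif, repeats, start, end, start, end)


class TestCompound:
    def test_adjacent_merge(self):
        ssrs = find_perfect_ssrs("GTAT" * 3 + "GT" * 12)
        compounds, simples = merge_compound(ssrs)
        assert simples == []
        (c,) = compounds
        assert c.label == "(GTAT)3(GT)12"
        assert c.total_length_bp == 36

    def test_one_nt_interruption_stays_simple(self):
        ssrs = [_ssr("AG", 6, 1), _ssr("GT", 6, 14)]
        compounds, simples = merge_compound(ssrs)
        assert compounds == [] and len(simples) == 2

    def test_three_component_chain(self):
        ssrs = [_ssr("AAG", 4, 1), _ssr("TG", 7, 13), _ssr("CT", 6, 27)]
        compounds, simples = merge_compound(ssrs)
        (c,) = compounds
        assert len(c.components) == 3 and simples == []

    def test_overlapping_input_rejected(self):
        with pytest.raises(MiningError):
            merge_compound([_ssr("AG", 6, 1), _ssr("GT", 6, 10)])

    def test_split_returns_components(self):
        c = CompoundSSR((_ssr("GTAT", 3, 1), _ssr("GT", 12, 13)))
        parts = split_compound(c)
        assert [p.label for p in parts] == ["(GTAT)3", "(GT)12"]

    def test_every_input_in_exactly_one_output(self):
        ssrs = [_ssr("AG", 6, 1), _ssr("GT", 6, 13), _ssr("A", 12, 40), _ssr("TC", 8, 60)]
        compounds, simples = merge_compound(ssrs)
        out = list(simples)
        for c in compounds:
            out.extend(c.components)
        assert sorted(s.start for s in out) == [1, 13, 40, 60]


class TestExonSubtraction:
    def test_identical_lists_cancel(self):
        full = [_ssr("AG", 6, 5)]
        assert subtract_exon_ssrs(full, full) == []

    def test_partial_subtraction(self):
        full = [_ssr("AG", 6, i) for i in (1, 20, 40, 60, 80)]
        exon = [full[1], full[3]]
        assert subtract_exon_ssrs(full, exon) == [full[0], full[2], full[4]]

    def test_offset_mapping(self):
        # exon occupies full-alignment columns 101..200
        full_hit = _ssr("AG", 6, 120)
        exon_hit = _ssr("AG", 6, 20)
        out = subtract_exon_ssrs([full_hit], [exon_hit], {"L1": (101, 200)})
        assert out == []
        # same repeat at a different position survives
        out = subtract_exon_ssrs([_ssr("AG", 6, 130)], [exon_hit], {"L1": (101, 200)})
        assert len(out) == 1


def test_ssr_table_roundtrip(tmp_path):
    ssrs = find_perfect_ssrs("CCTTAAC" + "AG" * 6 + "TTCCATG" + "GTAT" * 3 + "GT" * 12)
    compounds, simples = merge_compound(
        [s.__class__(**{**s.__dict__, "sample_id": "s1", "locus_id": "L3"}) for s in ssrs]
    )
    path = tmp_path / "ssrs.tsv"
    write_ssr_table(simples, compounds, path)
    rs, rc = read_ssr_table(path)
    assert [(s.motif, s.repeats, s.start, s.end) for s in rs] == [
        (s.motif, s.repeats, s.start, s.end) for s in simples
    ]
    assert [c.label for c in rc] == [c.label for c in compounds]
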