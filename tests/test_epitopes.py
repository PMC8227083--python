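"""Propensity panel, consensus voting, and the packaged epitope fixtures."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ltp_epimap.epitopes import (
    DEFAULT_SCALES,
    SCALE_REGISTRY,
    consensus_regions,
    default_min_votes,
    load_reported_epitopes,
    panel_profiles,
    scale_profile,
    vote_counts,
)
from ltp_epimap.residues import AMINO_ACIDS

sequences = st.text(alphabet=AMINO_ACIDS, min_size=7, max_size=60)


class TestScaleProfile:
    def test_registry_covers_all_residues(self):
        for name, spec in SCALE_REGISTRY.items():
            assert set(spec["values"]) == set(AMINO_ACIDS), name

    def test_homopolymer_gives_no_calls(self):
        profile = scale_profile("A" * 20, "parker_hydrophilicity")
        assert all(r == pytest.approx(2.1) for r in profile.raw)
        assert all(z == 0.0 for z in profile.z)
        assert not any(profile.calls)

    def test_window_one_returns_per_residue_values(self):
        seq = "ACDEFG"
        profile = scale_profile(seq, "parker_hydrophilicity", window=1)
        values = SCALE_REGISTRY["parker_hydrophilicity"]["values"]
        assert profile.raw == tuple(values[ch] for ch in seq)

    def test_windowed_mean_truncated_at_termini(self):
        values = SCALE_REGISTRY["parker_hydrophilicity"]["values"]
        seq = "ACDEFGH"
        profile = scale_profile(seq, "parker_hydrophilicity", window=5)
        # first position: window truncates to positions 1..3
        expected = np.mean([values[ch] for ch in seq[:3]])
        assert profile.raw[0] == pytest.approx(expected)
        # central position: full 5-wide window
        expected_mid = np.mean([values[ch] for ch in seq[1:6]])
        assert profile.raw[3] == pytest.approx(expected_mid)

    def test_kolaskar_uses_absolute_rule(self):
        # VCVCVCVCVC: all propensities > 1 -> every residue called even
        # though z-scores straddle zero
        profile = scale_profile("VCVCVCVCVC", "kolaskar_tongaonkar_antigenicity")
        assert all(profile.calls)

    def test_emini_product_form(self):
        spec = SCALE_REGISTRY["emini_accessibility"]
        seq = "KKKKK"
        profile = scale_profile(seq, "emini_accessibility", window=5)
        expected = (spec["values"]["K"] / spec["normalizer"]) ** 5
        assert profile.raw[2] == pytest.approx(expected)

    def test_adversarial_scale_concentrates_calls_on_dominant_runs(self):
        # with hydrophilicity, a D/E-rich run inside a hydrophobic context
        # must collect the calls; brute-force expectation: call <=> windowed
        # mean z-score > 0
        seq = "ILILILILIL" + "DEDEDEDEDE" + "LILILILILI"
        profile = scale_profile(seq, "parker_hydrophilicity")
        called = {i for i, c in enumerate(profile.calls) if c}
        assert called and called <= set(range(7, 23))

    def test_errors(self):
        with pytest.raises(KeyError):
            scale_profile("ACDE", "nope")
        with pytest.raises(ValueError, match="odd"):
            scale_profile("ACDEFGH", "parker_hydrophilicity", window=4)
        with pytest.raises(ValueError, match="exceeds"):
            scale_profile("ACD", "parker_hydrophilicity", window=7)


class TestConsensus:
    def make_profiles(self, calls_matrix):
        from ltp_epimap.epitopes import PropensityProfile

        return [
            PropensityProfile(
                scale=f"s{i}",
                window=7,
                raw=tuple(0.0 for _ in row),
                z=tuple(0.0 for _ in row),
                calls=tuple(row),
            )
            for i, row in enumerate(calls_matrix)
        ]

    def test_five_of_eight_retained_four_dropped(self):
        length = 12
        # residues 0..5 called by 5 profiles, residues 6..11 by 4
        rows = []
        for i in range(8):
            calls = [i < 5] * 6 + [i < 4] * 6
            rows.append(calls)
        profiles = self.make_profiles(rows)
        regions = consensus_regions("A" * length, profiles, min_votes=5, min_region_length=6)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (1, 6)
        assert regions[0].votes == 5

    def test_short_runs_dropped(self):
        rows = [[True] * 5 + [False] * 7] * 5
        profiles = self.make_profiles(rows)
        assert consensus_regions("A" * 12, profiles, min_votes=5, min_region_length=6) == []
        kept = consensus_regions("A" * 12, profiles, min_votes=5, min_region_length=5)
        assert len(kept) == 1

    def test_default_min_votes_rescales_five_of_eight(self):
        assert default_min_votes(8) == 5
        assert default_min_votes(7) == 5
        assert default_min_votes(16) == 10

    def test_votes_monotone_in_added_predictor(self):
        # adding a predictor never removes a consensus residue at fixed min_votes
        rng = np.random.default_rng(0)
        length = 40
        base = [list(rng.random(length) < 0.5) for _ in range(6)]
        extra = list(rng.random(length) < 0.5)
        seq = "A" * length
        before = vote_counts(seq, self.make_profiles(base))
        after = vote_counts(seq, self.make_profiles(base + [extra]))
        assert np.all(after >= before)
        kept_before = set(np.flatnonzero(before >= 4))
        kept_after = set(np.flatnonzero(after >= 4))
        assert kept_before <= kept_after

    def test_min_votes_one_is_union_of_calls(self):
        rng = np.random.default_rng(3)
        length = 30
        rows = [list(rng.random(length) < 0.3) for _ in range(4)]
        profiles = self.make_profiles(rows)
        regions = consensus_regions("A" * length, profiles, min_votes=1, min_region_length=1)
        union = np.any(rows, axis=0)
        covered = np.zeros(length, dtype=bool)
        for region in regions:
            covered[region.start - 1 : region.end] = True
        assert np.array_equal(covered, union)

    def test_mismatched_lengths_error(self):
        profiles = self.make_profiles([[True] * 5])
        with pytest.raises(ValueError, match="do not match"):
            consensus_regions("A" * 6, profiles)

    @given(sequences)
    def test_regions_disjoint_sorted_in_bounds(self, seq):
        profiles = panel_profiles(seq, DEFAULT_SCALES, window=7)
        regions = consensus_regions(seq, profiles, min_region_length=3)
        previous_end = 0
        for region in regions:
            assert region.start > previous_end
            assert 1 <= region.start <= region.end <= len(seq)
            assert region.sequence == seq[region.start - 1 : region.end]
            previous_end = region.end


class TestReportedEpitopeFixtures:
    def test_chickpea_region_two(self):
        chick = [r for r in load_reported_epitopes("table2") if r.parent_id == "chickpea"]
        region = chick[1]
        assert (region.start, region.end) == (56, 70)
        assert region.sequence == "RNLNSAAVTTPDRQA"
        assert len(region) == 15

    def test_soybean_has_five_regions(self):
        soy = [r for r in load_reported_epitopes("table2") if r.parent_id == "soybean"]
        assert len(soy) == 5

    def test_counts_per_query(self, table2_by_parent):
        counts = {k: len(v) for k, v in table2_by_parent.items()}
        assert counts == {
            "chickpea": 3,
            "mung_bean": 3,
            "cowpea": 5,
            "pigeon_pea": 4,
            "soybean": 5,
        }

    def test_validated_peach_epitope_three(self, validated_peach):
        third = validated_peach[2]
        assert (third.start, third.end) == (71, 80)
        assert third.sequence == "GKCGVSIPYK"
        assert len(third) == third.end - third.start + 1

    def test_validated_epitope_two_discrepancy_recorded(self, validated_peach):
        second = validated_peach[1]
        assert len(second.sequence) == 16
        assert second.end - second.start + 1 == 15
        assert second.note  # discrepancy must be recorded, not silently fixed

    def test_coordinate_mismatch_without_note_errors(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "parent_id\tepitope_index\tstart\tend\tsequence\tkind\tnote\n"
            "x\t1\t5\t10\tACDE\tlinear\t\n"
        )
        with pytest.raises(ValueError, match="no\\s+note"):
            load_reported_epitopes(path)

    def test_all_table2_rows_consistent(self, table2_by_parent):
        for regions in table2_by_parent.values():
            for region in regions:
                assert len(region.sequence) == region.end - region.start + 1
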