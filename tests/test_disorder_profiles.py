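"""Unit and property tests for the per-protein disorder computations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idphub.disorder_profiles import (
    ConsensusParams,
    DisorderClass,
    IDRInterval,
    binarize_track,
    classify_disorder,
    consensus_mask,
    disorder_ratio,
    extract_idrs,
    mean_disorder_score,
    summarize_protein,
)

from conftest import brute_force_idrs, make_mask, make_track


class TestBinarize:
    def test_threshold_is_inclusive(self):
        mask = binarize_track(make_track([0.50, 0.49, 0.90]))
        assert mask.states.tolist() == [True, False, True]

    def test_all_zero_scores_are_ordered(self):
        assert not binarize_track(make_track([0.0] * 10)).states.any()

    def test_matches_elementwise_oracle_on_random_scores(self):
        rng = np.random.default_rng(0)
        scores = rng.random(1000)
        mask = binarize_track(make_track(scores))
        expected = [s >= 0.5 for s in scores]  # independent elementwise check
        assert mask.states.tolist() == expected

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            make_track([])


class TestRatioAndMean:
    @pytest.mark.parametrize(
        "states, expected",
        [([True] * 5, 1.0), ([False] * 4, 0.0), ([True] * 30 + [False] * 70, 0.30)],
    )
    def test_disorder_ratio(self, states, expected):
        assert disorder_ratio(make_mask(states)) == pytest.approx(expected)

    def test_ratio_invariant_under_reversal(self):
        rng = np.random.default_rng(1)
        states = rng.random(500) < 0.4
        assert disorder_ratio(make_mask(states)) == disorder_ratio(make_mask(states[::-1]))

    @pytest.mark.parametrize("scores, expected", [([0.7] * 9, 0.7), ([0.0, 1.0], 0.5)])
    def test_mean_score(self, scores, expected):
        assert mean_disorder_score(make_track(scores)) == pytest.approx(expected)

    def test_mean_matches_naive_summation(self):
        rng = np.random.default_rng(2)
        scores = rng.random(500)
        naive = sum(float(s) for s in scores) / len(scores)
        assert mean_disorder_score(make_track(scores)) == pytest.approx(naive, abs=1e-12)


class TestExtractIdrs:
    def test_run_of_29_is_excluded(self):
        assert extract_idrs(make_mask([True] * 29)) == []

    def test_single_run_coordinates_are_one_based_inclusive(self):
        states = np.zeros(60, dtype=bool)
        states[10:40] = True  # residues 11..40
        assert extract_idrs(make_mask(states)) == [IDRInterval(11, 40)]

    def test_two_runs_split_by_single_ordered_residue(self):
        states = [True] * 30 + [False] + [True] * 35
        result = extract_idrs(make_mask(states))
        assert result == [IDRInterval(1, 30), IDRInterval(32, 66)]

    @settings(max_examples=300, derandomize=True)
    @given(st.data())
    def test_equals_brute_force_scanner(self, data):
        n = data.draw(st.integers(1, 400))
        density = data.draw(st.floats(0.05, 0.95))
        seed = data.draw(st.integers(0, 2**31 - 1))
        states = np.random.default_rng(seed).random(n) < density
        min_window = data.draw(st.sampled_from([1, 5, 30]))
        got = [(iv.start, iv.end) for iv in extract_idrs(make_mask(states), min_window)]
        assert got == brute_force_idrs(states, min_window)

    @settings(max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_intervals_are_maximal_runs(self, seed):
        rng = np.random.default_rng(seed)
        states = rng.random(300) < 0.5
        for iv in extract_idrs(make_mask(states), min_window=5):
            assert states[iv.start - 1 : iv.end].all()
            assert iv.start == 1 or not states[iv.start - 2]
            assert iv.end == len(states) or not states[iv.end]

    def test_commutes_with_reversal_up_to_mirroring(self):
        rng = np.random.default_rng(3)
        states = rng.random(500) < 0.6
        n = len(states)
        fwd = extract_idrs(make_mask(states), min_window=10)
        rev = extract_idrs(make_mask(states[::-1]), min_window=10)
        mirrored = sorted(IDRInterval(n - iv.end + 1, n - iv.start + 1) for iv in rev)
        assert fwd == mirrored


class TestConsensus:
    def test_unanimous_long_run_is_preserved(self):
        states = np.zeros(100, dtype=bool)
        states[0:40] = True  # run touching the N-terminus
        states[60:95] = True
        masks = [make_mask(states, predictor_id=f"p{i}") for i in range(4)]
        out = consensus_mask(masks)
        assert out.states.tolist() == states.tolist()
        assert out.predictor_id == "consensus"

    def test_five_of_eight_votes_meets_default_agreement(self):
        run = np.zeros(80, dtype=bool)
        run[20:60] = True
        yes = [make_mask(run, predictor_id=f"y{i}") for i in range(5)]
        no = [make_mask(np.zeros(80, dtype=bool), predictor_id=f"n{i}") for i in range(3)]
        out = consensus_mask(yes + no)  # 5/8 = 0.625 meets the >= rule
        assert out.states[20:60].all() and out.states.sum() == 40

    def test_four_of_eight_votes_fails_default_agreement(self):
        run = np.zeros(80, dtype=bool)
        run[20:60] = True
        yes = [make_mask(run, predictor_id=f"y{i}") for i in range(4)]
        no = [make_mask(np.zeros(80, dtype=bool), predictor_id=f"n{i}") for i in range(4)]
        assert not consensus_mask(yes + no).states.any()

    def test_short_surviving_region_removed_by_min_region(self):
        states = np.zeros(60, dtype=bool)
        states[20:39] = True  # length 19 < min_region 20
        out = consensus_mask([make_mask(states)], ConsensusParams(morph_radius=0, min_region=20))
        assert not out.states.any()
        kept = consensus_mask([make_mask(states)], ConsensusParams(morph_radius=0, min_region=19))
        assert kept.states.sum() == 19

    def test_identity_with_single_mask_and_trivial_params(self):
        rng = np.random.default_rng(4)
        states = rng.random(200) < 0.5
        out = consensus_mask(
            [make_mask(states)], ConsensusParams(morph_radius=0, min_region=1)
        )
        assert out.states.tolist() == states.tolist()

    def test_length_mismatch_names_offenders(self):
        masks = [make_mask([True] * 10, predictor_id="a"), make_mask([True] * 12, predictor_id="b")]
        with pytest.raises(ValueError, match="b"):
            consensus_mask(masks)

    def test_closing_bridges_small_gaps(self):
        states = np.zeros(100, dtype=bool)
        states[10:40] = True
        states[44:80] = True  # gap of 4 < 2*radius
        out = consensus_mask([make_mask(states)], ConsensusParams(morph_radius=3, min_region=20))
        assert out.states[10:80].all()


class TestClassify:
    @pytest.mark.parametrize(
        "d, expected",
        [
            (0.0, DisorderClass.ORDERED),
            (0.05, DisorderClass.ORDERED),
            (0.1, DisorderClass.ORDERED),
            (0.11, DisorderClass.LD),
            (0.29, DisorderClass.LD),
            (0.3, DisorderClass.MD),
            (0.49, DisorderClass.MD),
            (0.5, DisorderClass.HD),
            (1.0, DisorderClass.HD),
        ],
    )
    def test_band_assignment(self, d, expected):
        assert classify_disorder(d) is expected

    def test_monotone_in_d_ratio(self):
        grid = np.linspace(0, 1, 201)
        classes = [classify_disorder(float(d)) for d in grid]
        assert all(a <= b for a, b in zip(classes, classes[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_disorder(1.2)


class TestSummarize:
    def test_single_all_disordered_track(self):
        s = summarize_protein([make_track([0.9] * 40)], reference_predictor="predA")
        assert s.d_ratio == 1.0
        assert s.idr_intervals == [IDRInterval(1, 40)]
        assert s.disorder_class is DisorderClass.HD and s.is_idp

    def test_single_planted_block_yields_ld(self):
        scores = np.full(200, 0.2)
        scores[50:100] = 0.8  # one 50-residue block in 200 residues
        s = summarize_protein([make_track(scores)], reference_predictor="predA")
        assert s.d_ratio == pytest.approx(0.25)
        assert s.disorder_class is DisorderClass.LD
        assert s.idr_count == 1

    def test_track_below_threshold_everywhere_is_ordered(self):
        s = summarize_protein([make_track([0.3] * 100)], reference_predictor="predA")
        assert s.idr_count == 0 and s.disorder_class is DisorderClass.ORDERED

    def test_unknown_reference_predictor_raises(self):
        with pytest.raises(KeyError, match="nope"):
            summarize_protein([make_track([0.9] * 40)], reference_predictor="nope")

    def test_consensus_reference_uses_all_tracks(self):
        block = np.full(120, 0.1)
        block[20:80] = 0.9
        tracks = [make_track(block, predictor_id=f"p{i}") for i in range(3)]
        s = summarize_protein(tracks)  # default consensus reference
        assert s.predictor_id == "consensus"
        assert s.idr_intervals == [IDRInterval(21, 80)]
        assert s.d_ratio == pytest.approx(0.5)
        assert s.is_idp
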