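"""Signed scores, EMA smoothing, TMR segmentation and refinement filters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmrcall.caller import (
    SmoothingParams,
    Thresholds,
    call_tmrs,
    filter_mappability,
    filter_min_cpgs,
    signed_score,
    signed_scores,
    smooth_scores,
)
from tmrcall.correlation import CorrelationTrack
from tmrcall.intervals import GenomicInterval
from oracles import brute_force_smooth


class TestSignedScore:
    def test_negative_correlation_at_threshold_q(self):
        assert signed_score(0.05, -1) == pytest.approx(math.log10(0.05))

    def test_positive_correlation_q_001(self):
        assert signed_score(0.01, +1) == pytest.approx(2.0)

    def test_q_one_is_zero_either_sign(self):
        assert signed_score(1.0, -1) == 0.0
        assert signed_score(1.0, +1) == 0.0

    def test_q_outside_unit_interval_asserts(self):
        with pytest.raises(ValueError):
            signed_score(0.0, -1)
        with pytest.raises(ValueError):
            signed_scores([0.5, 1.5], [1, 1])

    def test_vectorized_matches_scalar_and_propagates_nan(self):
        q = np.array([0.05, np.nan, 0.01])
        rho = np.array([-0.5, 0.3, 0.4])
        out = signed_scores(q, rho)
        assert out[0] == pytest.approx(signed_score(0.05, -1))
        assert np.isnan(out[1])
        assert out[2] == pytest.approx(2.0)


class TestSmoothScores:
    def test_factor_zero_is_identity(self):
        s = np.array([1.0, -2.0, 3.0, np.nan, 0.5])
        out = smooth_scores(s, SmoothingParams(0.0, 10))
        np.testing.assert_allclose(out[np.isfinite(s)], s[np.isfinite(s)])
        assert np.isnan(out[3])

    def test_hand_computed_interior_window(self):
        out = smooth_scores([0.0, 1.0, 0.0], SmoothingParams(0.5, 1))
        assert out[1] == pytest.approx(0.5)

    def test_edge_window_truncated_and_renormalized(self):
        out = smooth_scores([2.0, 0.0, 0.0], SmoothingParams(0.5, 1))
        assert out[0] == pytest.approx(4.0 / 3.0)

    def test_missing_center_filled_from_neighbors(self):
        out = smooth_scores([1.0, np.nan, 3.0], SmoothingParams(0.5, 1))
        assert out[1] == pytest.approx(2.0)

    def test_all_missing_window_stays_missing(self):
        out = smooth_scores([np.nan, np.nan], SmoothingParams(0.75, 1))
        assert np.all(np.isnan(out))

    def test_window_size_is_two_nflank_plus_one(self):
        assert SmoothingParams(0.75, 5).window_size == 11
        assert SmoothingParams(0.75, 0).window_size == 1

    @pytest.mark.parametrize("factor", [0.0, 0.25, 0.75, 1.0])
    @pytest.mark.parametrize("n_flank", [0, 1, 5, 10])
    def test_matches_brute_force_oracle(self, factor, n_flank):
        rng = np.random.default_rng(17)
        for _ in range(5):
            s = rng.normal(0, 5, size=rng.integers(1, 60))
            s[rng.random(s.size) < 0.2] = np.nan
            got = smooth_scores(s, SmoothingParams(factor, n_flank))
            want = brute_force_smooth(s, factor, n_flank)
            np.testing.assert_allclose(got, want, atol=1e-12, equal_nan=True)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        scores=st.lists(
            st.one_of(st.floats(-30, 30), st.just(float("nan"))), min_size=1, max_size=40
        ),
        factor=st.floats(0, 1),
        n_flank=st.integers(0, 12),
    )
    def test_oracle_property(self, scores, factor, n_flank):
        got = smooth_scores(scores, SmoothingParams(factor, n_flank))
        want = brute_force_smooth(scores, factor, n_flank)
        np.testing.assert_allclose(got, want, atol=1e-10, equal_nan=True)


def _track(smoothed, positions=None, strand="+"):
    n = len(smoothed)
    positions = np.arange(n) * 50 + 1000 if positions is None else np.asarray(positions)
    return CorrelationTrack(
        transcript_id="T",
        chrom="chr1",
        positions=positions.astype(np.int64),
        distance_to_tss=positions.astype(np.int64) - 1000,
        rho=np.zeros(n),
        n_used=np.full(n, 50),
        p=np.full(n, 0.5),
        q=np.full(n, 0.5),
        score=np.zeros(n),
        smoothed_score=np.asarray(smoothed, dtype=float),
        strand=strand,
    )


class TestCallTmrs:
    def test_hand_scanned_negative_run(self):
        track = _track([-0.5, -1.5, -2.0, -1.4, -0.2])
        tmrs = call_tmrs(track, Thresholds())
        assert len(tmrs) == 1
        t = tmrs[0]
        assert t.direction == "negative"
        assert (t.start_index, t.end_index) == (1, 3)
        assert t.cpg_count == 3
        assert t.peak_score == pytest.approx(-2.0)
        assert (t.interval.start, t.interval.end) == (1050, 1151)

    def test_adjacent_opposite_directions_not_merged(self):
        tmrs = call_tmrs(_track([1.4, -1.4]))
        assert {t.direction for t in tmrs} == {"negative", "positive"}
        assert all(t.cpg_count == 1 for t in tmrs)

    def test_all_zero_scores_yield_nothing(self):
        assert call_tmrs(_track([0.0] * 6)) == []

    def test_threshold_is_inclusive(self):
        thr = Thresholds()
        tmrs = call_tmrs(_track([thr.negative, thr.positive]))
        assert len(tmrs) == 2

    def test_missing_smoothed_values_break_runs(self):
        tmrs = call_tmrs(_track([-2.0, np.nan, -2.0]))
        assert len(tmrs) == 2
        assert all(t.cpg_count == 1 for t in tmrs)

    def test_members_all_exceed_their_threshold(self):
        rng = np.random.default_rng(2)
        sm = rng.normal(0, 2, size=200)
        thr = Thresholds()
        for t in call_tmrs(_track(sm), thr):
            members = sm[t.start_index : t.end_index + 1]
            if t.direction == "negative":
                assert np.all(members <= thr.negative)
            else:
                assert np.all(members >= thr.positive)

    def test_tightening_thresholds_never_grows_calls(self):
        rng = np.random.default_rng(4)
        sm = rng.normal(0, 2, size=300)
        loose = call_tmrs(_track(sm), Thresholds(-1.0, 1.0))
        tight = call_tmrs(_track(sm), Thresholds(-2.0, 2.0))
        # every tight TMR lies inside some loose TMR of the same direction
        for t in tight:
            assert any(
                l.direction == t.direction
                and l.start_index <= t.start_index
                and l.end_index >= t.end_index
                for l in loose
            )
        assert len(tight) >= 0 and sum(t.cpg_count for t in tight) <= sum(
            l.cpg_count for l in loose
        )


class TestFilters:
    def test_min_cpgs_boundary_inclusive(self):
        tmrs = call_tmrs(_track([-2.0] * 5 + [0.0] + [-2.0] * 4))
        kept = filter_min_cpgs(tmrs, 5)
        assert [t.cpg_count for t in kept] == [5]
        assert all("min_cpgs" in t.filters_passed for t in kept)

    def test_min_cpgs_matches_brute_force(self):
        rng = np.random.default_rng(6)
        tmrs = call_tmrs(_track(rng.normal(0, 2, size=400)))
        kept = filter_min_cpgs(tmrs, 5)
        expected = [t for t in tmrs if t.cpg_count >= 5]
        assert [(t.start_index, t.end_index) for t in kept] == [
            (t.start_index, t.end_index) for t in expected
        ]

    def _one_tmr(self):
        return call_tmrs(_track([-2.0] * 5))  # spans [1000, 1201)

    def test_full_containment_vs_any_overlap(self):
        tmrs = self._one_tmr()
        gapped = [
            GenomicInterval("chr1", 0, 1100, score=1.0),
            GenomicInterval("chr1", 1100, 1102, score=0.8),
            GenomicInterval("chr1", 1102, 5000, score=1.0),
        ]
        assert filter_mappability(tmrs, gapped, mode="full_containment") == []
        assert len(filter_mappability(tmrs, gapped, mode="any_overlap")) == 1

    def test_fully_contained_is_retained(self):
        tmrs = self._one_tmr()
        track = [GenomicInterval("chr1", 0, 10_000, score=1.0)]
        kept = filter_mappability(tmrs, track)
        assert len(kept) == 1 and "mappability" in kept[0].filters_passed

    def test_no_mappable_bases_drops_everything(self):
        tmrs = self._one_tmr()
        track = [GenomicInterval("chr1", 0, 10_000, score=0.5)]
        assert filter_mappability(tmrs, track) == []

    def test_empty_mappability_is_hard_error(self):
        with pytest.raises(ValueError, match="empty"):
            filter_mappability(self._one_tmr(), [])
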