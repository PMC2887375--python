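import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maci import (
    RepetitionSegments,
    ScoreTrajectory,
    adjacent_distances,
    detect_turning_points,
    repetition_correlation,
    segment_repetitions,
)
from maci.trajectory import DegenerateSegmentError, SegmentationError


def _bump(length, peak=1.0):
    """One rest->raise->rest repetition profile (half-sine bump)."""
    return peak * np.sin(np.linspace(0, np.pi, length)) ** 2


class TestAdjacentDistances:
    def test_constant_scores_give_zero(self):
        d = adjacent_distances(ScoreTrajectory(np.ones((5, 2))))
        np.testing.assert_array_equal(d, 0.0)

    def test_three_four_five(self):
        d = adjacent_distances(ScoreTrajectory(np.array([[0.0, 0.0], [3.0, 4.0]])))
        assert d[0] == pytest.approx(5.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 2 * np.pi))
    def test_invariant_to_score_rotation(self, seed, angle):
        scores = np.random.default_rng(seed).normal(size=(10, 2))
        R = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        d1 = adjacent_distances(ScoreTrajectory(scores))
        d2 = adjacent_distances(ScoreTrajectory(scores @ R.T))
        np.testing.assert_allclose(d1, d2, atol=1e-10)

    def test_dynamic_phases_move_farther_than_holds(self, heel_bundle):
        d = adjacent_distances(heel_bundle.traj)
        labels = np.asarray(heel_bundle.truth.phase_labels)[1:]
        moving = d[(labels == "concentric") | (labels == "eccentric")]
        still = d[(labels == "rest") | (labels == "hold")]
        assert np.median(moving) > 2 * np.median(still)


class TestTurningPoints:
    def test_monotone_score_has_no_turns(self):
        traj = ScoreTrajectory(np.linspace(0, 1, 50)[:, None])
        assert detect_turning_points(traj).size == 0

    def test_sinusoid_extrema_within_two_frames(self):
        t = np.arange(300)
        traj = ScoreTrajectory(np.sin(2 * np.pi * t / 100)[:, None])
        turns = detect_turning_points(traj, min_separation=20)
        expected = np.array([25, 75, 125, 175, 225, 275])
        assert turns.size == expected.size
        assert np.abs(turns - expected).max() <= 2

    def test_kinds_alternate_on_sinusoid(self):
        t = np.arange(300)
        traj = ScoreTrajectory(np.sin(2 * np.pi * t / 100)[:, None])
        _, kinds = detect_turning_points(traj, min_separation=20, return_kinds=True)
        assert np.all(kinds[::2] == kinds[0])
        assert np.all(kinds[1::2] == -kinds[0])

    def test_window_too_large_raises(self):
        traj = ScoreTrajectory(np.zeros((10, 1)))
        with pytest.raises(ValueError, match="smooth_window"):
            detect_turning_points(traj, smooth_window=10)

    def test_noise_wiggles_in_flat_phases_are_suppressed(self, rng):
        flat = np.concatenate([np.zeros(50), _bump(100), np.zeros(50)])
        noisy = flat + rng.normal(0, 0.005, flat.size)
        turns = detect_turning_points(ScoreTrajectory(noisy[:, None]), min_separation=10)
        assert turns.size == 1
        assert abs(turns[0] - 100) <= 3


class TestSegmentation:
    def test_single_repetition_spans_sequence(self):
        traj = ScoreTrajectory(np.sin(np.linspace(0, np.pi, 40))[:, None])
        segs = segment_repetitions(traj, 1)
        assert list(segs) == [(0, 40)]

    def test_three_identical_cycles_recovered(self):
        cycle = _bump(100)
        traj = ScoreTrajectory(np.tile(cycle, 3)[:, None])
        segs = segment_repetitions(traj, 3)
        for (s, e), (ts, te) in zip(segs, [(0, 100), (100, 200), (200, 300)]):
            assert abs(s - ts) <= 2 and abs(e - te) <= 2

    def test_orientation_flip_handled(self):
        # excursions downward: score decreases during each repetition
        cycle = -_bump(80)
        traj = ScoreTrajectory(np.tile(cycle, 2)[:, None])
        segs = segment_repetitions(traj, 2)
        assert abs(segs[0][1] - 80) <= 2

    def test_too_many_repetitions_requested_raises(self):
        traj = ScoreTrajectory(_bump(60)[:, None])
        with pytest.raises(SegmentationError, match="manual"):
            segment_repetitions(traj, 4)

    def test_segments_validation(self):
        with pytest.raises(ValueError, match="overlap"):
            RepetitionSegments([(0, 10), (5, 20)], 20)


class TestRepetitionCorrelation:
    def test_identical_segments_correlate_perfectly(self):
        cycle = _bump(50)
        traj = ScoreTrajectory(np.tile(cycle, 3)[:, None])
        segs = RepetitionSegments([(0, 50), (50, 100), (100, 150)], 150)
        corr = repetition_correlation(traj, segs)
        np.testing.assert_allclose(corr, 1.0, atol=1e-12)

    def test_negated_segment_gives_minus_one(self):
        cycle = _bump(40)
        series = np.concatenate([cycle, -cycle])
        segs = RepetitionSegments([(0, 40), (40, 80)], 80)
        corr = repetition_correlation(ScoreTrajectory(series[:, None]), segs)
        assert corr[0, 1] == pytest.approx(-1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.floats(0.1, 10.0), st.floats(-5.0, 5.0), st.integers(0, 2**31 - 1)
    )
    def test_affine_rescaling_invariance(self, scale, offset, seed):
        y = np.random.default_rng(seed).normal(size=60).cumsum()
        series = np.concatenate([y, scale * y + offset])
        segs = RepetitionSegments([(0, 60), (60, 120)], 120)
        corr = repetition_correlation(ScoreTrajectory(series[:, None]), segs)
        assert corr[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_unequal_durations_are_resampled(self):
        a, b = _bump(60), _bump(45)  # same shape, different duration
        series = np.concatenate([a, b])
        segs = RepetitionSegments([(0, 60), (60, 105)], 105)
        corr = repetition_correlation(ScoreTrajectory(series[:, None]), segs)
        assert corr[0, 1] >= 0.999

    def test_constant_segment_raises(self):
        series = np.concatenate([_bump(30), np.zeros(30)])
        segs = RepetitionSegments([(0, 30), (30, 60)], 60)
        with pytest.raises(DegenerateSegmentError):
            repetition_correlation(ScoreTrajectory(series[:, None]), segs)
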