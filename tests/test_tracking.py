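import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maci import (
    ImageSequence,
    RoiRect,
    SyntheticSpec,
    heel_raise_preset,
    pca_of_tracks,
    pennation_angle,
    render_sequence,
    track_grid,
    track_points,
    track_segmented_roi,
)
from maci.tracking import DegenerateDataError


def _static_sequence(n=8, shape=(96, 96), seed=6):
    spec = SyntheticSpec(
        frame_shape=shape, n_frames=n, motion_model="translation",
        translation_per_frame=(0.0, 0.0), noise_sigma=0.0, seed=seed,
    )
    return render_sequence(spec)[0]


def _translating_sequence(v, n, shape, seed=5, noise=0.0):
    spec = SyntheticSpec(
        frame_shape=shape, n_frames=n, motion_model="translation",
        translation_per_frame=v, noise_sigma=noise, seed=seed,
    )
    return render_sequence(spec)


class TestTrackPoints:
    def test_static_scene_zero_displacement(self):
        seq = _static_sequence()
        ts = track_points(seq, [(40, 40), (60, 30), (25, 70)])
        disp = np.abs(ts.positions - ts.positions[:, :1])
        assert disp.max() <= 0.05
        assert ts.valid.all()

    def test_known_translation_recovered(self):
        seq, truth = _translating_sequence((3.0, 0.0), 20, (160, 96))
        ts = track_points(seq, [(20, 30), (25, 48), (18, 70)])
        disp = ts.positions[:, :, 0] - ts.positions[:, :1, 0]
        err = disp - truth.translation[:, 0][None, :]
        assert np.abs(err).max() <= 0.25
        assert ts.valid.all()

    def test_seed_driven_past_border_goes_invalid_and_stays(self):
        seq, _ = _translating_sequence((3.0, 0.0), 12, (96, 96), seed=6)
        ts = track_points(seq, [(80, 48)])
        assert not ts.valid[0, -1]
        assert np.all(np.diff(ts.valid[0].astype(int)) <= 0)

    def test_empty_seed_list_raises(self):
        seq = _static_sequence(n=3)
        with pytest.raises(ValueError, match="empty"):
            track_points(seq, [])

    def test_seed_outside_frame_raises(self):
        seq = _static_sequence(n=3)
        with pytest.raises(ValueError, match="inside"):
            track_points(seq, [(200, 40)])

    def test_forward_backward_consistency(self):
        spec = heel_raise_preset(
            n_reps=1, frames_per_rep=100, frame_shape=(96, 96), seed=3
        )
        seq, _ = render_sequence(spec)
        seeds = np.array([(30.0, 40.0), (60.0, 50.0), (75.0, 30.0), (45.0, 70.0)])
        fw = track_points(seq, seeds)
        rev = ImageSequence(seq.frames[::-1].copy())
        bw = track_points(rev, fw.positions[:, -1])
        drift = np.linalg.norm(bw.positions[:, -1] - seeds, axis=1)
        assert drift.max() <= 0.5


class TestSegmentedRoi:
    def test_static_scene_flat_zero_series(self):
        seq = _static_sequence()
        series = track_segmented_roi(seq, RoiRect(20, 35, 50, 20), n_segments=1)
        assert np.abs(series.displacement_px).max() <= 0.05

    def test_depth_gradient_ordering(self):
        spec = SyntheticSpec(
            frame_shape=(128, 96), n_frames=40, motion_model="depth_shear",
            max_displacement=5.0, surface_gain=0.2, noise_sigma=0.005, seed=4,
        )
        seq, truth = render_sequence(spec)
        series = track_segmented_roi(seq, RoiRect(20, 38, 90, 20), n_segments=5)
        final = series.displacement_px[:, -1]
        assert np.all(np.diff(final) > 0)  # deeper segments move more
        centers = 20 + (np.arange(5) + 0.5) * 90 / 5
        expected = truth.amplitude[-1] * np.interp(
            centers, np.arange(128), truth.gain_row
        )
        assert np.abs(final / expected - 1).max() <= 0.10

    def test_mm_conversion_uses_pixel_spacing(self):
        seq = _static_sequence()
        seq.pixel_spacing = (0.5, 0.5)
        series = track_segmented_roi(seq, RoiRect(20, 35, 40, 20), n_segments=2)
        np.testing.assert_allclose(
            series.displacement_mm, series.displacement_px * 0.5
        )

    def test_invalid_segment_count_raises(self):
        seq = _static_sequence(n=3)
        with pytest.raises(ValueError, match="n_segments"):
            track_segmented_roi(seq, RoiRect(20, 35, 10, 5), n_segments=50)


class TestGrid:
    def test_static_grid_all_valid_zero_displacement(self):
        seq = _static_sequence()
        ts = track_grid(seq, (5, 5))
        assert ts.grid_shape == (5, 5)
        assert ts.valid.all()
        assert np.abs(ts.positions - ts.positions[:, :1]).max() <= 0.05

    def test_rigid_translation_shared_by_all_tracks(self):
        seq, truth = _translating_sequence((1.5, 0.0), 10, (128, 96), seed=9)
        ts = track_grid(seq, (6, 5))
        disp = ts.positions[:, :, 0] - ts.positions[:, :1, 0]
        err = disp[ts.valid[:, -1]] - truth.translation[:, 0][None, :]
        assert np.abs(err).max() <= 0.25

    def test_too_dense_grid_raises(self):
        seq = _static_sequence(n=3, shape=(64, 64))
        with pytest.raises(ValueError, match="dense"):
            track_grid(seq, (60, 60))


class TestPcaOfTracks:
    def test_rigid_translation_is_rank_one(self):
        seq, _ = _translating_sequence((1.5, 0.5), 12, (128, 128), seed=8)
        ts = track_grid(seq, (5, 5))
        model, traj = pca_of_tracks(ts, k=2)
        assert model.explained_variance_ratio_[0] >= 0.99
        assert traj.n_frames == 12

    def test_static_scene_rejected_as_degenerate(self):
        seq = _static_sequence()
        ts = track_grid(seq, (4, 4))
        with pytest.raises(DegenerateDataError, match="static|variation"):
            pca_of_tracks(ts)


class TestPennationAngle:
    def test_right_angle(self):
        res = pennation_angle([(0.0, 1.0)], [(0.0, 0.0)], [(1.0, 0.0)])
        assert res.angles_deg[0] == pytest.approx(90.0)

    def test_collinear_opposite_sides_is_straight(self):
        res = pennation_angle([(0.0, -2.0)], [(0.0, 0.0)], [(0.0, 3.0)])
        assert res.angles_deg[0] == pytest.approx(180.0)

    def test_zero_length_arm_flagged_undefined(self):
        res = pennation_angle([(0.0, 0.0)], [(0.0, 0.0)], [(1.0, 0.0)])
        assert not res.valid[0]
        assert np.isnan(res.angles_deg[0])

    def test_matches_atan2_oracle(self, rng):
        p1, p2, p3 = (rng.normal(size=(200, 2)) for _ in range(3))
        res = pennation_angle(p1, p2, p3)
        a1 = np.arctan2(p1[:, 0] - p2[:, 0], p1[:, 1] - p2[:, 1])
        a2 = np.arctan2(p3[:, 0] - p2[:, 0], p3[:, 1] - p2[:, 1])
        diff = np.abs(np.degrees(np.angle(np.exp(1j * (a1 - a2)))))
        assert np.abs(res.angles_deg - diff).max() <= 1e-9

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.0, 2 * np.pi), st.floats(0.1, 50.0), st.integers(0, 2**31 - 1))
    def test_invariant_under_rotation_and_scaling(self, angle, scale, seed):
        pts = np.random.default_rng(seed).normal(size=(3, 2))
        R = scale * np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        a = pennation_angle(pts[0][None], pts[1][None], pts[2][None]).angles_deg[0]
        q = pts @ R.T
        b = pennation_angle(q[0][None], q[1][None], q[2][None]).angles_deg[0]
        assert b == pytest.approx(a, abs=1e-6)
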