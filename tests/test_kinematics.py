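"""Trajectory building, gap handling, differentiation, reach segmentation."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.spatial.transform import Rotation

from behavekin.kinematics import (
    ReachInterval,
    build_trajectory3d,
    interpolate_gaps,
    kinematic_summary,
    minimum_jerk_peak_speed,
    segment_reaches,
    smooth,
    speed_series,
)
from behavekin.synthetic import default_reach_script, simulate_reach_session
from behavekin.trajectory import Trajectory3D


def _traj(points, fps=100.0, label="paw"):
    points = np.asarray(points, dtype=float)
    return Trajectory3D(label, fps, np.arange(len(points)), points)


class TestBuildTrajectory3D:
    def test_noiseless_closed_loop(self, mouse_rig):
        script = default_reach_script(seed=7)
        sess = simulate_reach_session(mouse_rig, script)
        traj = build_trajectory3d(sess.table("a"), sess.table("b"), "paw",
                                  mouse_rig, conf_min=0.5, fps=script.fps)
        assert traj.n_gaps == 0
        assert np.abs(traj.points - sess.truth.points).max() / 80.0 < 1e-6

    def test_low_confidence_view_becomes_gap(self, mouse_rig):
        script = default_reach_script(seed=8)
        sess = simulate_reach_session(mouse_rig, script)
        # force one frame of camera b below the confidence threshold
        sess.records_b[10]["conf"] = 0.3
        frame = sess.records_b[10]["_frame"]
        traj = build_trajectory3d(sess.table("a"), sess.table("b"), "paw",
                                  mouse_rig, conf_min=0.5, fps=script.fps)
        assert traj.gap_mask[frame - traj.frames[0]]

    def test_independent_dropout_rate_multiplies(self, mouse_rig):
        script = default_reach_script(seed=9, dropout_p=0.1)
        sess = simulate_reach_session(mouse_rig, script)
        traj = build_trajectory3d(sess.table("a"), sess.table("b"), "paw",
                                  mouse_rig, conf_min=0.5, fps=script.fps)
        n = len(traj)
        frac = 1 - traj.n_gaps / n
        # expected 0.9 * 0.9 = 0.81, binomial 4-sigma band
        se = np.sqrt(0.81 * 0.19 / n)
        assert abs(frac - 0.81) < 4 * se

    def test_absent_label_raises(self, mouse_rig):
        script = default_reach_script(seed=10)
        sess = simulate_reach_session(mouse_rig, script)
        with pytest.raises(ValueError):
            build_trajectory3d(sess.table("a"), sess.table("b"), "nope", mouse_rig)


class TestInterpolateGaps:
    def test_linear_fill_is_exact_on_a_line(self):
        pts = np.outer(np.arange(10.0), [1.0, 2.0, 0.5])
        pts[4:6] = np.nan
        out = interpolate_gaps(_traj(pts), max_gap_frames=3)
        expect = np.outer(np.arange(10.0), [1.0, 2.0, 0.5])
        assert np.allclose(out.points, expect)
        assert (out.confidence[4:6] == 0).all()

    def test_run_longer_than_max_gap_untouched(self):
        pts = np.outer(np.arange(10.0), [1.0, 0, 0])
        pts[3:7] = np.nan
        out = interpolate_gaps(_traj(pts), max_gap_frames=3)
        assert np.isnan(out.points[3:7]).all()

    def test_leading_gap_never_filled(self):
        pts = np.outer(np.arange(5.0), [1.0, 0, 0])
        pts[0] = np.nan
        out = interpolate_gaps(_traj(pts), max_gap_frames=3)
        assert np.isnan(out.points[0]).all()


class TestSmooth:
    def test_window_one_is_identity(self, rng):
        pts = rng.normal(0, 1, (20, 3))
        out = smooth(_traj(pts), 1)
        assert np.array_equal(out.points, pts)

    def test_constant_trajectory_unchanged(self):
        pts = np.tile([1.0, 2.0, 3.0], (15, 1))
        assert np.allclose(smooth(_traj(pts), 5).points, pts)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth(_traj(np.zeros((5, 3))), 4)

    def test_white_noise_variance_reduced_by_window(self, rng):
        ratios = []
        for _ in range(50):
            pts = rng.normal(0, 1.0, (200, 3))
            sm = smooth(_traj(pts), 5)
            ratios.append(pts[2:-2].var() / sm.points[2:-2].var())
        assert abs(np.mean(ratios) - 5.0) / 5.0 < 0.3


class TestSpeedSeries:
    def test_stationary_point_zero_speed(self):
        sp = speed_series(_traj(np.tile([1.0, 1, 1], (10, 1))))
        assert np.allclose(sp.values, 0.0)

    def test_uniform_motion_closed_form(self):
        d, fps = 0.25, 124.0
        pts = np.outer(np.arange(20.0) * d, [1.0, 0, 0])
        sp = speed_series(_traj(pts, fps=fps))
        assert np.allclose(sp.values, d * fps)

    def test_minimum_jerk_peak_speed_matches_analytic(self):
        L, T, fps = 30.0, 0.5, 124.0
        t = np.arange(int(T * fps) + 1) / fps
        tau = t / T
        prof = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
        pts = np.outer(L * prof, [1.0, 0, 0])
        sp = speed_series(_traj(pts, fps=fps))
        # oracle: numerically maximize the continuous speed profile
        v = lambda tt: -L / T * 30 * (tt**2 - 2 * tt**3 + tt**4)
        vmax = -minimize_scalar(v, bounds=(0, 1), method="bounded").fun
        assert vmax == pytest.approx(minimum_jerk_peak_speed(L, T), rel=1e-6)
        assert np.nanmax(sp.values) == pytest.approx(vmax, rel=0.02)


class TestSegmentReaches:
    def test_speed_below_threshold_gives_no_intervals(self):
        sp = speed_series(_traj(np.zeros((50, 3))))
        assert segment_reaches(sp, v_on=2.0, v_off=1.0) == []

    def test_ten_scripted_reaches_recovered(self, mouse_rig):
        script = default_reach_script(seed=11)
        sess = simulate_reach_session(mouse_rig, script)
        traj = build_trajectory3d(sess.table("a"), sess.table("b"), "paw",
                                  mouse_rig, fps=script.fps)
        sp = speed_series(smooth(traj, 5))
        ivs = segment_reaches(sp, v_on=20.0, v_off=10.0, min_duration_s=0.1,
                              merge_gap_s=0.05)
        assert len(ivs) == 10
        for iv, (gt_on, _) in zip(ivs, sess.intervals):
            assert abs(iv.onset_frame - gt_on) <= 3

    def test_bursts_within_merge_gap_are_merged(self):
        vals = np.zeros(100)
        vals[10:30] = 10.0
        vals[33:55] = 10.0  # 3-frame dip < merge gap of 5 frames
        pts = np.zeros((100, 3))
        pts[:, 0] = np.cumsum(vals) / 100.0
        sp = speed_series(_traj(pts, fps=100.0))
        ivs = segment_reaches(sp, v_on=5.0, v_off=3.0, min_duration_s=0.05,
                              merge_gap_s=0.05)
        assert len(ivs) == 1


class TestKinematicSummary:
    def test_straight_uniform_reach(self):
        pts = np.outer(np.linspace(0, 10, 50), [1.0, 0, 0])
        traj = _traj(pts)
        s = kinematic_summary(traj, ReachInterval(0, 49, 0.0), v_off=1.0)
        assert s.path_length_ratio == pytest.approx(1.0)
        assert s.n_velocity_peaks == 1
        assert s.distance_traveled == pytest.approx(10.0)
        assert s.duration == pytest.approx(49 / 100.0)

    def test_two_submovement_reach_has_two_velocity_peaks(self):
        fps = 200.0
        t1 = np.linspace(0, 1, 100)
        mj = 10 * t1**3 - 15 * t1**4 + 6 * t1**5
        seg1 = np.outer(10 * mj, [1.0, 0, 0])
        seg2 = seg1[-1] + np.outer(10 * mj, [1.0, 0, 0])
        pts = np.vstack([seg1, seg2[1:]])
        traj = _traj(pts, fps=fps)
        s = kinematic_summary(traj, ReachInterval(0, len(pts) - 1, 0.0), v_off=5.0)
        assert s.n_velocity_peaks == 2

    def test_semicircular_path_ratio_is_half_pi(self):
        theta = np.linspace(0, np.pi, 2000)
        r = 10.0
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), np.zeros_like(theta)])
        traj = _traj(pts, fps=1000.0)
        s = kinematic_summary(traj, ReachInterval(0, 1999, 0.0), v_off=1.0)
        assert s.path_length_ratio == pytest.approx(np.pi / 2, rel=0.01)

    def test_too_few_samples_raise(self):
        pts = np.full((10, 3), np.nan)
        pts[0] = 0.0
        with pytest.raises(ValueError):
            kinematic_summary(_traj(pts), ReachInterval(0, 9, 0.0))


class TestInvariants:
    def test_rigid_motion_invariance(self, rng):
        pts = np.cumsum(rng.normal(0, 1, (80, 3)), axis=0)
        traj = _traj(pts)
        R = Rotation.from_rotvec([0.3, -0.8, 0.5]).as_matrix()
        t = np.array([100.0, -50.0, 20.0])
        moved = _traj(pts @ R.T + t)
        iv = ReachInterval(5, 70, 0.0)
        s1 = kinematic_summary(traj, iv, v_off=1.0)
        s2 = kinematic_summary(moved, iv, v_off=1.0)
        for f in ("distance_traveled", "duration", "max_speed", "mean_speed",
                  "path_length_ratio"):
            assert getattr(s1, f) == pytest.approx(getattr(s2, f), abs=1e-9)
        assert s1.n_velocity_peaks == s2.n_velocity_peaks

    def test_sampling_rate_consistency(self):
        # the same continuous reach sampled at 124 and 248 fps
        L, T = 30.0, 0.5
        out = {}
        for fps in (124.0, 248.0):
            t = np.arange(int(3.0 * fps)) / fps
            tau = np.clip((t - 1.0) / T, 0, 1)
            prof = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
            pts = np.outer(L * prof, [1.0, 0, 0])
            traj = _traj(pts, fps=fps)
            iv = ReachInterval(int(1.0 * fps), int((1.0 + T) * fps), 0.0)
            out[fps] = kinematic_summary(traj, iv, v_off=1.0)
        for f in ("distance_traveled", "duration", "max_speed", "mean_speed"):
            a, b = getattr(out[124.0], f), getattr(out[248.0], f)
            assert abs(a - b) / b < 0.01

    @pytest.mark.parametrize("seed", range(5))
    def test_parameter_recovery_under_noise(self, seed, mouse_rig):
        script = default_reach_script(seed=200 + seed, noise_px=0.5)
        sess = simulate_reach_session(mouse_rig, script)
        traj = build_trajectory3d(sess.table("a"), sess.table("b"), "paw",
                                  mouse_rig, fps=script.fps)
        sp = speed_series(smooth(traj, 5))
        ivs = segment_reaches(sp, v_on=20.0, v_off=10.0, min_duration_s=0.1,
                              merge_gap_s=0.05)
        assert len(ivs) == len(sess.intervals)
        for iv, pk, (gt_on, gt_off) in zip(ivs, sess.peak_speeds, sess.intervals):
            assert abs(iv.peak_speed - pk) / pk < 0.10
            gt_dur = (gt_off - gt_on) / script.fps
            dur = (iv.offset_frame - iv.onset_frame) / script.fps
            assert abs(dur - gt_dur) / gt_dur < 0.10
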