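"""Stereo geometry: projection, calibration, triangulation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from behavekin.detections import PixelPoint
from behavekin.geometry import (
    BoardSpec,
    CalibrationError,
    CameraIntrinsics,
    CameraModel,
    CameraPose,
    GeometryError,
    StereoRig,
    calibrate_planar,
    estimate_homography,
    load_rig,
    project,
    project_points,
    reprojection_rms,
    save_rig,
    solve_stereo_extrinsics,
    triangulate,
    triangulate_points,
    undistort_point,
    undistort_points,
)
from behavekin.synthetic import look_at_pose, make_rig, simulate_checkerboard_views

IDENTITY_POSE = CameraPose(np.eye(3), np.zeros(3))


class TestProjection:
    def test_optical_axis_maps_to_principal_point(self):
        cam = CameraModel(CameraIntrinsics(1000, 1000, 320, 240), IDENTITY_POSE)
        assert project((0, 0, 1), cam) == PixelPoint(320, 240)

    def test_similar_triangles(self):
        cam = CameraModel(CameraIntrinsics(1000, 1000, 0, 0), IDENTITY_POSE)
        assert project((0.1, 0, 1), cam) == PixelPoint(100, 0)

    def test_radial_distortion_hand_value(self):
        # k1 = -0.1 at r^2 = 0.25: u = 1000 * (1 - 0.025) * 0.5 = 487.5
        cam = CameraModel(CameraIntrinsics(1000, 1000, 0, 0, k1=-0.1), IDENTITY_POSE)
        assert project((0.5, 0, 1), cam).u == pytest.approx(487.5, abs=1e-9)

    def test_point_behind_camera_raises(self):
        cam = CameraModel(CameraIntrinsics(1000, 1000, 0, 0), IDENTITY_POSE)
        with pytest.raises(GeometryError):
            project((0, 0, -1), cam)


class TestUndistort:
    def test_zero_distortion_is_identity(self):
        intr = CameraIntrinsics(900, 950, 320, 240)
        p = PixelPoint(123.4, 567.8)
        assert undistort_point(p, intr) == p

    def test_undistort_inverts_distortion(self, rng):
        intr = CameraIntrinsics(900, 950, 320, 240, k1=-0.08, k2=0.012)
        ideal = CameraIntrinsics(900, 950, 320, 240)
        cam_d = CameraModel(intr, IDENTITY_POSE)
        cam_i = CameraModel(ideal, IDENTITY_POSE)
        pts = np.column_stack([rng.uniform(-0.2, 0.2, 200), rng.uniform(-0.2, 0.2, 200),
                               np.ones(200)])
        uv_d = project_points(pts, cam_d)
        uv_i = project_points(pts, cam_i)
        assert np.abs(undistort_points(uv_d, intr) - uv_i).max() < 1e-6

    def test_non_invertible_distortion_raises(self):
        # strongly negative k1: the radial polynomial folds over at this radius
        intr = CameraIntrinsics(1000, 1000, 0, 0, k1=-5.0)
        with pytest.raises(GeometryError):
            undistort_point(PixelPoint(900.0, 0.0), intr)


class TestHomography:
    def test_identity_correspondences(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.3, 0.7]], dtype=float)
        H = estimate_homography(pts, pts)
        assert np.allclose(H, np.eye(3), atol=1e-9)

    def test_recovers_known_similarity(self):
        src = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        s, th, tx, ty = 2.5, 0.3, 4.0, -1.0
        S = np.array([[s * np.cos(th), -s * np.sin(th), tx],
                      [s * np.sin(th), s * np.cos(th), ty],
                      [0, 0, 1]])
        dst = (np.column_stack([src, np.ones(4)]) @ S.T)[:, :2]
        H = estimate_homography(src, dst)
        assert np.allclose(H, S / S[2, 2], atol=1e-9)

    def test_exact_interpolation_at_zero_noise(self, rng):
        src = rng.uniform(0, 10, (12, 2))
        H_true = np.array([[1.2, 0.1, 3.0], [-0.2, 0.9, 1.0], [0.001, 0.002, 1.0]])
        hom = np.column_stack([src, np.ones(12)]) @ H_true.T
        dst = hom[:, :2] / hom[:, 2:]
        H = estimate_homography(src, dst)
        back = np.column_stack([src, np.ones(12)]) @ H.T
        assert np.abs(back[:, :2] / back[:, 2:] - dst).max() < 1e-9

    def test_collinear_points_raise(self):
        src = np.column_stack([np.arange(6.0), np.zeros(6)])
        dst = src * 2
        with pytest.raises(GeometryError):
            estimate_homography(src, dst)


def _synthetic_views(intr, board, n_views, seed, noise=0.0):
    rng = np.random.default_rng(seed)
    obj = np.column_stack([board.object_points(), np.zeros(board.n_corners)])
    span = max(board.n_cols, board.n_rows) * board.square_size
    views = []
    while len(views) < n_views:
        R = Rotation.from_rotvec(rng.normal(0, 0.35, 3)).as_matrix()
        t = np.array([rng.normal(-span / 2, span / 4), rng.normal(-span / 2, span / 4),
                      rng.uniform(2.0, 3.5) * span])
        try:
            uv = project_points(obj, CameraModel(intr, CameraPose(R, t)))
        except GeometryError:
            continue
        views.append((board, uv + rng.normal(0, noise, uv.shape)))
    return views


class TestCalibratePlanar:
    BOARD = BoardSpec(10, 7, 115.0)
    TRUE = CameraIntrinsics(fx=900, fy=950, cx=320, cy=240)

    def test_noiseless_recovery(self):
        views = _synthetic_views(self.TRUE, self.BOARD, 10, seed=0)
        res = calibrate_planar(views)
        for got, want in [(res.intrinsics.fx, 900), (res.intrinsics.fy, 950),
                          (res.intrinsics.cx, 320), (res.intrinsics.cy, 240)]:
            assert abs(got - want) / want < 1e-3
        assert res.rms_px < 1e-6
        assert res.final_cost <= res.initial_cost * (1 + 1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_recovery_within_one_percent(self, seed):
        views = _synthetic_views(self.TRUE, self.BOARD, 15, seed=seed, noise=0.2)
        res = calibrate_planar(views)
        assert abs(res.intrinsics.fx - 900) / 900 < 0.01
        assert abs(res.intrinsics.fy - 950) / 950 < 0.01
        assert res.rms_px < 0.4  # ~ noise sigma, within factor 2

    def test_large_board_geometry_accepted(self):
        # 10x7-square board with 115 mm squares: 9x7 = 63 interior corners/view
        board = BoardSpec(9, 7, 115.0)
        views = _synthetic_views(self.TRUE, board, 24, seed=3)
        assert all(len(c) == 63 for _, c in views)
        res = calibrate_planar(views)
        assert res.n_views == 24

    def test_too_few_views_raise(self):
        views = _synthetic_views(self.TRUE, self.BOARD, 2, seed=1)
        with pytest.raises(CalibrationError):
            calibrate_planar(views)


class TestStereoExtrinsics:
    def test_baseline_recovered_noiseless(self, mouse_rig):
        board = BoardSpec(4, 6, 4.5)
        views = simulate_checkerboard_views(mouse_rig, board, 10, seed=4)
        res_a = calibrate_planar([(board, c) for c in views.corners_a])
        res_b = calibrate_planar([(board, c) for c in views.corners_b])
        rig = solve_stereo_extrinsics(list(zip(views.corners_a, views.corners_b)),
                                      res_a.intrinsics, res_b.intrinsics, board)
        assert abs(rig.baseline - mouse_rig.baseline) / mouse_rig.baseline < 1e-6

    def test_single_shared_view_averaging_is_identity(self, mouse_rig):
        board = BoardSpec(4, 6, 4.5)
        views = simulate_checkerboard_views(mouse_rig, board, 3, seed=5)
        intr_a = mouse_rig.camera_a.intrinsics
        intr_b = mouse_rig.camera_b.intrinsics
        one = solve_stereo_extrinsics([(views.corners_a[0], views.corners_b[0])],
                                      intr_a, intr_b, board)
        assert one.meta["rotation_spread_deg"] < 1e-8
        assert one.meta["translation_spread"] < 1e-6

    def test_orthogonal_camera_orientations_supported(self, mouse_rig):
        # the mouse preset has near-orthogonal optical axes by construction
        za = mouse_rig.camera_a.pose.rotation[2]
        zb = mouse_rig.camera_b.pose.rotation[2]
        angle = np.degrees(np.arccos(abs(np.dot(za, zb))))
        assert 60 < angle <= 90.1

    def test_no_shared_view_raises(self, mouse_rig):
        with pytest.raises(CalibrationError):
            solve_stereo_extrinsics([], mouse_rig.camera_a.intrinsics,
                                    mouse_rig.camera_b.intrinsics, BoardSpec(4, 6, 4.5))


class TestTriangulation:
    def test_round_trip_1000_points(self, mouse_rig, rng):
        pts = rng.uniform(-40, 40, (1000, 3))
        uva = project_points(pts, mouse_rig.camera_a)
        uvb = project_points(pts, mouse_rig.camera_b)
        back, resid = triangulate_points(uva, uvb, mouse_rig)
        scale = 80.0
        assert np.abs(back - pts).max() / scale < 1e-8
        assert resid.max() < 1e-8

    def test_round_trip_with_distortion(self, rng):
        intr_a = CameraIntrinsics(700, 710, 224, 230, k1=-0.05, k2=0.01)
        intr_b = CameraIntrinsics(690, 705, 220, 228, k1=0.03, k2=-0.005)
        rig = StereoRig(CameraModel(intr_a, look_at_pose((0, -180, 50), (0, 0, 0)), 448, 460),
                        CameraModel(intr_b, look_at_pose((180, 0, 50), (0, 0, 0)), 448, 460))
        pts = rng.uniform(-30, 30, (300, 3))
        back, resid = triangulate_points(project_points(pts, rig.camera_a),
                                         project_points(pts, rig.camera_b), rig)
        assert np.abs(back - pts).max() / 60.0 < 1e-8

    def test_symmetric_rig_midpoint(self):
        intr = CameraIntrinsics(700, 700, 224, 230)
        rig = StereoRig(CameraModel(intr, look_at_pose((-100, -150, 0), (0, 0, 0)), 448, 460),
                        CameraModel(intr, look_at_pose((100, -150, 0), (0, 0, 0)), 448, 460))
        p = np.array([0.0, 10.0, 5.0])  # on the baseline's perpendicular bisector plane
        got, _ = triangulate(project(p, rig.camera_a), project(p, rig.camera_b), rig)
        assert abs(got[0]) < 1e-9

    def test_noise_monotonicity(self, mouse_rig, rng):
        pts = rng.uniform(-30, 30, (400, 3))
        uva = project_points(pts, mouse_rig.camera_a)
        uvb = project_points(pts, mouse_rig.camera_b)
        med = []
        for sigma in (0.0, 0.5, 1.0, 2.0):
            na = uva + rng.normal(0, sigma, uva.shape)
            nb = uvb + rng.normal(0, sigma, uvb.shape)
            back, _ = triangulate_points(na, nb, mouse_rig)
            med.append(np.median(np.linalg.norm(back - pts, axis=1)))
        assert med == sorted(med)

    def test_parallel_rays_raise(self):
        intr = CameraIntrinsics(700, 700, 0, 0)
        pose = look_at_pose((0, -100, 0), (0, 0, 0))
        shifted = CameraPose(pose.rotation, pose.translation + pose.rotation @ np.array([0, 0, -50.0]))
        rig = StereoRig(CameraModel(intr, pose), CameraModel(intr, shifted))
        # identical pixel in two cameras sharing one optical axis -> rays parallel/identical
        with pytest.raises(GeometryError):
            triangulate(PixelPoint(0.0, 0.0), PixelPoint(0.0, 0.0), rig)


class TestReprojectionRms:
    def _cam(self):
        return CameraModel(CameraIntrinsics(700, 700, 224, 230),
                           look_at_pose((0, -180, 50), (0, 0, 0)))

    def test_perfect_correspondences_are_zero(self, rng):
        cam = self._cam()
        pts = rng.uniform(-20, 20, (50, 3))
        uv = project_points(pts, cam)
        assert reprojection_rms([(cam, pts, uv)]) < 1e-9

    def test_single_displaced_corner_closed_form(self, rng):
        cam = self._cam()
        n = 25
        pts = rng.uniform(-20, 20, (n, 3))
        uv = project_points(pts, cam)
        uv[3, 0] += 3.0
        assert reprojection_rms([(cam, pts, uv)]) == pytest.approx(3.0 / np.sqrt(n))

    def test_permutation_invariance(self, rng):
        cam = self._cam()
        pts = rng.uniform(-20, 20, (30, 3))
        uv = project_points(pts, cam) + rng.normal(0, 1, (30, 2))
        perm = rng.permutation(30)
        assert reprojection_rms([(cam, pts, uv)]) == pytest.approx(
            reprojection_rms([(cam, pts[perm], uv[perm])]))


class TestWorldFrameEquivariance:
    def test_rigid_world_transform_preserves_triangulated_distances(self, rng):
        intr = CameraIntrinsics(700, 700, 224, 230)
        pose_a = look_at_pose((0, -180, 50), (0, 0, 0))
        pose_b = look_at_pose((180, 0, 50), (0, 0, 0))
        rig = StereoRig(CameraModel(intr, pose_a, 448, 460),
                        CameraModel(intr, pose_b, 448, 460))
        Rw = Rotation.from_rotvec([0.4, -0.2, 0.9]).as_matrix()
        tw = np.array([30.0, -70.0, 15.0])

        def moved(pose):
            return CameraPose(pose.rotation @ Rw.T, pose.translation - pose.rotation @ Rw.T @ tw)

        rig2 = StereoRig(CameraModel(intr, moved(pose_a), 448, 460),
                         CameraModel(intr, moved(pose_b), 448, 460))
        pts = rng.uniform(-30, 30, (50, 3))
        pts2 = pts @ Rw.T + tw
        x1, _ = triangulate_points(project_points(pts, rig.camera_a),
                                   project_points(pts, rig.camera_b), rig)
        x2, _ = triangulate_points(project_points(pts2, rig2.camera_a),
                                   project_points(pts2, rig2.camera_b), rig2)
        d1 = np.linalg.norm(x1[:-1] - x1[1:], axis=1)
        d2 = np.linalg.norm(x2[:-1] - x2[1:], axis=1)
        assert np.abs(d1 - d2).max() < 1e-8


def test_rig_json_round_trip(tmp_path, mouse_rig):
    path = tmp_path / "rig.json"
    save_rig(mouse_rig, path)
    back = load_rig(path)
    assert np.allclose(back.camera_a.pose.rotation, mouse_rig.camera_a.pose.rotation)
    assert np.allclose(back.camera_b.pose.translation, mouse_rig.camera_b.pose.translation)
    assert back.camera_a.intrinsics == mouse_rig.camera_a.intrinsics
    assert back.world_units == "mm"
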