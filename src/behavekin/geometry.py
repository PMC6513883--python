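"""Planar checkerboard calibration, projection and two-view triangulation.

The camera model is the standard pinhole with optional two-term radial
distortion. A world point ``p`` maps to pixels through

    X = R p + t                      (world -> camera)
    (x, y) = (X1/X3, X2/X3)          (normalized image plane)
    rho = 1 + k1 r^2 + k2 r^4,  r^2 = x^2 + y^2
    u = fx rho x + skew y + cx
    v = fy rho y + cy

Intrinsics are estimated from >= 3 views of a flat checkerboard: each view
gives a plane-to-image homography whose columns constrain the image of the
absolute conic (Zhang's method); the closed-form solution seeds a joint
nonlinear least-squares refinement of intrinsics and per-view poses over
total squared reprojection error. Two cameras observing the same board
views are placed in a shared world frame anchored to the first common view
(board origin = world origin, board plane = z = 0), and a pair of pixel
observations is lifted to 3D by linear (SVD) triangulation after
undistortion.

Lengths are in the board's square units (mm throughout this package).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .detections import PixelPoint

__all__ = [
    "CameraIntrinsics",
    "CameraPose",
    "CameraModel",
    "StereoRig",
    "BoardSpec",
    "CalibrationResult",
    "project",
    "project_points",
    "undistort_point",
    "undistort_points",
    "estimate_homography",
    "calibrate_planar",
    "solve_stereo_extrinsics",
    "triangulate",
    "triangulate_points",
    "reprojection_rms",
    "save_rig",
    "load_rig",
]


class GeometryError(RuntimeError):
    """Degenerate geometric configuration (parallel rays, point behind camera...)."""


class CalibrationError(RuntimeError):
    """Calibration could not be performed on the given views."""


@dataclass(frozen=True)
class CameraIntrinsics:
    fx: float
    fy: float
    cx: float
    cy: float
    skew: float = 0.0
    k1: float = 0.0
    k2: float = 0.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if abs(self.skew) >= self.fx:
            raise ValueError("skew unreasonably large relative to fx")

    @property
    def K(self) -> np.ndarray:
        return np.array([
            [self.fx, self.skew, self.cx],
            [0.0, self.fy, self.cy],
            [0.0, 0.0, 1.0],
        ])


@dataclass(frozen=True)
class CameraPose:
    """World -> camera rigid transform."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation determinant must be +1")

    @property
    def center(self) -> np.ndarray:
        """Camera optical center in world coordinates: -R^T t."""
        return -self.rotation.T @ self.translation

    def transform(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class CameraModel:
    intrinsics: CameraIntrinsics
    pose: CameraPose
    image_width: int = 0
    image_height: int = 0


@dataclass(frozen=True)
class StereoRig:
    camera_a: CameraModel
    camera_b: CameraModel
    world_units: str = "mm"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        baseline = np.linalg.norm(self.camera_a.pose.center - self.camera_b.pose.center)
        if baseline <= 0:
            raise ValueError("stereo baseline must be positive")

    @property
    def baseline(self) -> float:
        return float(np.linalg.norm(self.camera_a.pose.center - self.camera_b.pose.center))


@dataclass(frozen=True)
class BoardSpec:
    """Checkerboard interior-corner grid: n_cols x n_rows corners, square_size in mm."""

    n_cols: int
    n_rows: int
    square_size: float

    def __post_init__(self) -> None:
        if self.n_cols < 2 or self.n_rows < 2:
            raise ValueError("need at least a 2x2 interior corner grid")
        if self.square_size <= 0:
            raise ValueError("square size must be positive")

    @property
    def n_corners(self) -> int:
        return self.n_cols * self.n_rows

    def object_points(self) -> np.ndarray:
        """Corner coordinates on the board plane (z = 0), row-major, in mm."""
        cols, rows = np.meshgrid(np.arange(self.n_cols), np.arange(self.n_rows))
        pts = np.stack([cols.ravel(), rows.ravel()], axis=1).astype(float)
        return pts * self.square_size


# ---------------------------------------------------------------------------
# projection

def project_points(points: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Project (n, 3) world points to (n, 2) pixels. Raises on non-positive depth."""
    X = cam.pose.transform(np.atleast_2d(np.asarray(points, dtype=float)))
    if np.any(X[:, 2] <= 0):
        raise GeometryError("point(s) at non-positive depth in the camera frame")
    intr = cam.intrinsics
    xy = X[:, :2] / X[:, 2:3]
    r2 = np.sum(xy**2, axis=1)
    rho = 1.0 + intr.k1 * r2 + intr.k2 * r2**2
    u = intr.fx * rho * xy[:, 0] + intr.skew * xy[:, 1] + intr.cx
    v = intr.fy * rho * xy[:, 1] + intr.cy
    return np.stack([u, v], axis=1)


def project(p, cam: CameraModel) -> PixelPoint:
    """Project one world point; see :func:`project_points`."""
    uv = project_points(np.asarray(p, dtype=float).reshape(1, 3), cam)[0]
    return PixelPoint(float(uv[0]), float(uv[1]))


def _pixels_to_distorted_normalized(uv: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    yd = (uv[:, 1] - intr.cy) / intr.fy
    xd = (uv[:, 0] - intr.cx - intr.skew * yd) / intr.fx
    return np.stack([xd, yd], axis=1)


def _undistort_normalized(xyd: np.ndarray, intr: CameraIntrinsics,
                          max_iter: int = 20, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Invert the radial model by fixed-point iteration in normalized coordinates.

    Returns (undistorted normalized coords, per-point convergence mask).
    """
    if intr.k1 == 0.0 and intr.k2 == 0.0:
        return xyd.copy(), np.ones(len(xyd), dtype=bool)
    xy = xyd.copy()
    converged = np.zeros(len(xyd), dtype=bool)
    for _ in range(max_iter):
        r2 = np.sum(xy**2, axis=1)
        rho = 1.0 + intr.k1 * r2 + intr.k2 * r2**2
        new = np.where(np.abs(rho[:, None]) > 1e-12, xyd / rho[:, None], xy)
        converged = np.linalg.norm(new - xy, axis=1) < tol
        xy = new
        if converged.all():
            break
    # a diverged iterate re-distorts far from the observation
    r2 = np.sum(xy**2, axis=1)
    rho = 1.0 + intr.k1 * r2 + intr.k2 * r2**2
    back = xy * rho[:, None]
    converged = converged & (np.linalg.norm(back - xyd, axis=1) < 1e-6) & np.isfinite(xy).all(axis=1)
    return xy, converged


def undistort_points(uv: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Map observed pixels to ideal (distortion-free) pinhole pixels."""
    uv = np.atleast_2d(np.asarray(uv, dtype=float))
    xyd = _pixels_to_distorted_normalized(uv, intr)
    xy, ok = _undistort_normalized(xyd, intr)
    if not ok.all():
        bad = uv[~ok][0]
        raise GeometryError(f"undistortion did not converge at pixel ({bad[0]:.2f}, {bad[1]:.2f})")
    u = intr.fx * xy[:, 0] + intr.skew * xy[:, 1] + intr.cx
    v = intr.fy * xy[:, 1] + intr.cy
    return np.stack([u, v], axis=1)


def undistort_point(p: PixelPoint, intr: CameraIntrinsics) -> PixelPoint:
    uv = undistort_points(np.array([[p.u, p.v]]), intr)[0]
    return PixelPoint(float(uv[0]), float(uv[1]))


# ---------------------------------------------------------------------------
# homography + Zhang closed form

def _hartley_normalization(pts: np.ndarray) -> np.ndarray:
    """Similarity transform bringing the points to centroid 0, mean radius sqrt(2)."""
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1).mean()
    if d < 1e-12:
        raise GeometryError("degenerate (coincident) point configuration")
    s = np.sqrt(2.0) / d
    return np.array([[s, 0, -s * centroid[0]], [0, s, -s * centroid[1]], [0, 0, 1]])


def estimate_homography(object_points_2d: np.ndarray, image_points: np.ndarray) -> np.ndarray:
    """Normalized DLT homography from board-plane (z=0) coordinates to pixels."""
    obj = np.asarray(object_points_2d, dtype=float).reshape(-1, 2)
    img = np.asarray(image_points, dtype=float).reshape(-1, 2)
    if len(obj) != len(img) or len(obj) < 4:
        raise ValueError("need >= 4 correspondences of equal count")
    T_obj = _hartley_normalization(obj)
    T_img = _hartley_normalization(img)
    on = (np.column_stack([obj, np.ones(len(obj))]) @ T_obj.T)[:, :2]
    im = (np.column_stack([img, np.ones(len(img))]) @ T_img.T)[:, :2]
    A = []
    for (X, Y), (u, v) in zip(on, im):
        A.append([-X, -Y, -1, 0, 0, 0, u * X, u * Y, u])
        A.append([0, 0, 0, -X, -Y, -1, v * X, v * Y, v])
    A = np.asarray(A)
    _, s, Vt = np.linalg.svd(A)
    if s[-2] < 1e-12 * s[0]:
        raise GeometryError("degenerate (collinear) correspondence configuration")
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(T_img) @ Hn @ T_obj
    if abs(H[2, 2]) > 1e-12:
        H = H / H[2, 2]
    return H


def _zhang_v(H: np.ndarray, i: int, j: int) -> np.ndarray:
    return np.array([
        H[0, i] * H[0, j],
        H[0, i] * H[1, j] + H[1, i] * H[0, j],
        H[1, i] * H[1, j],
        H[2, i] * H[0, j] + H[0, i] * H[2, j],
        H[2, i] * H[1, j] + H[1, i] * H[2, j],
        H[2, i] * H[2, j],
    ])


def _intrinsics_from_homographies(Hs: list[np.ndarray], fix_skew: bool) -> CameraIntrinsics:
    V = []
    for H in Hs:
        V.append(_zhang_v(H, 0, 1))
        V.append(_zhang_v(H, 0, 0) - _zhang_v(H, 1, 1))
    V = np.asarray(V)
    _, _, Vt = np.linalg.svd(V)
    b11, b12, b22, b13, b23, b33 = Vt[-1]
    denom = b11 * b22 - b12**2
    if abs(denom) < 1e-18 or abs(b11) < 1e-18:
        raise CalibrationError("closed-form intrinsics are degenerate; add more varied views")
    v0 = (b12 * b13 - b11 * b23) / denom
    lam = b33 - (b13**2 + v0 * (b12 * b13 - b11 * b23)) / b11
    if lam / b11 <= 0:
        # conic sign flip: the SVD null vector is sign-ambiguous
        b11, b12, b22, b13, b23, b33 = -Vt[-1]
        denom = b11 * b22 - b12**2
        v0 = (b12 * b13 - b11 * b23) / denom
        lam = b33 - (b13**2 + v0 * (b12 * b13 - b11 * b23)) / b11
    alpha = np.sqrt(lam / b11)
    beta = np.sqrt(lam * b11 / denom)
    gamma = -b12 * alpha**2 * beta / lam
    u0 = gamma * v0 / beta - b13 * alpha**2 / lam
    if fix_skew:
        gamma = 0.0
    if not (np.isfinite(alpha) and np.isfinite(beta) and alpha > 0 and beta > 0):
        raise CalibrationError("closed-form intrinsics are not finite")
    return CameraIntrinsics(fx=float(alpha), fy=float(beta), cx=float(u0), cy=float(v0),
                            skew=float(gamma))


def _pose_from_homography(H: np.ndarray, K: np.ndarray) -> CameraPose:
    """Board-plane pose (board frame -> camera) from a homography and intrinsics."""
    A = np.linalg.solve(K, H)
    lam = 1.0 / np.linalg.norm(A[:, 0])
    if A[2, 2] * lam < 0:  # board must sit in front of the camera
        lam = -lam
    r1 = lam * A[:, 0]
    r2 = lam * A[:, 1]
    t = lam * A[:, 2]
    Q = np.column_stack([r1, r2, np.cross(r1, r2)])
    U, _, Vt = np.linalg.svd(Q)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    return CameraPose(rotation=R, translation=t)


@dataclass
class CalibrationResult:
    intrinsics: CameraIntrinsics
    view_poses: list[CameraPose]
    rms_px: float
    per_view_rms_px: np.ndarray
    initial_cost: float
    final_cost: float
    n_views: int


def _pack_params(intr: CameraIntrinsics, poses: list[CameraPose],
                 estimate_skew: bool, estimate_distortion: bool) -> np.ndarray:
    p = [intr.fx, intr.fy, intr.cx, intr.cy]
    if estimate_skew:
        p.append(intr.skew)
    if estimate_distortion:
        p.extend([intr.k1, intr.k2])
    for pose in poses:
        p.extend(Rotation.from_matrix(pose.rotation).as_rotvec())
        p.extend(pose.translation)
    return np.asarray(p, dtype=float)


def _unpack_params(p: np.ndarray, n_views: int, estimate_skew: bool,
                   estimate_distortion: bool) -> tuple[CameraIntrinsics, list[CameraPose]]:
    fx, fy, cx, cy = p[:4]
    i = 4
    skew = 0.0
    k1 = k2 = 0.0
    if estimate_skew:
        skew = p[i]
        i += 1
    if estimate_distortion:
        k1, k2 = p[i], p[i + 1]
        i += 2
    intr = CameraIntrinsics(fx=fx, fy=fy, cx=cx, cy=cy, skew=skew, k1=k1, k2=k2)
    poses = []
    for v in range(n_views):
        rv = p[i + 6 * v: i + 6 * v + 3]
        t = p[i + 6 * v + 3: i + 6 * v + 6]
        poses.append(CameraPose(rotation=Rotation.from_rotvec(rv).as_matrix(), translation=t))
    return intr, poses


def calibrate_planar(views: list[tuple[BoardSpec, np.ndarray]],
                     estimate_distortion: bool = False,
                     estimate_skew: bool = False) -> CalibrationResult:
    """Zhang-style planar calibration from checkerboard corner grids.

    Parameters
    ----------
    views : list of (BoardSpec, corners)
        One entry per view; ``corners`` is an (n_corners, 2) pixel array in
        the board's row-major corner order. All views must share one board.
    estimate_distortion : bool
        Also estimate radial k1, k2 during refinement (off by default).
    estimate_skew : bool
        Also estimate the skew term (off by default; skew fixed at 0).
    """
    if len(views) < 3:
        raise CalibrationError(f"planar calibration needs >= 3 views, got {len(views)}")
    board = views[0][0]
    if any(b != board for b, _ in views):
        raise CalibrationError("all views must observe the same board")
    obj2d = board.object_points()
    corners = [np.asarray(c, dtype=float).reshape(-1, 2) for _, c in views]
    for c in corners:
        if len(c) != board.n_corners:
            raise CalibrationError("each view must contain the full corner grid")
    Hs = [estimate_homography(obj2d, c) for c in corners]
    intr0 = _intrinsics_from_homographies(Hs, fix_skew=not estimate_skew)
    poses0 = [_pose_from_homography(H, intr0.K) for H in Hs]

    obj3d = np.column_stack([obj2d, np.zeros(len(obj2d))])
    observed = np.concatenate(corners, axis=0)

    def residuals(p: np.ndarray) -> np.ndarray:
        intr, poses = _unpack_params(p, len(views), estimate_skew, estimate_distortion)
        preds = [project_points(obj3d, CameraModel(intr, pose)) for pose in poses]
        return (np.concatenate(preds, axis=0) - observed).ravel()

    p0 = _pack_params(intr0, poses0, estimate_skew, estimate_distortion)
    r0 = residuals(p0)
    initial_cost = float(r0 @ r0)
    sol = least_squares(residuals, p0, method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    final_cost = float(2 * sol.cost)
    if final_cost > initial_cost * (1 + 1e-9):
        raise CalibrationError("refinement increased the reprojection cost")
    intr, poses = _unpack_params(sol.x, len(views), estimate_skew, estimate_distortion)
    resid = sol.fun.reshape(-1, 2)
    per_point = np.linalg.norm(resid, axis=1)
    rms = float(np.sqrt(np.mean(per_point**2)))
    per_view = np.sqrt(np.mean(per_point.reshape(len(views), -1) ** 2, axis=1))
    return CalibrationResult(intrinsics=intr, view_poses=poses, rms_px=rms,
                             per_view_rms_px=per_view, initial_cost=initial_cost,
                             final_cost=final_cost, n_views=len(views))


# ---------------------------------------------------------------------------
# stereo extrinsics

def _board_pose_in_camera(corners: np.ndarray, intr: CameraIntrinsics,
                          board: BoardSpec) -> CameraPose:
    pix = undistort_points(corners, intr)
    ideal = CameraIntrinsics(intr.fx, intr.fy, intr.cx, intr.cy, intr.skew)
    H = estimate_homography(board.object_points(), pix)
    pose0 = _pose_from_homography(H, ideal.K)

    # refine the single-view pose on reprojection error (closed form is seed)
    obj3d = np.column_stack([board.object_points(), np.zeros(board.n_corners)])

    def resid(p):
        pose = CameraPose(Rotation.from_rotvec(p[:3]).as_matrix(), p[3:])
        return (project_points(obj3d, CameraModel(ideal, pose)) - pix).ravel()

    p0 = np.concatenate([Rotation.from_matrix(pose0.rotation).as_rotvec(), pose0.translation])
    sol = least_squares(resid, p0, method="lm", xtol=1e-12, ftol=1e-12)
    return CameraPose(Rotation.from_rotvec(sol.x[:3]).as_matrix(), sol.x[3:])


def solve_stereo_extrinsics(shared_views: list[tuple[np.ndarray, np.ndarray]],
                            intr_a: CameraIntrinsics, intr_b: CameraIntrinsics,
                            board: BoardSpec,
                            image_size_a: tuple[int, int] = (0, 0),
                            image_size_b: tuple[int, int] = (0, 0),
                            world_units: str = "mm") -> StereoRig:
    """Place two calibrated cameras in one world frame from shared board views.

    The world frame is anchored to the first shared view: board origin =
    world origin, board plane = z = 0. With several shared views the
    relative pose is averaged (rotation: chordal quaternion mean;
    translation: arithmetic mean) and the residual spread is recorded in
    ``rig.meta``.
    """
    if not shared_views:
        raise CalibrationError("no shared board view between the cameras")
    poses_a = [_board_pose_in_camera(ca, intr_a, board) for ca, _ in shared_views]
    poses_b = [_board_pose_in_camera(cb, intr_b, board) for _, cb in shared_views]
    rel_R = [pb.rotation @ pa.rotation.T for pa, pb in zip(poses_a, poses_b)]
    rel_t = [pb.translation - R @ pa.translation
             for pa, pb, R in zip(poses_a, poses_b, rel_R)]
    R_mean = Rotation.from_matrix(np.stack(rel_R)).mean().as_matrix()
    t_mean = np.mean(rel_t, axis=0)
    rot_spread = max(
        float(np.degrees(np.linalg.norm(Rotation.from_matrix(R_mean.T @ R).as_rotvec())))
        for R in rel_R
    )
    t_spread = max(float(np.linalg.norm(t - t_mean)) for t in rel_t)

    pose_a0 = poses_a[0]
    pose_b = CameraPose(rotation=R_mean @ pose_a0.rotation,
                        translation=R_mean @ pose_a0.translation + t_mean)
    cam_a = CameraModel(intr_a, pose_a0, *image_size_a)
    cam_b = CameraModel(intr_b, pose_b, *image_size_b)
    meta = {"n_shared_views": len(shared_views),
            "rotation_spread_deg": rot_spread,
            "translation_spread": t_spread}
    return StereoRig(camera_a=cam_a, camera_b=cam_b, world_units=world_units, meta=meta)


# ---------------------------------------------------------------------------
# triangulation

def _ideal_projection_matrix(cam: CameraModel) -> np.ndarray:
    intr = cam.intrinsics
    K = CameraIntrinsics(intr.fx, intr.fy, intr.cx, intr.cy, intr.skew).K
    return K @ np.column_stack([cam.pose.rotation, cam.pose.translation])


def triangulate_points(uv_a: np.ndarray, uv_b: np.ndarray, rig: StereoRig) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-view linear triangulation.

    Returns (world points (n, 3), mean reprojection residual per point in px).
    Points whose homogeneous solution is at infinity (near-parallel rays)
    come back as NaN rows with infinite residual.
    """
    uv_a = np.atleast_2d(np.asarray(uv_a, dtype=float))
    uv_b = np.atleast_2d(np.asarray(uv_b, dtype=float))
    pa = undistort_points(uv_a, rig.camera_a.intrinsics)
    pb = undistort_points(uv_b, rig.camera_b.intrinsics)
    Pa = _ideal_projection_matrix(rig.camera_a)
    Pb = _ideal_projection_matrix(rig.camera_b)
    n = len(pa)
    A = np.empty((n, 4, 4))
    A[:, 0] = pa[:, 0:1] * Pa[2] - Pa[0]
    A[:, 1] = pa[:, 1:2] * Pa[2] - Pa[1]
    A[:, 2] = pb[:, 0:1] * Pb[2] - Pb[0]
    A[:, 3] = pb[:, 1:2] * Pb[2] - Pb[1]
    _, _, Vt = np.linalg.svd(A)
    X = Vt[:, -1, :]
    w = X[:, 3]
    scale = np.linalg.norm(X[:, :3], axis=1) + 1e-300
    at_infinity = np.abs(w) < 1e-10 * scale
    pts = np.full((n, 3), np.nan)
    good = ~at_infinity
    pts[good] = X[good, :3] / w[good, None]
    resid = np.full(n, np.inf)
    if good.any():
        ra = np.linalg.norm(_reproject_ideal(pts[good], rig.camera_a) - pa[good], axis=1)
        rb = np.linalg.norm(_reproject_ideal(pts[good], rig.camera_b) - pb[good], axis=1)
        resid[good] = (ra + rb) / 2.0
    return pts, resid


def _reproject_ideal(points: np.ndarray, cam: CameraModel) -> np.ndarray:
    X = cam.pose.transform(points)
    depth = X[:, 2]
    depth = np.where(np.abs(depth) < 1e-300, 1e-300, depth)
    xy = X[:, :2] / depth[:, None]
    intr = cam.intrinsics
    u = intr.fx * xy[:, 0] + intr.skew * xy[:, 1] + intr.cx
    v = intr.fy * xy[:, 1] + intr.cy
    return np.stack([u, v], axis=1)


def triangulate(pa: PixelPoint, pb: PixelPoint, rig: StereoRig) -> tuple[np.ndarray, float]:
    """Triangulate one stereo correspondence; returns (world point, residual px)."""
    pts, resid = triangulate_points(np.array([[pa.u, pa.v]]), np.array([[pb.u, pb.v]]), rig)
    if np.isnan(pts[0]).any():
        raise GeometryError(f"near-parallel rays for ({pa}, {pb})")
    return pts[0], float(resid[0])


def reprojection_rms(correspondences: list[tuple[CameraModel, np.ndarray, np.ndarray]]) -> float:
    """RMS pixel error over (camera, world points, observed pixels) groups."""
    if not correspondences:
        raise ValueError("empty correspondence set")
    sq = []
    for cam, world, observed in correspondences:
        pred = project_points(np.asarray(world, dtype=float),
                              cam)
        d = np.linalg.norm(pred - np.asarray(observed, dtype=float).reshape(-1, 2), axis=1)
        sq.append(d**2)
    return float(np.sqrt(np.mean(np.concatenate(sq))))


# ---------------------------------------------------------------------------
# rig JSON I/O

def _intr_to_dict(i: CameraIntrinsics) -> dict:
    return {"fx": i.fx, "fy": i.fy, "cx": i.cx, "cy": i.cy,
            "skew": i.skew, "k1": i.k1, "k2": i.k2}


def _cam_to_dict(c: CameraModel) -> dict:
    return {
        "intrinsics": _intr_to_dict(c.intrinsics),
        "rotation": c.pose.rotation.tolist(),
        "translation": c.pose.translation.tolist(),
        "image_width": c.image_width,
        "image_height": c.image_height,
    }


def _cam_from_dict(d: dict) -> CameraModel:
    return CameraModel(
        intrinsics=CameraIntrinsics(**d["intrinsics"]),
        pose=CameraPose(rotation=np.asarray(d["rotation"]), translation=np.asarray(d["translation"])),
        image_width=d.get("image_width", 0),
        image_height=d.get("image_height", 0),
    )


def save_rig(rig: StereoRig, path: str | Path) -> None:
    doc = {
        "format": "behavekin-rig v1",
        "world_units": rig.world_units,
        "camera_a": _cam_to_dict(rig.camera_a),
        "camera_b": _cam_to_dict(rig.camera_b),
        "meta": rig.meta,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_rig(path: str | Path) -> StereoRig:
    doc = json.loads(Path(path).read_text())
    return StereoRig(
        camera_a=_cam_from_dict(doc["camera_a"]),
        camera_b=_cam_from_dict(doc["camera_b"]),
        world_units=doc.get("world_units", "mm"),
        meta=doc.get("meta", {}),
    )
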