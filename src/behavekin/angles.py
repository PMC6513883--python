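"""3D joint angles from multi-keypoint pose trajectories.

Covers the angles used in upper-limb reach analysis: the generic
three-point angle (e.g. elbow = shoulder-elbow-wrist), the shoulder-vs-body
angle (trunk axis mid_hip->neck against the upper-arm vector
shoulder->elbow), and the supination angle -- the signed rotation of the
hand about the forearm axis, operationalized as the rotation of the
palm-breadth vector (index_mcp - pinky_mcp) projected into the plane
normal to the forearm, relative to its direction at a reference frame.

All angles are in degrees; three-point angles lie in [0, 180]; supination
series are signed and unwrapped over time so consecutive frames never jump
by more than 180 deg. A frame missing any required joint yields NaN (a
gap), never an exception.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "PoseSequence",
    "AngleSeries",
    "three_point_angle",
    "vector_angle",
    "elbow_angle_series",
    "shoulder_body_angle_series",
    "supination_angle_series",
    "angular_velocity",
]

EPS = 1e-9

#: Joint naming convention (25-keypoint body layout + hand MCPs):
#: neck, mid_hip, {r,l}_shoulder, {r,l}_elbow, {r,l}_wrist,
#: {r,l}_index_mcp, {r,l}_pinky_mcp.
SIDES = {"right": "r", "left": "l"}


@dataclass
class PoseSequence:
    """Per-frame 3D joint positions; each joint is an (n, 3) array, NaN = gap."""

    fps: float
    frames: np.ndarray
    joints: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        n = len(self.frames)
        for name, arr in self.joints.items():
            arr = np.asarray(arr, dtype=float).reshape(-1, 3)
            if len(arr) != n:
                raise ValueError(f"joint {name!r} has {len(arr)} frames, expected {n}")
            self.joints[name] = arr

    def __len__(self) -> int:
        return len(self.frames)

    def joint(self, name: str) -> np.ndarray:
        if name not in self.joints:
            raise KeyError(f"joint {name!r} not present (have {sorted(self.joints)})")
        return self.joints[name]


@dataclass
class AngleSeries:
    fps: float
    frames: np.ndarray
    values: np.ndarray  # degrees, NaN = gap
    angle_kind: str

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def three_point_angle(a, b, c) -> float:
    """Angle at ``b`` between rays b->a and b->c, in degrees [0, 180].

    Computed via atan2(‖u x v‖, u.v) for stability near 0 and 180. A
    degenerate limb (either ray shorter than 1e-9) returns NaN with a
    warning rather than raising.
    """
    u = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    v = np.asarray(c, dtype=float) - np.asarray(b, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if not np.isfinite(nu) or not np.isfinite(nv):
        return float("nan")
    if nu <= EPS or nv <= EPS:
        warnings.warn("degenerate limb segment in three-point angle", stacklevel=2)
        return float("nan")
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v))))


def vector_angle(u, v) -> float:
    """Angle between two free vectors in degrees [0, 180]; NaN if degenerate."""
    return three_point_angle(u, (0.0, 0.0, 0.0), v)


def _series(poses: PoseSequence, fn, kind: str) -> AngleSeries:
    vals = np.array([fn(i) for i in range(len(poses))], dtype=float)
    return AngleSeries(fps=poses.fps, frames=poses.frames.copy(), values=vals, angle_kind=kind)


def elbow_angle_series(poses: PoseSequence, side: str = "right") -> AngleSeries:
    """Arm-vs-forearm angle: three_point_angle(shoulder, elbow, wrist) per frame."""
    p = SIDES[side]
    sh = poses.joint(f"{p}_shoulder")
    el = poses.joint(f"{p}_elbow")
    wr = poses.joint(f"{p}_wrist")

    def fn(i: int) -> float:
        row = np.concatenate([sh[i], el[i], wr[i]])
        if np.isnan(row).any():
            return float("nan")
        return three_point_angle(sh[i], el[i], wr[i])

    return _series(poses, fn, f"elbow_{side}")


def shoulder_body_angle_series(poses: PoseSequence, side: str = "right") -> AngleSeries:
    """Angle between the trunk axis (mid_hip->neck) and the upper arm
    (shoulder->elbow), as free vectors in [0, 180]."""
    p = SIDES[side]
    neck = poses.joint("neck")
    hip = poses.joint("mid_hip")
    sh = poses.joint(f"{p}_shoulder")
    el = poses.joint(f"{p}_elbow")

    def fn(i: int) -> float:
        row = np.concatenate([neck[i], hip[i], sh[i], el[i]])
        if np.isnan(row).any():
            return float("nan")
        return vector_angle(neck[i] - hip[i], el[i] - sh[i])

    return _series(poses, fn, f"shoulder_body_{side}")


def _palm_perp(wrist: np.ndarray, elbow: np.ndarray, index_mcp: np.ndarray,
               pinky_mcp: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    f = wrist - elbow
    nf = np.linalg.norm(f)
    if nf <= EPS:
        return None
    f = f / nf
    h = index_mcp - pinky_mcp
    h_perp = h - np.dot(h, f) * f
    if np.linalg.norm(h_perp) <= EPS:
        return None
    return f, h_perp / np.linalg.norm(h_perp)


def _minimal_rotation(f0: np.ndarray, f1: np.ndarray) -> Rotation:
    """Smallest rotation carrying unit vector f0 onto f1 (identity if equal)."""
    c = np.cross(f0, f1)
    d = float(np.clip(np.dot(f0, f1), -1.0, 1.0))
    s = np.linalg.norm(c)
    if s <= EPS:
        if d > 0:
            return Rotation.identity()
        # antiparallel: rotate 180 deg about any axis normal to f0
        axis = np.cross(f0, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) <= EPS:
            axis = np.cross(f0, [0.0, 1.0, 0.0])
        axis = axis / np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis)
    axis = c / s
    angle = np.arctan2(s, d)
    return Rotation.from_rotvec(angle * axis)


def supination_angle_series(poses: PoseSequence, side: str = "right",
                            reference_frame_policy: str | int = "first_valid") -> AngleSeries:
    """Signed forearm rotation angle from elbow/wrist/index_mcp/pinky_mcp.

    Per frame, the palm-breadth vector h = index_mcp - pinky_mcp is
    projected into the plane normal to the forearm axis f = wrist - elbow.
    The reference direction (same construction at the reference frame) is
    parallel-transported into the current frame's plane by the minimal
    rotation carrying the reference forearm axis onto the current one; the
    reported angle is the signed angle from the transported reference to
    h_perp, by the right-hand rule about f, then unwrapped over time so
    consecutive valid frames differ by less than 180 deg.

    ``reference_frame_policy`` is either ``"first_valid"`` or an explicit
    frame index whose geometry defines angle zero.
    """
    p = SIDES[side]
    el = poses.joint(f"{p}_elbow")
    wr = poses.joint(f"{p}_wrist")
    im = poses.joint(f"{p}_index_mcp")
    pm = poses.joint(f"{p}_pinky_mcp")
    n = len(poses)

    geom: list[tuple[np.ndarray, np.ndarray] | None] = []
    for i in range(n):
        row = np.concatenate([el[i], wr[i], im[i], pm[i]])
        if np.isnan(row).any():
            geom.append(None)
            continue
        g = _palm_perp(wr[i], el[i], im[i], pm[i])
        if g is None:
            warnings.warn(f"palm parallel to forearm axis at frame {poses.frames[i]}",
                          stacklevel=2)
        geom.append(g)

    if reference_frame_policy == "first_valid":
        ref_idx = next((i for i, g in enumerate(geom) if g is not None), None)
    else:
        ref_idx = int(reference_frame_policy)
        ref_idx = int(np.searchsorted(poses.frames, ref_idx))
        if ref_idx >= n or geom[ref_idx] is None:
            raise ValueError("reference frame has no valid hand geometry")
    vals = np.full(n, np.nan)
    if ref_idx is None:
        return AngleSeries(poses.fps, poses.frames.copy(), vals, f"supination_{side}")
    f_ref, h_ref = geom[ref_idx]

    for i in range(n):
        if geom[i] is None:
            continue
        f, h = geom[i]
        r = _minimal_rotation(f_ref, f).apply(h_ref)
        r = r - np.dot(r, f) * f
        nr = np.linalg.norm(r)
        if nr <= EPS:
            continue
        r = r / nr
        vals[i] = np.degrees(np.arctan2(np.dot(np.cross(r, h), f), np.dot(r, h)))

    # unwrap across gaps: only consecutive valid samples constrain each other
    valid = np.flatnonzero(~np.isnan(vals))
    if len(valid) > 1:
        vals[valid] = np.degrees(np.unwrap(np.radians(vals[valid])))
    return AngleSeries(poses.fps, poses.frames.copy(), vals, f"supination_{side}")


def angular_velocity(series: AngleSeries) -> AngleSeries:
    """Signed central-difference derivative of an angle series, deg/s."""
    n = len(series)
    vals = series.values
    out = np.full(n, np.nan)
    for i in range(n):
        if np.isnan(vals[i]):
            continue
        prev_ok = i > 0 and not np.isnan(vals[i - 1])
        next_ok = i < n - 1 and not np.isnan(vals[i + 1])
        if prev_ok and next_ok:
            df = series.frames[i + 1] - series.frames[i - 1]
            out[i] = (vals[i + 1] - vals[i - 1]) * series.fps / df
        elif next_ok:
            df = series.frames[i + 1] - series.frames[i]
            out[i] = (vals[i + 1] - vals[i]) * series.fps / df
        elif prev_ok:
            df = series.frames[i] - series.frames[i - 1]
            out[i] = (vals[i] - vals[i - 1]) * series.fps / df
    return AngleSeries(series.fps, series.frames.copy(), out,
                       f"{series.angle_kind}_velocity")
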