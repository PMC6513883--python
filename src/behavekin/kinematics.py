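"""Reach kinematics: stereo detections -> gap-aware 3D trajectories -> metrics.

Pipeline: :func:`build_trajectory3d` triangulates per-frame detection pairs
into a dense :class:`~behavekin.trajectory.Trajectory3D`;
:func:`interpolate_gaps` fills short occlusion gaps; :func:`smooth` applies
a centered moving average; :func:`speed_series` differentiates; reaches are
segmented by hysteresis thresholding of the speed and summarized per reach
(distance traveled, duration, peak and mean speed, path-length ratio,
velocity-peak count).

"Velocity" in summaries and plots is the scalar speed ‖dp/dt‖; the vector
derivative is available via :func:`velocity_vectors`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .detections import DetectionTable
from .geometry import StereoRig, triangulate_points
from .trajectory import Trajectory3D, gap_runs, is_gap

__all__ = [
    "SpeedSeries",
    "ReachInterval",
    "KinematicSummary",
    "build_trajectory3d",
    "interpolate_gaps",
    "smooth",
    "speed_series",
    "velocity_vectors",
    "segment_reaches",
    "kinematic_summary",
    "write_reach_summary_csv",
]

#: Sentinel reported when the path-length ratio denominator (net displacement)
#: is below threshold; avoids propagating infinities into summary tables.
UNDEFINED_RATIO = float("nan")


@dataclass
class SpeedSeries:
    """Per-frame scalar speed aligned to a trajectory; NaN where undefined."""

    fps: float
    frames: np.ndarray
    values: np.ndarray  # mm/s, NaN = gap

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if (finite < 0).any():
            raise ValueError("speeds must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ReachInterval:
    """Half-open [onset_frame, offset_frame) interval of one reach."""

    onset_frame: int
    offset_frame: int
    peak_speed: float

    def __post_init__(self) -> None:
        if self.onset_frame >= self.offset_frame:
            raise ValueError("reach onset must precede offset")


@dataclass
class KinematicSummary:
    distance_traveled: float  # mm
    duration: float  # s
    max_speed: float  # mm/s
    mean_speed: float  # mm/s
    path_length_ratio: float  # >= 1, NaN when displacement ~ 0
    n_velocity_peaks: int
    n_onsets: int


def build_trajectory3d(table_a: DetectionTable, table_b: DetectionTable, label: str,
                       rig: StereoRig, conf_min: float = 0.5,
                       residual_max: float = float("inf"),
                       camera_id_a: str | None = None,
                       camera_id_b: str | None = None,
                       fps: float = 124.0, units: str = "mm") -> Trajectory3D:
    """Triangulate matching detections of one label into a dense trajectory.

    A frame contributes a 3D sample only if both cameras detected the part
    with confidence >= ``conf_min`` and the triangulation's reprojection
    residual is <= ``residual_max`` px; every other frame in the covered
    range is a gap. Box detections are reduced to their centers. The sample
    confidence is the minimum of the two view confidences.
    """
    ca = table_a.centers(camera_id_a, label)
    cb = table_b.centers(camera_id_b, label)
    if ca.empty or cb.empty:
        raise ValueError(f"label {label!r} absent from one of the detection tables")
    lo = int(min(ca.index.min(), cb.index.min()))
    hi = int(max(ca.index.max(), cb.index.max()))
    frames = np.arange(lo, hi + 1)
    points = np.full((len(frames), 3), np.nan)
    conf = np.zeros(len(frames))

    both = ca.join(cb, how="inner", lsuffix="_a", rsuffix="_b")
    both = both[(both["confidence_a"] >= conf_min) & (both["confidence_b"] >= conf_min)]
    if not both.empty:
        uva = both[["u_a", "v_a"]].to_numpy()
        uvb = both[["u_b", "v_b"]].to_numpy()
        pts, resid = triangulate_points(uva, uvb, rig)
        keep = resid <= residual_max
        idx = both.index.to_numpy(dtype=int)[keep] - lo
        points[idx] = pts[keep]
        conf[idx] = np.minimum(both["confidence_a"].to_numpy(),
                               both["confidence_b"].to_numpy())[keep]
    return Trajectory3D(label=label, fps=fps, frames=frames, points=points,
                        confidence=conf, units=units)


def interpolate_gaps(traj: Trajectory3D, max_gap_frames: int = 5) -> Trajectory3D:
    """Linearly fill interior gap runs no longer than ``max_gap_frames``.

    Boundary gaps and longer runs are left untouched. Filled samples get
    confidence 0 so downstream code can tell them from measured ones.
    """
    out = traj.copy()
    mask = out.gap_mask
    n = len(out)
    for start, stop in gap_runs(mask):
        if start == 0 or stop == n:  # boundary gaps are never extrapolated
            continue
        if stop - start > max_gap_frames:
            continue
        p0, p1 = out.points[start - 1], out.points[stop]
        f0, f1 = out.frames[start - 1], out.frames[stop]
        for i in range(start, stop):
            w = (out.frames[i] - f0) / (f1 - f0)
            out.points[i] = (1 - w) * p0 + w * p1
            out.confidence[i] = 0.0
    return out


def smooth(traj: Trajectory3D, window_frames: int = 5) -> Trajectory3D:
    """Centered moving average per coordinate; gaps excluded and preserved."""
    if window_frames < 1 or window_frames % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if window_frames == 1:
        return traj.copy()
    out = traj.copy()
    half = window_frames // 2
    mask = traj.gap_mask
    pts = traj.points
    n = len(traj)
    smoothed = pts.copy()
    for i in range(n):
        if mask[i]:
            continue
        lo, hi = max(0, i - half), min(n, i + half + 1)
        window = pts[lo:hi][~mask[lo:hi]]
        smoothed[i] = window.mean(axis=0)
    out.points = smoothed
    return out


def _speed_values(frames: np.ndarray, pts: np.ndarray, fps: float) -> np.ndarray:
    n = len(frames)
    mask = is_gap(pts)
    speed = np.full(n, np.nan)
    for i in range(n):
        if mask[i]:
            continue
        prev_ok = i > 0 and not mask[i - 1]
        next_ok = i < n - 1 and not mask[i + 1]
        if prev_ok and next_ok:
            df = frames[i + 1] - frames[i - 1]
            speed[i] = np.linalg.norm(pts[i + 1] - pts[i - 1]) * fps / df
        elif next_ok:
            df = frames[i + 1] - frames[i]
            speed[i] = np.linalg.norm(pts[i + 1] - pts[i]) * fps / df
        elif prev_ok:
            df = frames[i] - frames[i - 1]
            speed[i] = np.linalg.norm(pts[i] - pts[i - 1]) * fps / df
    return speed


def speed_series(traj: Trajectory3D) -> SpeedSeries:
    """Scalar speed by central difference: ‖p(i+1) − p(i−1)‖·fps/2 on interior
    non-gap triples, one-sided at the ends, NaN where neighbors are missing."""
    return SpeedSeries(fps=traj.fps, frames=traj.frames.copy(),
                       values=_speed_values(traj.frames, traj.points, traj.fps))


def velocity_vectors(traj: Trajectory3D) -> np.ndarray:
    """(n, 3) central-difference velocity in units/s; NaN rows at gaps/edges."""
    n = len(traj)
    mask = traj.gap_mask
    vel = np.full((n, 3), np.nan)
    for i in range(1, n - 1):
        if mask[i] or mask[i - 1] or mask[i + 1]:
            continue
        df = traj.frames[i + 1] - traj.frames[i - 1]
        vel[i] = (traj.points[i + 1] - traj.points[i - 1]) * traj.fps / df
    return vel


def segment_reaches(speed: SpeedSeries, v_on: float, v_off: float,
                    min_duration_s: float = 0.1,
                    merge_gap_s: float = 0.05) -> list[ReachInterval]:
    """Hysteresis segmentation of movement bouts from a speed series.

    A bout opens when the speed rises above ``v_on`` and closes when it
    falls below ``v_off`` (v_on >= v_off > 0). Bouts separated by less than
    ``merge_gap_s`` are merged, then bouts shorter than ``min_duration_s``
    are dropped. NaN samples count as below threshold.
    """
    if not v_on >= v_off > 0:
        raise ValueError("thresholds must satisfy v_on >= v_off > 0")
    vals = np.nan_to_num(speed.values, nan=0.0)
    intervals: list[list[int]] = []
    active = False
    onset = 0
    for i, v in enumerate(vals):
        if not active and v > v_on:
            active = True
            onset = i
        elif active and v < v_off:
            intervals.append([onset, i])
            active = False
    if active:
        intervals.append([onset, len(vals)])

    merge_gap = merge_gap_s * speed.fps
    merged: list[list[int]] = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] < merge_gap:
            merged[-1][1] = iv[1]
        else:
            merged.append(iv)

    min_len = min_duration_s * speed.fps
    out = []
    for a, b in merged:
        if b - a >= min_len:
            peak = float(np.nanmax(speed.values[a:b]))
            out.append(ReachInterval(onset_frame=int(speed.frames[a]),
                                     offset_frame=int(speed.frames[min(b, len(vals) - 1)]),
                                     peak_speed=peak))
    return out


def kinematic_summary(traj: Trajectory3D, interval: ReachInterval,
                      v_off: float | None = None,
                      peak_smooth_window: int = 5) -> KinematicSummary:
    """Per-reach kinematics over ``[onset_frame, offset_frame]``.

    distance = sum of consecutive non-gap segment lengths; duration =
    (offset − onset)/fps; max/mean of the speed series over the interval;
    path_length_ratio = distance / net displacement (NaN when the
    displacement is < 1e-9); n_velocity_peaks counts strict local maxima of
    the smoothed speed above ``v_off`` (default: 10% of the interval's peak
    speed); n_onsets counts upward crossings of ``v_off``.
    """
    sel = (traj.frames >= interval.onset_frame) & (traj.frames <= interval.offset_frame)
    frames = traj.frames[sel]
    pts = traj.points[sel]
    mask = is_gap(pts)
    good = pts[~mask]
    if len(good) < 2:
        raise ValueError("interval holds fewer than 2 non-gap samples")

    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    distance = float(np.nansum(np.where(~(mask[:-1] | mask[1:]), steps, 0.0)))
    duration = (interval.offset_frame - interval.onset_frame) / traj.fps

    speeds = _speed_values(frames, pts, traj.fps)
    max_speed = float(np.nanmax(speeds))
    mean_speed = float(np.nanmean(speeds))
    if v_off is None:
        v_off = 0.1 * max_speed

    displacement = float(np.linalg.norm(good[-1] - good[0]))
    ratio = distance / displacement if displacement > 1e-9 else UNDEFINED_RATIO

    # peak counting on a mildly smoothed speed to avoid counting jitter
    sm = pd.Series(speeds).rolling(peak_smooth_window, center=True, min_periods=1).mean().to_numpy()
    eps = 1e-9 * max(max_speed, 1.0)  # float-jitter guard for plateaus
    n_peaks = _count_plateau_peaks(sm, v_off, eps)
    if n_peaks == 0 and np.nanmax(sm) > v_off:
        n_peaks = 1  # monotone or plateau profile still has one burst
    above = np.nan_to_num(sm, nan=0.0) > v_off
    n_onsets = int(np.sum(above[1:] & ~above[:-1]) + int(above[0]))
    return KinematicSummary(
        distance_traveled=distance,
        duration=duration,
        max_speed=max_speed,
        mean_speed=mean_speed,
        path_length_ratio=ratio,
        n_velocity_peaks=n_peaks,
        n_onsets=n_onsets,
    )


def _count_plateau_peaks(values: np.ndarray, floor: float, eps: float) -> int:
    """Local maxima above ``floor``, treating near-equal runs as one peak."""
    n_peaks = 0
    i = 0
    n = len(values)
    while i < n:
        if np.isnan(values[i]) or values[i] <= floor:
            i += 1
            continue
        j = i
        while j + 1 < n and not np.isnan(values[j + 1]) and abs(values[j + 1] - values[i]) <= eps:
            j += 1
        left_lower = i > 0 and not np.isnan(values[i - 1]) and values[i - 1] < values[i] - eps
        right_lower = j + 1 < n and not np.isnan(values[j + 1]) and values[j + 1] < values[j] - eps
        if left_lower and right_lower:
            n_peaks += 1
        i = j + 1
    return n_peaks


def write_reach_summary_csv(traj: Trajectory3D, intervals: list[ReachInterval],
                            path: str | Path, v_off: float | None = None) -> pd.DataFrame:
    """One summary row per reach interval; returns the DataFrame written."""
    rows = []
    for i, iv in enumerate(intervals):
        s = kinematic_summary(traj, iv, v_off=v_off)
        rows.append({
            "reach": i,
            "onset_frame": iv.onset_frame,
            "offset_frame": iv.offset_frame,
            "onset_s": iv.onset_frame / traj.fps,
            "peak_speed": iv.peak_speed,
            "distance_traveled": s.distance_traveled,
            "duration": s.duration,
            "max_speed": s.max_speed,
            "mean_speed": s.mean_speed,
            "path_length_ratio": s.path_length_ratio,
            "n_velocity_peaks": s.n_velocity_peaks,
            "n_onsets": s.n_onsets,
        })
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.9g")
    return df


def build_pose_sequence(table_a: DetectionTable, table_b: DetectionTable,
                        rig: StereoRig, joint_names: list[str],
                        conf_min: float = 0.5,
                        residual_max: float = float("inf"),
                        fps: float = 60.0):
    """Triangulate every named keypoint into a per-frame 3D pose sequence.

    Each joint label is lifted independently via :func:`build_trajectory3d`;
    frames missing a joint in either camera leave that joint as a gap.
    Returns an :class:`behavekin.angles.PoseSequence` on the union frame range.
    """
    from .angles import PoseSequence

    trajs = {}
    for name in joint_names:
        try:
            trajs[name] = build_trajectory3d(table_a, table_b, name, rig,
                                             conf_min=conf_min,
                                             residual_max=residual_max, fps=fps)
        except ValueError:
            trajs[name] = None
    valid = [t for t in trajs.values() if t is not None]
    if not valid:
        raise ValueError("none of the requested joints is present in both tables")
    lo = min(int(t.frames[0]) for t in valid)
    hi = max(int(t.frames[-1]) for t in valid)
    frames = np.arange(lo, hi + 1)
    joints = {}
    for name, t in trajs.items():
        arr = np.full((len(frames), 3), np.nan)
        if t is not None:
            arr[t.frames - lo] = t.points
        joints[name] = arr
    return PoseSequence(fps=fps, frames=frames, joints=joints)


# reach onset/offset defaults: ~100 ms minimum movement, 50 ms merge window
DEFAULT_SEGMENTATION = dict(min_duration_s=0.1, merge_gap_s=0.05)


def minimum_jerk_peak_speed(length: float, duration: float) -> float:
    """Analytic peak speed of a minimum-jerk point-to-point movement: 1.875 L/T."""
    return 1.875 * length / duration


def minimum_jerk_position(tau: np.ndarray | float) -> np.ndarray | float:
    """Normalized minimum-jerk position profile 10t^3 - 15t^4 + 6t^5 on [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5
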