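"""Seeded generators of ground-truthed synthetic sessions for every pipeline stage.

Everything the real apparatus would record -- stereo checkerboard views,
paw-reach detection files, two-mouse arena sessions, three-chamber visits,
human pose sessions with forearm rotations -- is emulated here with exact
ground truth, so the whole post-processing chain is testable without video
or a trained detector.

Conventions mirror the recording setups this toolbox targets: the mouse
reach rig runs two hardware-synced cameras at 124 fps and 448x460 px with a
short baseline; the human rig two cameras 62 inches (1574.8 mm) apart with
near-orthogonal optical axes at 1280x1024 px; top-view social assays run at
30 fps in a 45x45 cm (two-mouse) or 60x45 cm three-chamber arena. Limb
motion uses the minimum-jerk profile x(tau) = x0 + (xf-x0)(10 tau^3 -
15 tau^4 + 6 tau^5), whose analytic peak speed 1.875 L/T gives an oracle
for the kinematics stage. Detector imperfection is modeled as Gaussian
pixel noise on the emitted geometry plus per-frame per-camera dropout;
detection confidences are drawn uniformly from [0.6, 1.0], independent of
dropout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .detections import Detection, DetectionTable, PixelPoint, BoundingBox
from .geometry import (
    BoardSpec,
    CameraIntrinsics,
    CameraModel,
    CameraPose,
    GeometryError,
    StereoRig,
    project_points,
)
from .social import ArenaLayout, Track2D
from .trajectory import Trajectory3D

__all__ = [
    "ReachEvent",
    "ContactEvent",
    "VisitEvent",
    "RotationEvent",
    "SceneScript",
    "make_rig",
    "look_at_pose",
    "simulate_checkerboard_views",
    "CheckerboardViews",
    "read_corners_csv",
    "write_corners_csv",
    "simulate_reach_session",
    "ReachSession",
    "simulate_social_session",
    "SocialSession",
    "simulate_three_chamber",
    "ThreeChamberSession",
    "simulate_pose_session",
    "PoseSession",
    "KEYPOINT_LAYOUT",
    "default_reach_script",
    "default_social_script",
    "switch_social_script",
    "random_social_script",
    "default_rotation_script",
    "default_three_chamber_layout",
    "minimum_jerk",
]


# ---------------------------------------------------------------------------
# script events

@dataclass(frozen=True)
class ReachEvent:
    """Out-and-back reach: onset_s, outward length L (mm) and duration T (s),
    unit direction; the return stroke retraces the path over the same T."""

    onset_s: float
    length_mm: float
    duration_s: float
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)


@dataclass(frozen=True)
class ContactEvent:
    start_s: float
    end_s: float
    mode: str  # one of social.PAIR_PRIORITY


@dataclass(frozen=True)
class VisitEvent:
    cup: str
    start_s: float
    end_s: float


@dataclass(frozen=True)
class RotationEvent:
    """Sinusoidal supination/pronation about the forearm axis."""

    side: str  # "right" | "left"
    amplitude_deg: float
    period_s: float
    n_cycles: int
    start_s: float = 0.0
    sign: float = 1.0  # +1 supination-first, -1 pronation-first


@dataclass
class SceneScript:
    seed: int
    fps: float
    duration_s: float
    events: list = field(default_factory=list)
    noise_px: float = 0.0
    dropout_p: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")
        for ev in self.events:
            end = getattr(ev, "end_s", None)
            if end is None:
                if isinstance(ev, ReachEvent):
                    end = ev.onset_s + 2 * ev.duration_s
                elif isinstance(ev, RotationEvent):
                    end = ev.start_s + ev.n_cycles * ev.period_s
                else:
                    end = 0.0
            if end > self.duration_s + 1e-9:
                raise ValueError(f"event {ev} extends past the session duration")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


def minimum_jerk(tau: np.ndarray | float) -> np.ndarray | float:
    """Normalized minimum-jerk position profile on [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _smoothstep(tau: np.ndarray | float) -> np.ndarray | float:
    tau = np.clip(tau, 0.0, 1.0)
    return 3 * tau**2 - 2 * tau**3


# ---------------------------------------------------------------------------
# rigs

def look_at_pose(center, target, up=(0.0, 0.0, 1.0)) -> CameraPose:
    """World->camera pose for a camera at ``center`` looking at ``target``."""
    center = np.asarray(center, dtype=float)
    z = np.asarray(target, dtype=float) - center
    z = z / np.linalg.norm(z)
    x = np.cross(z, np.asarray(up, dtype=float))
    if np.linalg.norm(x) < 1e-9:
        x = np.cross(z, [0.0, 1.0, 0.0])
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])
    return CameraPose(rotation=R, translation=-R @ center)


#: Reach workspace center of the mouse preset (world mm); reaches start here.
MOUSE_WORKSPACE = np.zeros(3)
#: Torso reference of the human preset (world mm, z up).
HUMAN_TARGET = np.array([0.0, 0.0, 1200.0])


def make_rig(preset: str, seed: int = 0) -> StereoRig:
    """Ground-truth stereo rig for a named recording geometry.

    ``"mouse"``: 448x460 px cameras ~180 mm from the paw workspace with
    near-orthogonal optical axes. ``"human"``: 1280x1024 px cameras
    1574.8 mm (62 in) apart, near-orthogonal axes, ~1.1 m from the
    subject. A deterministic seed jitters positions (~2%) and focal
    lengths (~1%) so different seeds give distinct but valid rigs.
    """
    rng = np.random.default_rng(seed)

    def jit(scale):
        return 1.0 + scale * rng.uniform(-1, 1)

    if preset == "mouse":
        w, h = 448, 460
        f = 600.0
        d = 180.0
        target = MOUSE_WORKSPACE
        pos_a = np.array([0.0, -d * jit(0.02), 50.0 * jit(0.05)])
        pos_b = np.array([d * jit(0.02), 0.0, 50.0 * jit(0.05)])
    elif preset == "human":
        w, h = 1280, 1024
        f = 800.0
        baseline = 1574.8  # 62 inches
        d = baseline / np.sqrt(2.0)  # ~orthogonal axes as seen from the subject
        target = HUMAN_TARGET
        ang = np.radians(45.0)
        pos_a = target + d * jit(0.02) * np.array([-np.sin(ang), -np.cos(ang), 0.0])
        pos_b = target + d * jit(0.02) * np.array([np.sin(ang), -np.cos(ang), 0.0])
        pos_a[2] += 100.0 * rng.uniform(-1, 1)
        pos_b[2] += 100.0 * rng.uniform(-1, 1)
    else:
        raise ValueError(f"unknown rig preset {preset!r}")

    def cam(pos):
        intr = CameraIntrinsics(fx=f * jit(0.01), fy=f * jit(0.01),
                                cx=w / 2 + 5 * rng.uniform(-1, 1),
                                cy=h / 2 + 5 * rng.uniform(-1, 1))
        return CameraModel(intr, look_at_pose(pos, target), w, h)

    return StereoRig(camera_a=cam(pos_a), camera_b=cam(pos_b), world_units="mm",
                     meta={"preset": preset, "seed": int(seed),
                           "target": [float(v) for v in target]})


def _in_view(uv: np.ndarray, cam: CameraModel, margin: float = 2.0) -> np.ndarray:
    return ((uv[:, 0] >= margin) & (uv[:, 0] <= cam.image_width - margin)
            & (uv[:, 1] >= margin) & (uv[:, 1] <= cam.image_height - margin))


# ---------------------------------------------------------------------------
# checkerboard views

@dataclass
class CheckerboardViews:
    """Simulated corner observations plus ground truth."""

    board: BoardSpec
    rig: StereoRig
    corners_a: list[np.ndarray]
    corners_b: list[np.ndarray]
    board_to_world: list[tuple[np.ndarray, np.ndarray]]  # (R, t) board->world
    true_corners_a: list[np.ndarray]
    true_corners_b: list[np.ndarray]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_corners_csv(self.corners_a, self.board, out / "corners_a.csv")
        write_corners_csv(self.corners_b, self.board, out / "corners_b.csv")


def write_corners_csv(views: list[np.ndarray], board: BoardSpec, path: str | Path) -> None:
    """Calibration input format: one row per corner (view, row, col, u, v)."""
    lines = ["view,row,col,u,v"]
    for vi, corners in enumerate(views):
        grid = corners.reshape(board.n_rows, board.n_cols, 2)
        for r in range(board.n_rows):
            for c in range(board.n_cols):
                u, v = grid[r, c]
                lines.append(f"{vi},{r},{c},{float(u)!r},{float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_corners_csv(path: str | Path, board: BoardSpec) -> list[np.ndarray]:
    """Read corner views written by :func:`write_corners_csv`."""
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    views = []
    for _, sub in df.groupby("view", sort=True):
        grid = np.full((board.n_rows, board.n_cols, 2), np.nan)
        for _, row in sub.iterrows():
            grid[int(row["row"]), int(row["col"])] = (row["u"], row["v"])
        if np.isnan(grid).any():
            raise ValueError(f"{path}: incomplete corner grid in a view")
        views.append(grid.reshape(-1, 2))
    return views


def simulate_checkerboard_views(rig: StereoRig, board: BoardSpec, n_views: int,
                                noise_px: float = 0.0, seed: int = 0,
                                max_attempts: int = 1000) -> CheckerboardViews:
    """Random board poses whose full corner grid is visible in both cameras.

    Poses are sampled near the rig's workspace with tilts up to ~35 deg;
    a pose is kept only if every corner projects in-view and in front of
    both cameras. Observed corners get i.i.d. Gaussian pixel noise.
    """
    if n_views < 3:
        raise ValueError("need at least 3 views for calibration")
    rng = np.random.default_rng(seed)
    target = np.asarray(rig.meta.get("target", [0.0, 0.0, 0.0]), dtype=float)
    # aim boards roughly at the midpoint of the two camera centers
    mid = (rig.camera_a.pose.center + rig.camera_b.pose.center) / 2.0
    aim = mid - target
    aim = aim / np.linalg.norm(aim)
    base = _minimal_rotation_matrix(np.array([0.0, 0.0, 1.0]), aim)
    scale = np.linalg.norm(rig.camera_a.pose.center - target)
    obj = np.column_stack([board.object_points(), np.zeros(board.n_corners)])
    board_extent = np.array([(board.n_cols - 1), (board.n_rows - 1), 0.0]) * board.square_size / 2
    board_span = 2 * np.linalg.norm(board_extent)
    # shrink position jitter and tilt when the board is large relative to the view
    tightness = min(1.0, scale / max(board_span, 1e-9))
    pos_jitter = 0.25 * tightness
    tilt_max = 0.6 * min(1.0, tightness)

    views_a, views_b, poses, true_a, true_b = [], [], [], [], []
    attempts = 0
    while len(views_a) < n_views:
        attempts += 1
        if attempts > max_attempts:
            raise GeometryError(
                f"could not place board view {len(views_a) + 1} in both cameras "
                f"after {max_attempts} attempts")
        tilt = Rotation.from_rotvec(rng.uniform(-tilt_max, tilt_max, 3)).as_matrix()
        R = base @ tilt
        center = target + rng.uniform(-pos_jitter, pos_jitter, 3) * scale
        t = center - R @ board_extent
        world = obj @ R.T + t
        try:
            uva = project_points(world, rig.camera_a)
            uvb = project_points(world, rig.camera_b)
        except GeometryError:
            continue
        if not (_in_view(uva, rig.camera_a).all() and _in_view(uvb, rig.camera_b).all()):
            continue
        true_a.append(uva)
        true_b.append(uvb)
        views_a.append(uva + rng.normal(0, noise_px, uva.shape) if noise_px else uva.copy())
        views_b.append(uvb + rng.normal(0, noise_px, uvb.shape) if noise_px else uvb.copy())
        poses.append((R, t))
    return CheckerboardViews(board=board, rig=rig, corners_a=views_a, corners_b=views_b,
                             board_to_world=poses, true_corners_a=true_a,
                             true_corners_b=true_b)


def _minimal_rotation_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    c = np.cross(a, b)
    d = float(np.clip(np.dot(a, b), -1, 1))
    s = np.linalg.norm(c)
    if s < 1e-12:
        return np.eye(3) if d > 0 else Rotation.from_rotvec([np.pi, 0, 0]).as_matrix()
    axis = c / s
    return Rotation.from_rotvec(np.arctan2(s, d) * axis).as_matrix()


# ---------------------------------------------------------------------------
# reach sessions

def default_reach_script(seed: int = 0, n_reaches: int = 10, fps: float = 124.0,
                         length_mm: float = 40.0, duration_s: float = 0.25,
                         noise_px: float = 0.0, dropout_p: float = 0.0) -> SceneScript:
    """Standard reach session: ``n_reaches`` out-and-back reaches at 124 fps,
    one per second, directions jittered around an upward-forward axis."""
    rng = np.random.default_rng(seed)
    events = []
    for k in range(n_reaches):
        d = np.array([0.5, 0.5, 0.7]) + rng.uniform(-0.15, 0.15, 3)
        d = d / np.linalg.norm(d)
        events.append(ReachEvent(onset_s=0.5 + k * 1.0, length_mm=length_mm,
                                 duration_s=duration_s, direction=tuple(d)))
    return SceneScript(seed=seed, fps=fps, duration_s=0.5 + n_reaches * 1.0,
                       events=events, noise_px=noise_px, dropout_p=dropout_p)


@dataclass
class ReachSession:
    """Simulated reach recording: per-camera box records plus ground truth."""

    script: SceneScript
    rig: StereoRig
    truth: Trajectory3D  # noiseless 3D paw path
    intervals: list[tuple[int, int]]  # ground-truth (onset_frame, offset_frame)
    peak_speeds: list[float]  # analytic 1.875 L/T per reach
    records_a: list[dict]
    records_b: list[dict]
    box_px: float = 40.0

    def table(self, camera: str) -> DetectionTable:
        records = self.records_a if camera == "a" else self.records_b
        cam = self.rig.camera_a if camera == "a" else self.rig.camera_b
        dets = [
            Detection(camera, rec["_frame"], "paw",
                      BoundingBox(rec["x1"], rec["y1"], rec["x2"], rec["y2"]),
                      rec["conf"])
            for rec in records
        ]
        return DetectionTable(cam.image_width, cam.image_height, dets)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for cam, records in (("a", self.records_a), ("b", self.records_b)):
            clean = [{k: v for k, v in r.items() if not k.startswith("_")} for r in records]
            p = out / f"cam_{cam}.json"
            p.write_text(json.dumps(clean, indent=1))
            paths[cam] = p
        gt = {
            "fps": self.script.fps,
            "units": "mm",
            "intervals": [list(iv) for iv in self.intervals],
            "peak_speeds": self.peak_speeds,
            "points": [[None, None, None] if np.isnan(p).any() else list(map(float, p))
                       for p in self.truth.points],
        }
        gp = out / "ground_truth.json"
        gp.write_text(json.dumps(gt))
        paths["ground_truth"] = gp
        return paths


def simulate_reach_session(rig: StereoRig, script: SceneScript,
                           rest_point: np.ndarray | None = None,
                           box_px: float = 40.0) -> ReachSession:
    """Render a reach script to single-box detection records for both cameras.

    The paw rests at ``rest_point`` (the mouse workspace center by default)
    and performs one out-and-back minimum-jerk stroke per
    :class:`ReachEvent`. Emitted boxes are ``box_px`` squares centered on
    the projected paw with Gaussian pixel noise on the center, per-camera
    Bernoulli dropout, and confidences uniform in [0.6, 1.0].
    """
    rng = np.random.default_rng(script.seed)
    rest = MOUSE_WORKSPACE.copy() if rest_point is None else np.asarray(rest_point, float)
    t = script.times
    pos = np.tile(rest, (script.n_frames, 1))
    intervals: list[tuple[int, int]] = []
    peaks: list[float] = []
    for ev in script.events:
        if not isinstance(ev, ReachEvent):
            raise ValueError(f"reach sessions accept ReachEvent only, got {ev}")
        d = np.asarray(ev.direction, dtype=float)
        d = d / np.linalg.norm(d)
        tau_out = (t - ev.onset_s) / ev.duration_s
        tau_back = (t - ev.onset_s - ev.duration_s) / ev.duration_s
        out_mask = (tau_out >= 0) & (tau_out < 1)
        back_mask = (tau_back >= 0) & (tau_back <= 1)
        pos[out_mask] = rest + np.outer(minimum_jerk(tau_out[out_mask]), ev.length_mm * d)
        pos[back_mask] = rest + np.outer(1 - minimum_jerk(tau_back[back_mask]), ev.length_mm * d)
        onset_f = int(round(ev.onset_s * script.fps))
        offset_f = int(round((ev.onset_s + 2 * ev.duration_s) * script.fps))
        intervals.append((onset_f, offset_f))
        peaks.append(1.875 * ev.length_mm / ev.duration_s)

    uva = project_points(pos, rig.camera_a)
    uvb = project_points(pos, rig.camera_b)
    bad = ~(_in_view(uva, rig.camera_a) & _in_view(uvb, rig.camera_b))
    if bad.any():
        raise GeometryError(f"paw leaves a camera view at frames {np.flatnonzero(bad)[:10]}")

    half = box_px / 2.0

    def render(uv: np.ndarray) -> list[dict]:
        noisy = uv + rng.normal(0, script.noise_px, uv.shape) if script.noise_px else uv
        keep = rng.random(len(uv)) >= script.dropout_p
        conf = rng.uniform(0.6, 1.0, len(uv))
        records = []
        for i in np.flatnonzero(keep):
            u, v = noisy[i]
            records.append({
                "image": f"img_{i:06d}.png",
                "x1": float(u - half), "y1": float(v - half),
                "x2": float(u + half), "y2": float(v + half),
                "conf": round(float(conf[i]), 6),
                "_frame": int(i),
            })
        return records

    truth = Trajectory3D(label="paw", fps=script.fps,
                         frames=np.arange(script.n_frames), points=pos.copy(),
                         units="mm")
    return ReachSession(script=script, rig=rig, truth=truth, intervals=intervals,
                        peak_speeds=peaks, records_a=render(uva), records_b=render(uvb),
                        box_px=box_px)


# ---------------------------------------------------------------------------
# two-mouse social sessions

#: Rigid top-view mouse template: signed offsets (cm) of each part along the
#: heading axis from the body center.
MOUSE_TEMPLATE = {"nose": 4.0, "head": 2.0, "body": 0.0, "tail": -4.0}
SOCIAL_CLASSES = [f"mouse{m}_{part}" for m in "AB" for part in ("body", "nose", "head", "tail")]
#: Box sizes (cm) per part for emitted normalized-box detections.
PART_BOX_CM = {"body": 6.0, "head": 3.0, "nose": 1.6, "tail": 1.6}

# contact-pose geometry (cm): body-center separation and relative headings per
# mode, chosen so the named pair is ~1 cm apart and every other pair is > 3 cm
_CONTACT_POSES = {
    # mode: (center separation, heading_A_rel, heading_B_rel) where headings
    # are relative to the A->B direction (A at -sep/2, B at +sep/2 on that axis)
    "nose-nose": (9.0, 0.0, 180.0),
    "noseA-tailB": (9.0, 0.0, 0.0),
    "noseB-tailA": (9.0, 180.0, 180.0),
    "noseA-bodyB": (5.0, 0.0, 90.0),
    "noseB-bodyA": (5.0, 90.0, 180.0),
}


def default_social_script(seed: int = 0, fps: float = 30.0,
                          modes: tuple[str, ...] = ("nose-nose", "noseA-tailB",
                                                    "noseB-tailA", "noseA-bodyB"),
                          contact_s: float = 2.0, gap_s: float = 6.0,
                          noise_px: float = 0.0, dropout_p: float = 0.0) -> SceneScript:
    """One contact event per requested mode, well separated in time."""
    events = []
    tcur = 4.0
    for m in modes:
        events.append(ContactEvent(start_s=tcur, end_s=tcur + contact_s, mode=m))
        tcur += contact_s + gap_s
    return SceneScript(seed=seed, fps=fps, duration_s=tcur + 2.0, events=events,
                       noise_px=noise_px, dropout_p=dropout_p)


def random_social_script(seed: int = 0, fps: float = 30.0,
                         n_events: int = 4, noise_px: float = 0.0) -> SceneScript:
    """Randomized session: ``n_events`` contacts with seeded modes and timing."""
    rng = np.random.default_rng(seed)
    modes = list(_CONTACT_POSES)
    events = []
    tcur = 4.0 + rng.uniform(0, 2)
    for _ in range(n_events):
        dur = rng.uniform(1.0, 3.0)
        events.append(ContactEvent(start_s=round(tcur, 2), end_s=round(tcur + dur, 2),
                                   mode=modes[rng.integers(len(modes))]))
        tcur += dur + rng.uniform(5.0, 8.0)
    return SceneScript(seed=seed, fps=fps, duration_s=tcur + 2.0, events=events,
                       noise_px=noise_px)


def switch_social_script(seed: int = 0, fps: float = 30.0,
                         first: str = "noseB-tailA", second: str = "nose-nose",
                         noise_px: float = 0.0) -> SceneScript:
    """A single close contact that starts in one mode and turns into another
    (rear-sniffing turning into nose-to-nose)."""
    events = [ContactEvent(start_s=4.0, end_s=7.0, mode=first),
              ContactEvent(start_s=7.0, end_s=10.0, mode=second)]
    return SceneScript(seed=seed, fps=fps, duration_s=13.0, events=events,
                       noise_px=noise_px, dropout_p=0.0)


def _heading_unit(deg: float | np.ndarray) -> np.ndarray:
    rad = np.radians(deg)
    return np.stack([np.cos(rad), np.sin(rad)], axis=-1)


def _angle_lerp(a: float, b: float, w: np.ndarray) -> np.ndarray:
    """Shortest-path interpolation between two headings in degrees."""
    diff = (b - a + 180.0) % 360.0 - 180.0
    return a + diff * w


@dataclass
class SocialSession:
    script: SceneScript
    arena: tuple[float, float]
    px_per_cm: float
    truth_tracks: list[Track2D]
    truth_labels: list[str]  # per-frame scripted mode ("" outside events)
    records: list[dict]
    image_size: tuple[int, int]

    def table(self) -> DetectionTable:
        W, H = self.image_size
        dets = []
        for rec in self.records:
            cx, cy, w, h = rec["cx"] * W, rec["cy"] * H, rec["w"] * W, rec["h"] * H
            box = BoundingBox(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
            dets.append(Detection("top", rec["_frame"], SOCIAL_CLASSES[rec["class"]],
                                  box, rec["conf"]))
        return DetectionTable(W, H, dets)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        clean = [{k: v for k, v in r.items() if not k.startswith("_")} for r in self.records]
        dp = out / "detections.json"
        dp.write_text(json.dumps(clean))
        gt = {
            "fps": self.script.fps,
            "labels": self.truth_labels,
            "tracks": {
                f"{t.identity}/{t.label}": [[None, None] if np.isnan(p).any()
                                            else [float(p[0]), float(p[1])]
                                            for p in t.points]
                for t in self.truth_tracks
            },
        }
        gp = out / "ground_truth.json"
        gp.write_text(json.dumps(gt))
        return {"detections": dp, "ground_truth": gp}


def simulate_social_session(script: SceneScript, arena_cm: tuple[float, float] = (45.0, 45.0),
                            px_per_cm: float = 20.0) -> SocialSession:
    """Two scripted mice on a rigid 4-point body template in a top-view arena.

    Between contact events each mouse sits near its home corner with a
    small smooth wander; around each :class:`ContactEvent` the pair glides
    to a mode-specific two-body configuration at the arena center (the
    named part pair ~1 cm apart, every other pair > 3 cm, body centers
    within the 10 cm contact threshold) and holds it for the event span.
    Back-to-back events blend smoothly, crossing over at the shared
    boundary. Output is 8-class normalized-box detections.
    """
    rng = np.random.default_rng(script.seed)
    fps = script.fps
    n = script.n_frames
    t = script.times
    cx, cyc = arena_cm[0] / 2.0, arena_cm[1] / 2.0
    homes = {"A": (np.array([10.0, 10.0]), 45.0), "B": (np.array([arena_cm[0] - 10.0, arena_cm[1] - 10.0]), 225.0)}

    events = sorted((ev for ev in script.events), key=lambda e: e.start_s)
    for ev in events:
        if not isinstance(ev, ContactEvent):
            raise ValueError("social sessions accept ContactEvent only")
        if ev.mode not in _CONTACT_POSES:
            raise ValueError(f"unknown contact mode {ev.mode!r}")
    for e1, e2 in zip(events, events[1:]):
        if e2.start_s < e1.end_s - 1e-9:
            raise ValueError("contact events must not overlap")

    meet = np.array([cx, cyc])
    approach_s = 1.5
    blend_s = 0.2  # half-window for back-to-back mode morphs

    def contact_pose(mode: str) -> dict[str, tuple[np.ndarray, float]]:
        sep, ha, hb = _CONTACT_POSES[mode]
        axis = 0.0  # A->B axis along +x at the meeting point
        pa = meet + _heading_unit(axis + 180.0) * (sep / 2.0)
        pb = meet + _heading_unit(axis) * (sep / 2.0)
        return {"A": (pa, axis + ha), "B": (pb, axis + hb)}

    # keyframes per mouse: (time, position, heading)
    keys: dict[str, list[tuple[float, np.ndarray, float]]] = {m: [] for m in "AB"}
    for m in "AB":
        keys[m].append((0.0, homes[m][0], homes[m][1]))
    for i, ev in enumerate(events):
        pose = contact_pose(ev.mode)
        prev_end = events[i - 1].end_s if i > 0 else None
        next_start = events[i + 1].start_s if i + 1 < len(events) else None
        for m in "AB":
            p, h = pose[m]
            if prev_end is None or ev.start_s - prev_end > 2 * approach_s:
                keys[m].append((ev.start_s - approach_s, homes[m][0], homes[m][1]))
                keys[m].append((ev.start_s, p, h))
            else:
                # back-to-back: morph from the previous pose across the boundary
                keys[m].append((ev.start_s + blend_s, p, h))
            hold_end = ev.end_s - blend_s if (next_start is not None
                                              and next_start - ev.end_s <= 2 * approach_s) else ev.end_s
            keys[m].append((hold_end, p, h))
            if next_start is None or next_start - ev.end_s > 2 * approach_s:
                keys[m].append((ev.end_s + approach_s, homes[m][0], homes[m][1]))
    for m in "AB":
        last = keys[m][-1]
        if last[0] < script.duration_s:
            keys[m].append((script.duration_s, last[1], last[2]))

    centers = {m: np.zeros((n, 2)) for m in "AB"}
    headings = {m: np.zeros(n) for m in "AB"}
    for m in "AB":
        kf = keys[m]
        times_k = np.array([k[0] for k in kf])
        for i in range(n):
            ti = t[i]
            j = int(np.searchsorted(times_k, ti, side="right")) - 1
            j = max(0, min(j, len(kf) - 2))
            t0, p0, h0 = kf[j]
            t1, p1, h1 = kf[j + 1]
            w = _smoothstep((ti - t0) / (t1 - t0)) if t1 > t0 else 1.0
            centers[m][i] = (1 - w) * p0 + w * p1
            headings[m][i] = _angle_lerp(h0, h1, np.asarray(w))
        # small smooth wander that cannot violate the pose margins
        phase = rng.uniform(0, 2 * np.pi, 2)
        freq = rng.uniform(0.2, 0.5, 2)
        centers[m] += 0.15 * np.stack([np.sin(2 * np.pi * freq[0] * t + phase[0]),
                                       np.sin(2 * np.pi * freq[1] * t + phase[1])], axis=1)

    # part positions from the rigid template
    truth_tracks = []
    part_pts: dict[tuple[str, str], np.ndarray] = {}
    frames = np.arange(n)
    for m in "AB":
        u = _heading_unit(headings[m])
        for part, off in MOUSE_TEMPLATE.items():
            pts = centers[m] + off * u
            part_pts[(m, part)] = pts
            truth_tracks.append(Track2D(identity=m, label=part, fps=fps,
                                        frames=frames.copy(), points=pts.copy()))

    labels = [""] * n
    for ev in events:
        f0 = int(round(ev.start_s * fps))
        f1 = int(round(ev.end_s * fps))
        for i in range(f0, min(f1, n)):
            labels[i] = ev.mode

    # render to normalized-box records
    W, H = int(round(arena_cm[0] * px_per_cm)), int(round(arena_cm[1] * px_per_cm))
    records = []
    for ci, cls in enumerate(SOCIAL_CLASSES):
        m, part = cls.replace("mouse", "").split("_")
        pts_px = part_pts[(m, part)] * px_per_cm
        if script.noise_px:
            pts_px = pts_px + rng.normal(0, script.noise_px, pts_px.shape)
        keep = rng.random(n) >= script.dropout_p
        conf = rng.uniform(0.6, 1.0, n)
        size = PART_BOX_CM[part] * px_per_cm
        for i in np.flatnonzero(keep):
            records.append({
                "image": f"frame_{i:06d}.png",
                "class": ci,
                "cx": float(pts_px[i, 0] / W), "cy": float(pts_px[i, 1] / H),
                "w": float(size / W), "h": float(size / H),
                "conf": round(float(conf[i]), 6),
                "_frame": int(i),
            })
    records.sort(key=lambda r: (r["_frame"], r["class"]))
    return SocialSession(script=script, arena=arena_cm, px_per_cm=px_per_cm,
                         truth_tracks=truth_tracks, truth_labels=labels,
                         records=records, image_size=(W, H))


# ---------------------------------------------------------------------------
# three-chamber sessions

def default_three_chamber_layout(px_per_cm: float = 20.0) -> ArenaLayout:
    """60 x 45 cm three-chamber box, cups centered in the side chambers."""
    return ArenaLayout(arena_width=60.0, arena_height=45.0, px_per_cm=px_per_cm,
                       cup_centers={"left": (10.0, 22.5), "right": (50.0, 22.5)},
                       cup_radius=5.0, interact_margin=2.0,
                       chamber_boundaries=[20.0, 40.0])


@dataclass
class ThreeChamberSession:
    script: SceneScript
    layout: ArenaLayout
    truth_track: Track2D
    cup_frames: dict[str, int]  # scripted per-cup interaction frame counts
    records: list[dict]

    def table(self) -> DetectionTable:
        W = int(round(self.layout.arena_width * self.layout.px_per_cm))
        H = int(round(self.layout.arena_height * self.layout.px_per_cm))
        dets = [Detection("top", rec["_frame"], "head",
                          BoundingBox(rec["x1"], rec["y1"], rec["x2"], rec["y2"]),
                          rec["conf"]) for rec in self.records]
        return DetectionTable(W, H, dets)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        clean = [{k: v for k, v in r.items() if not k.startswith("_")} for r in self.records]
        dp = out / "head_detections.json"
        dp.write_text(json.dumps(clean))
        gp = out / "ground_truth.json"
        gp.write_text(json.dumps({"fps": self.script.fps, "cup_frames": self.cup_frames}))
        return {"detections": dp, "ground_truth": gp}


def simulate_three_chamber(layout: ArenaLayout, script: SceneScript,
                           box_cm: float = 3.0) -> ThreeChamberSession:
    """Head trajectory visiting cups per :class:`VisitEvent` script.

    During a visit the head sits 4 cm from the cup center (inside the
    ``cup_radius + interact_margin`` interaction zone) with a small wobble;
    transit paths stay outside every interaction zone, so the scripted
    dwell frames are exactly the in-zone frames.
    """
    rng = np.random.default_rng(script.seed)
    fps = script.fps
    n = script.n_frames
    t = script.times
    home = np.array([layout.arena_width / 2.0, layout.arena_height / 2.0])
    reach = layout.cup_radius + layout.interact_margin

    events = sorted(script.events, key=lambda e: e.start_s)
    for ev in events:
        if not isinstance(ev, VisitEvent):
            raise ValueError("three-chamber sessions accept VisitEvent only")
        if ev.cup not in layout.cup_centers:
            raise ValueError(f"cup {ev.cup!r} not in layout ({sorted(layout.cup_centers)})")

    pos = np.tile(home, (n, 1))
    inside = np.zeros(n, dtype=bool)
    cup_frames = {name: 0 for name in layout.cup_centers}
    transit_s = 1.0
    for ev in events:
        center = np.asarray(layout.cup_centers[ev.cup], dtype=float)
        toward = home - center
        toward = toward / np.linalg.norm(toward)
        stage = center + toward * (reach + 0.6)  # just outside the zone
        dwell = center + toward * 4.0  # well inside the zone
        f0 = int(round(ev.start_s * fps))
        f1 = int(round(ev.end_s * fps))
        cup_frames[ev.cup] += min(f1, n) - f0
        go = (t >= ev.start_s - transit_s) & (t < ev.start_s)
        w = _smoothstep((t[go] - (ev.start_s - transit_s)) / transit_s)
        pos[go] = (1 - w[:, None]) * home + w[:, None] * stage
        for i in range(f0, min(f1, n)):
            wob = 0.3 * np.array([np.sin(0.7 * i / fps), np.cos(1.1 * i / fps)])
            pos[i] = dwell + wob
            inside[i] = True
        back = (t >= ev.end_s) & (t < ev.end_s + transit_s)
        w = _smoothstep((t[back] - ev.end_s) / transit_s)
        pos[back] = (1 - w[:, None]) * stage + w[:, None] * home

    # consistency: in-zone frames must equal the scripted dwell frames
    for name, center in layout.cup_centers.items():
        d = np.linalg.norm(pos - np.asarray(center), axis=1)
        assert int(((d <= reach)).sum()) == cup_frames[name]

    track = Track2D(identity="subject", label="head", fps=fps,
                    frames=np.arange(n), points=pos.copy())

    half = box_cm * layout.px_per_cm / 2.0
    pts_px = pos * layout.px_per_cm
    if script.noise_px:
        pts_px = pts_px + rng.normal(0, script.noise_px, pts_px.shape)
    keep = rng.random(n) >= script.dropout_p
    conf = rng.uniform(0.6, 1.0, n)
    records = []
    for i in np.flatnonzero(keep):
        u, v = pts_px[i]
        records.append({"image": f"frame_{i:06d}.png",
                        "x1": float(u - half), "y1": float(v - half),
                        "x2": float(u + half), "y2": float(v + half),
                        "conf": round(float(conf[i]), 6), "_frame": int(i)})
    return ThreeChamberSession(script=script, layout=layout, truth_track=track,
                               cup_frames=cup_frames, records=records)


# ---------------------------------------------------------------------------
# human pose sessions

#: Keypoint layout used by the pose simulator and its readers:
#: label -> (source array, triplet index), OpenPose body-25 + hand numbering.
KEYPOINT_LAYOUT = {
    "neck": ("pose", 1),
    "r_shoulder": ("pose", 2),
    "r_elbow": ("pose", 3),
    "r_wrist": ("pose", 4),
    "l_shoulder": ("pose", 5),
    "l_elbow": ("pose", 6),
    "l_wrist": ("pose", 7),
    "mid_hip": ("pose", 8),
    "r_index_mcp": ("hand_right", 5),
    "r_pinky_mcp": ("hand_right", 17),
    "l_index_mcp": ("hand_left", 5),
    "l_pinky_mcp": ("hand_left", 17),
}

_UPPER_ARM = 300.0  # mm
_FOREARM = 280.0
_PALM_ALONG = 60.0
_PALM_HALF = 40.0


def _neutral_skeleton() -> dict[str, np.ndarray]:
    """Static trunk + arms, subject facing the cameras (-y), z up, mm."""
    mid_hip = np.array([0.0, 0.0, 1000.0])
    neck = np.array([0.0, 0.0, 1450.0])
    sk = {"mid_hip": mid_hip, "neck": neck}
    for side, sx in (("r", -1.0), ("l", 1.0)):
        shoulder = np.array([sx * 180.0, 0.0, 1400.0])
        elbow = shoulder + np.array([0.0, 0.0, -_UPPER_ARM])  # upper arm down
        wrist = elbow + np.array([0.0, -_FOREARM, 0.0])  # forearm toward cameras
        sk[f"{side}_shoulder"] = shoulder
        sk[f"{side}_elbow"] = elbow
        sk[f"{side}_wrist"] = wrist
    return sk


def _hand_points(elbow: np.ndarray, wrist: np.ndarray, twist_deg: float,
                 side: str) -> tuple[np.ndarray, np.ndarray]:
    """index_mcp / pinky_mcp for a rigid hand rotated ``twist_deg`` about the forearm."""
    f = wrist - elbow
    f = f / np.linalg.norm(f)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, f)) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    e1 = ref - np.dot(ref, f) * f
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(f, e1)
    th = np.radians(twist_deg)
    palm = np.cos(th) * e1 + np.sin(th) * e2
    base = wrist + _PALM_ALONG * f
    return base + _PALM_HALF * palm, base - _PALM_HALF * palm


@dataclass
class PoseSession:
    script: SceneScript
    rig: StereoRig
    truth_joints: dict[str, np.ndarray]  # (n, 3) mm per joint
    truth_supination: dict[str, np.ndarray]  # side -> scripted twist series (deg)
    uv: dict[str, dict[str, np.ndarray]]  # camera -> joint -> noisy (n, 2)
    keep: dict[str, dict[str, np.ndarray]]  # camera -> joint -> kept mask
    conf: dict[str, dict[str, np.ndarray]]

    def table(self, camera: str) -> DetectionTable:
        cam = self.rig.camera_a if camera == "a" else self.rig.camera_b
        dets = []
        n = len(self.script.times)
        for joint in KEYPOINT_LAYOUT:
            uv = self.uv[camera][joint]
            keep = self.keep[camera][joint]
            conf = self.conf[camera][joint]
            for i in range(n):
                if keep[i]:
                    dets.append(Detection(camera, i, joint,
                                          PixelPoint(float(uv[i, 0]), float(uv[i, 1])),
                                          float(conf[i])))
        return DetectionTable(cam.image_width, cam.image_height, dets)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit per-frame keypoint JSON files (one directory per camera)."""
        out = Path(out_dir)
        n = len(self.script.times)
        paths = {}
        for camera in ("a", "b"):
            d = out / f"cam_{camera}"
            d.mkdir(parents=True, exist_ok=True)
            for i in range(n):
                pose = [0.0] * (25 * 3)
                hand_l = [0.0] * (21 * 3)
                hand_r = [0.0] * (21 * 3)
                arrays = {"pose": pose, "hand_left": hand_l, "hand_right": hand_r}
                for joint, (src, idx) in KEYPOINT_LAYOUT.items():
                    if not self.keep[camera][joint][i]:
                        continue
                    u, v = self.uv[camera][joint][i]
                    arr = arrays[src]
                    arr[3 * idx] = float(u)
                    arr[3 * idx + 1] = float(v)
                    arr[3 * idx + 2] = float(self.conf[camera][joint][i])
                doc = {"version": 1.3, "people": [{
                    "pose_keypoints_2d": pose,
                    "hand_left_keypoints_2d": hand_l,
                    "hand_right_keypoints_2d": hand_r,
                }]}
                (d / f"frame_{i:012d}_keypoints.json").write_text(json.dumps(doc))
            paths[camera] = d
        return paths


def default_rotation_script(seed: int = 0, fps: float = 60.0, side: str = "right",
                            amplitude_deg: float = 80.0, period_s: float = 1.0,
                            n_cycles: int = 9, noise_px: float = 0.0,
                            sign: float = 1.0) -> SceneScript:
    """Repetitive supination/pronation: ``n_cycles`` sinusoidal rotations."""
    ev = RotationEvent(side=side, amplitude_deg=amplitude_deg, period_s=period_s,
                       n_cycles=n_cycles, start_s=0.5, sign=sign)
    return SceneScript(seed=seed, fps=fps, duration_s=0.5 + n_cycles * period_s + 0.5,
                       events=[ev], noise_px=noise_px)


def simulate_pose_session(rig: StereoRig, script: SceneScript) -> PoseSession:
    """Animate an articulated upper body and project it to keypoint detections.

    :class:`RotationEvent` rotates the named hand rigidly about its forearm
    axis by A sin(2 pi (t - start)/period); :class:`ReachEvent` moves the
    wrist along a minimum-jerk out-and-back path (direction in world mm),
    the elbow following by two-link inverse kinematics with a downward
    elbow-swivel preference. Ground truth carries the true 3D joints and
    the scripted twist series per side.
    """
    rng = np.random.default_rng(script.seed)
    n = script.n_frames
    t = script.times
    base = _neutral_skeleton()
    joints = {name: np.tile(p, (n, 1)) for name, p in base.items()}
    twist = {"right": np.zeros(n), "left": np.zeros(n)}

    for ev in script.events:
        if isinstance(ev, RotationEvent):
            dur = ev.n_cycles * ev.period_s
            m = (t >= ev.start_s) & (t < ev.start_s + dur)
            twist[ev.side][m] += ev.sign * ev.amplitude_deg * np.sin(
                2 * np.pi * (t[m] - ev.start_s) / ev.period_s)
        elif isinstance(ev, ReachEvent):
            d = np.asarray(ev.direction, dtype=float)
            d = d / np.linalg.norm(d)
            side = "r"
            sh = base[f"{side}_shoulder"]
            w0 = base[f"{side}_wrist"]
            tau_out = (t - ev.onset_s) / ev.duration_s
            tau_back = tau_out - 1.0
            prog = np.zeros(n)
            m_out = (tau_out >= 0) & (tau_out < 1)
            m_back = (tau_back >= 0) & (tau_back <= 1)
            prog[m_out] = minimum_jerk(tau_out[m_out])
            prog[m_back] = 1 - minimum_jerk(tau_back[m_back])
            wr = w0 + np.outer(prog, ev.length_mm * d)
            el = np.array([_two_link_elbow(sh, w, _UPPER_ARM, _FOREARM) for w in wr])
            joints[f"{side}_wrist"] = wr
            joints[f"{side}_elbow"] = el
        else:
            raise ValueError(f"pose sessions accept RotationEvent/ReachEvent, got {ev}")

    for side, prefix in (("right", "r"), ("left", "l")):
        idx_pts = np.empty((n, 3))
        pky_pts = np.empty((n, 3))
        for i in range(n):
            idx_pts[i], pky_pts[i] = _hand_points(joints[f"{prefix}_elbow"][i],
                                                  joints[f"{prefix}_wrist"][i],
                                                  twist[side][i], side)
        joints[f"{prefix}_index_mcp"] = idx_pts
        joints[f"{prefix}_pinky_mcp"] = pky_pts

    uv: dict[str, dict[str, np.ndarray]] = {"a": {}, "b": {}}
    keep: dict[str, dict[str, np.ndarray]] = {"a": {}, "b": {}}
    conf: dict[str, dict[str, np.ndarray]] = {"a": {}, "b": {}}
    for camera, cam in (("a", rig.camera_a), ("b", rig.camera_b)):
        for joint in KEYPOINT_LAYOUT:
            pts = joints[joint]
            puv = project_points(pts, cam)
            if not _in_view(puv, cam).all():
                bad = np.flatnonzero(~_in_view(puv, cam))
                raise GeometryError(f"joint {joint} leaves camera {camera} at frames {bad[:10]}")
            noisy = puv + rng.normal(0, script.noise_px, puv.shape) if script.noise_px else puv
            uv[camera][joint] = noisy
            keep[camera][joint] = rng.random(n) >= script.dropout_p
            conf[camera][joint] = np.round(rng.uniform(0.6, 1.0, n), 6)
    return PoseSession(script=script, rig=rig, truth_joints=joints,
                       truth_supination={s: twist[s].copy() for s in twist},
                       uv=uv, keep=keep, conf=conf)


def _two_link_elbow(shoulder: np.ndarray, wrist: np.ndarray,
                    a: float, b: float) -> np.ndarray:
    """Elbow position for a two-link arm, preferring a downward elbow swivel."""
    d = wrist - shoulder
    L = np.linalg.norm(d)
    L = min(L, a + b - 1e-6)
    u = d / np.linalg.norm(d)
    cos_alpha = (a**2 + L**2 - b**2) / (2 * a * L)
    cos_alpha = float(np.clip(cos_alpha, -1.0, 1.0))
    sin_alpha = np.sqrt(1 - cos_alpha**2)
    swivel = np.array([0.0, 0.0, -1.0])
    v = swivel - np.dot(swivel, u) * u
    if np.linalg.norm(v) < 1e-9:
        v = np.array([0.0, -1.0, 0.0])
        v = v - np.dot(v, u) * u
    v = v / np.linalg.norm(v)
    return shoulder + a * (cos_alpha * u + sin_alpha * v)
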