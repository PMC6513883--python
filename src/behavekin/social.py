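"""Social-behavior assays from top-view 2D tracks.

Two assays are covered:

* **three-chamber sociability** -- a single head trajectory in a
  three-chamber arena; a frame counts as cup interaction when the head is
  within ``cup_radius + interact_margin`` of a cup center; the report gives
  per-cup interaction time, percentage split, chamber occupancy (by
  x-interval membership), chamber transitions and interaction bouts.

* **two-animal interaction** -- two identity-resolved animals (identity
  comes from the detector's classes, so no tracker is needed); the
  body-center distance defines *close-contact epochs* (distance below a
  threshold), and within an epoch each frame is labeled with an
  interaction type by the closest of the five nose/tail/body pairings
  (nose-nose, noseA-tailB, noseB-tailA, noseA-bodyB, noseB-bodyA), ties
  broken in that priority order; a pair must be closer than
  ``nose_contact_cm`` to label the frame, else the frame is
  ``proximity_only``.

All positions are in centimeters in the arena plane.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detections import DetectionTable
from .trajectory import gap_runs

__all__ = [
    "ArenaLayout",
    "Track2D",
    "ContactEpoch",
    "ThreeChamberReport",
    "build_tracks",
    "pair_distance_series",
    "detect_close_contacts",
    "classify_interactions",
    "three_chamber_report",
    "write_ethogram_csv",
    "PAIR_PRIORITY",
]

#: Interaction pairings in priority (tie-break) order.
PAIR_PRIORITY = ["nose-nose", "noseA-tailB", "noseB-tailA", "noseA-bodyB", "noseB-bodyA"]


@dataclass
class ArenaLayout:
    """Arena geometry in cm. ``cup_centers`` / ``chamber_boundaries`` are
    only used by the three-chamber assay."""

    arena_width: float
    arena_height: float
    px_per_cm: float
    cup_centers: dict[str, tuple[float, float]] = field(default_factory=dict)
    cup_radius: float = 5.0
    interact_margin: float = 2.0
    chamber_boundaries: list[float] = field(default_factory=list)  # interior x cuts

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        for name, (x, y) in self.cup_centers.items():
            if not (0 <= x <= self.arena_width and 0 <= y <= self.arena_height):
                raise ValueError(f"cup {name!r} lies outside the arena")

    def chamber_of(self, x: float) -> int:
        """Chamber index by x-interval membership (0 = leftmost)."""
        return int(np.searchsorted(np.asarray(self.chamber_boundaries), x, side="right"))


@dataclass
class Track2D:
    identity: str
    label: str  # nose | head | body | tail
    fps: float
    frames: np.ndarray
    points: np.ndarray  # (n, 2) cm, NaN = gap
    confidence: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.confidence is None:
            self.confidence = np.ones(len(self.frames))
        self.confidence = np.asarray(self.confidence, dtype=float)
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def gap_mask(self) -> np.ndarray:
        return np.isnan(self.points).any(axis=1)


@dataclass
class ContactEpoch:
    start_frame: int
    end_frame: int  # inclusive
    min_distance: float
    pair_distances: dict[str, np.ndarray] = field(default_factory=dict)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError("epoch start must not exceed end")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class ThreeChamberReport:
    session_duration_s: float
    cup_time_s: dict[str, float]
    cup_pct_of_interaction: dict[str, float]
    cup_pct_of_session: dict[str, float]
    chamber_time_s: list[float]
    transition_count: int
    bouts: dict[str, list[tuple[float, float]]]  # cup -> [(start_s, end_s)]

    @property
    def bout_count(self) -> int:
        return sum(len(v) for v in self.bouts.values())

    def to_json(self, path: str | Path) -> None:
        doc = {
            "session_duration_s": self.session_duration_s,
            "cup_time_s": self.cup_time_s,
            "cup_pct_of_interaction": self.cup_pct_of_interaction,
            "cup_pct_of_session": self.cup_pct_of_session,
            "chamber_time_s": self.chamber_time_s,
            "transition_count": self.transition_count,
            "bout_count": self.bout_count,
            "bouts": self.bouts,
        }
        Path(path).write_text(json.dumps(doc, indent=2))


# ---------------------------------------------------------------------------

def build_tracks(table: DetectionTable, class_map: dict[str, tuple[str, str]],
                 px_per_cm: float, fps: float = 30.0) -> list[Track2D]:
    """One dense Track2D per (identity, part) from a detection table.

    ``class_map`` maps detection labels to (identity, part), e.g.
    ``{"mouseA_nose": ("A", "nose"), ...}``. Box detections are already
    reduced to centers in the table; pixel coordinates are divided by
    ``px_per_cm``. Unmapped labels are skipped with a warning.
    """
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    tracks = []
    present = table.labels()
    for label in present:
        if label not in class_map:
            warnings.warn(f"detection label {label!r} not in class map; skipped", stacklevel=2)
    frames_all = table.df["frame_index"]
    lo, hi = int(frames_all.min()), int(frames_all.max())
    frames = np.arange(lo, hi + 1)
    for label, (identity, part) in class_map.items():
        sub = table.centers(None, label)
        pts = np.full((len(frames), 2), np.nan)
        conf = np.zeros(len(frames))
        if not sub.empty:
            idx = sub.index.to_numpy(dtype=int) - lo
            pts[idx, 0] = sub["u"].to_numpy() / px_per_cm
            pts[idx, 1] = sub["v"].to_numpy() / px_per_cm
            conf[idx] = sub["confidence"].to_numpy()
        tracks.append(Track2D(identity=identity, label=part, fps=fps,
                              frames=frames, points=pts, confidence=conf))
    return tracks


def pair_distance_series(a: Track2D, b: Track2D) -> np.ndarray:
    """Per-frame Euclidean distance (cm) on the common frame range; NaN where
    either track has a gap. Tracks must share fps."""
    if not np.isclose(a.fps, b.fps):
        raise ValueError(f"fps mismatch: {a.fps} vs {b.fps}")
    if len(a) != len(b) or not np.array_equal(a.frames, b.frames):
        # align on intersection
        common, ia, ib = np.intersect1d(a.frames, b.frames, return_indices=True)
        return np.linalg.norm(a.points[ia] - b.points[ib], axis=1)
    return np.linalg.norm(a.points - b.points, axis=1)


def detect_close_contacts(dist: np.ndarray, fps: float, threshold_cm: float = 10.0,
                          min_duration_s: float = 0.5,
                          merge_gap_s: float = 0.3,
                          frames: np.ndarray | None = None) -> list[ContactEpoch]:
    """Maximal runs with distance < threshold as close-contact epochs.

    GAP (NaN) frames break runs unless the interruption is shorter than
    ``merge_gap_s``; adjacent runs closer than ``merge_gap_s`` are merged;
    runs shorter than ``min_duration_s`` are dropped.
    """
    if threshold_cm <= 0:
        raise ValueError("threshold must be positive")
    dist = np.asarray(dist, dtype=float)
    if frames is None:
        frames = np.arange(len(dist))
    below = np.nan_to_num(dist, nan=np.inf) < threshold_cm
    runs = gap_runs(below)  # reuse run finder: True runs
    merge_gap = merge_gap_s * fps
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] < merge_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    min_len = min_duration_s * fps
    epochs = []
    for a, b in merged:
        if b - a >= min_len:
            epochs.append(ContactEpoch(
                start_frame=int(frames[a]), end_frame=int(frames[b - 1]),
                min_distance=float(np.nanmin(dist[a:b]))))
    return epochs


def _part_points(tracks: list[Track2D], identity: str, part: str) -> np.ndarray | None:
    for t in tracks:
        if t.identity == identity and t.label == part:
            return t
    return None


def classify_interactions(epoch: ContactEpoch, tracks: list[Track2D],
                          nose_contact_cm: float = 3.0) -> ContactEpoch:
    """Label every frame of an epoch with its interaction type.

    Requires nose/tail/body tracks for both identities (sorted identity
    order defines A and B). The label is the closest of the five pairings
    when that distance is below ``nose_contact_cm``, else
    ``proximity_only``; ties go to the earlier entry of
    :data:`PAIR_PRIORITY`. Missing parts yield ``unclassified``.
    """
    identities = sorted({t.identity for t in tracks})
    if len(identities) != 2:
        raise ValueError(f"need exactly 2 identities, got {identities}")
    ia, ib = identities
    parts = {}
    missing = []
    for ident, part in [(ia, "nose"), (ia, "tail"), (ia, "body"),
                        (ib, "nose"), (ib, "tail"), (ib, "body")]:
        tr = _part_points(tracks, ident, part)
        if tr is None:
            missing.append((ident, part))
        parts[(ident, part)] = tr
    if missing:
        warnings.warn(f"missing tracks {missing}; epoch left unclassified", stacklevel=2)
        epoch.labels = ["unclassified"] * epoch.n_frames
        return epoch

    ref = parts[(ia, "nose")]
    sel = (ref.frames >= epoch.start_frame) & (ref.frames <= epoch.end_frame)

    def pts(ident, part):
        return parts[(ident, part)].points[sel]

    pair_pts = {
        "nose-nose": (pts(ia, "nose"), pts(ib, "nose")),
        "noseA-tailB": (pts(ia, "nose"), pts(ib, "tail")),
        "noseB-tailA": (pts(ib, "nose"), pts(ia, "tail")),
        "noseA-bodyB": (pts(ia, "nose"), pts(ib, "body")),
        "noseB-bodyA": (pts(ib, "nose"), pts(ia, "body")),
    }
    dists = {k: np.linalg.norm(p - q, axis=1) for k, (p, q) in pair_pts.items()}
    stacked = np.stack([dists[k] for k in PAIR_PRIORITY])  # priority order: argmin -> first
    labels = []
    for j in range(stacked.shape[1]):
        col = stacked[:, j]
        if np.isnan(col).all():
            labels.append("unclassified")
            continue
        col = np.where(np.isnan(col), np.inf, col)
        k = int(np.argmin(col))  # argmin takes the first minimum: priority tie-break
        labels.append(PAIR_PRIORITY[k] if col[k] < nose_contact_cm else "proximity_only")
    epoch.pair_distances = dists
    epoch.labels = labels
    return epoch


def three_chamber_report(head: Track2D, layout: ArenaLayout) -> ThreeChamberReport:
    """Score a three-chamber session from the head trajectory.

    Interaction with cup ``c`` at frame ``i`` iff
    ``dist(head_i, cup_c) <= cup_radius + interact_margin``; chamber
    occupancy by x-interval membership; transitions count chamber changes
    between consecutive non-gap frames.
    """
    if len(head) == 0:
        raise ValueError("head track is empty")
    n = len(head)
    session_s = n / head.fps
    gap = head.gap_mask
    reach = layout.cup_radius + layout.interact_margin

    cup_time: dict[str, float] = {}
    bouts: dict[str, list[tuple[float, float]]] = {}
    for name, center in layout.cup_centers.items():
        d = np.linalg.norm(head.points - np.asarray(center, dtype=float), axis=1)
        inter = (~gap) & (d <= reach)
        cup_time[name] = float(inter.sum() / head.fps)
        bouts[name] = [
            (float(head.frames[a] / head.fps), float(head.frames[b - 1] / head.fps))
            for a, b in gap_runs(inter)
        ]
    total_inter = sum(cup_time.values())
    pct_inter = {k: (100.0 * v / total_inter if total_inter > 0 else 0.0)
                 for k, v in cup_time.items()}
    pct_session = {k: 100.0 * v / session_s for k, v in cup_time.items()}

    n_chambers = len(layout.chamber_boundaries) + 1
    chamber_time = [0.0] * n_chambers
    transitions = 0
    prev_ch = None
    for i in range(n):
        if gap[i]:
            continue
        ch = layout.chamber_of(head.points[i, 0])
        chamber_time[ch] += 1.0 / head.fps
        if prev_ch is not None and ch != prev_ch:
            transitions += 1
        prev_ch = ch
    return ThreeChamberReport(
        session_duration_s=session_s,
        cup_time_s=cup_time,
        cup_pct_of_interaction=pct_inter,
        cup_pct_of_session=pct_session,
        chamber_time_s=chamber_time,
        transition_count=transitions,
        bouts=bouts,
    )


def write_ethogram_csv(epochs: list[ContactEpoch], path: str | Path) -> pd.DataFrame:
    """Frame-by-frame ethogram: epoch id, label, and the five pair distances."""
    rows = []
    for eid, ep in enumerate(epochs):
        for j in range(ep.n_frames):
            row = {"frame": ep.start_frame + j, "epoch": eid,
                   "label": ep.labels[j] if ep.labels else ""}
            for k in PAIR_PRIORITY:
                if k in ep.pair_distances:
                    row[k] = ep.pair_distances[k][j]
            rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.6g")
    return df
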