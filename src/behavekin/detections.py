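"""Readers for the three per-frame detection JSON dialects, plus trajectory CSV I/O.

Object detectors and pose estimators in this pipeline emit one of three
JSON layouts:

1. *single-box* -- one bounding box per image, absolute pixel corners
   (``x1, y1, x2, y2``) with an optional confidence;
2. *normalized-box* -- multi-class boxes given as class id, normalized
   center (``cx, cy``) and normalized size (``w, h``), each relative to the
   image dimensions (up to 80 classes);
3. *keypoint* -- one file per frame holding a ``people`` list of flat
   ``(x, y, c)`` triplets for body and hand keypoints.

All three are normalized here into a :class:`DetectionTable` backed by a
pandas DataFrame, with exactly one detection per (camera, label, frame)
after dedup (highest confidence wins).

Canonical schemas (aliases accepted are noted):

``single-box``: an array (or object keyed by image id) of records
``{"image": "...0123.png", "x1":, "y1":, "x2":, "y2":, "conf":}``;
``conf``/``confidence``/``score`` are synonyms; a record without a
confidence is a manual label and defaults to 1.0; the frame index is the
trailing integer of the image identifier.

``normalized-box``: an array of records
``{"image":, "class":, "cx":, "cy":, "w":, "h":, "conf":}`` with
``cx, cy, w, h`` in [0, 1]; ``class``/``class_id`` and ``x``/``cx`` etc.
are synonyms.

``keypoint``: a directory of per-frame files, each
``{"people": [{"pose_keypoints_2d": [...], "hand_left_keypoints_2d": [...],
"hand_right_keypoints_2d": [...]}]}``; a triplet with ``c == 0`` means the
keypoint was not detected in that frame.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .trajectory import Trajectory3D

__all__ = [
    "BoundingBox",
    "PixelPoint",
    "Detection",
    "DetectionTable",
    "ParseReport",
    "box_center",
    "read_box_json",
    "read_normalized_box_json",
    "read_keypoint_json",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

#: Column layout of the detection DataFrame.
COLUMNS = ["camera_id", "label", "frame_index", "kind", "u", "v", "x1", "y1", "x2", "y2", "confidence"]


class FormatError(ValueError):
    """A detection or trajectory file does not match its documented schema."""


@dataclass(frozen=True)
class PixelPoint:
    u: float
    v: float

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.v], dtype=float)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box, origin top-left, u rightward, v downward."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        for v in (self.x1, self.y1, self.x2, self.y2):
            if not np.isfinite(v):
                raise ValueError("bounding box coordinates must be finite")
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(f"degenerate box: {self}")

    @classmethod
    def repaired(cls, x1: float, y1: float, x2: float, y2: float) -> tuple["BoundingBox", bool]:
        """Build a box, swapping corners if needed; returns (box, was_repaired)."""
        repaired = x1 > x2 or y1 > y2
        if x1 > x2:
            x1, x2 = x2, x1
        if y1 > y2:
            y1, y2 = y2, y1
        return cls(x1, y1, x2, y2), repaired


def box_center(box: BoundingBox) -> PixelPoint:
    """Center of a bounding box: ((x1+x2)/2, (y1+y2)/2)."""
    return PixelPoint((box.x1 + box.x2) / 2.0, (box.y1 + box.y2) / 2.0)


@dataclass(frozen=True)
class Detection:
    camera_id: str
    frame_index: int
    label: str
    geometry: BoundingBox | PixelPoint
    confidence: float

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")

    @property
    def center(self) -> PixelPoint:
        if isinstance(self.geometry, BoundingBox):
            return box_center(self.geometry)
        return self.geometry


@dataclass
class ParseReport:
    """Accounting of one parse pass: what was read, repaired, skipped."""

    n_records: int = 0
    n_parsed: int = 0
    skipped: int = 0
    repaired: int = 0
    deduplicated: int = 0
    messages: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


class DetectionTable:
    """Detections from one or more cameras, one row per kept detection.

    Geometry is kept both as corners (box rows) and as the point ``(u, v)``
    (the box center for boxes). Construction enforces the dedup rule --
    at most one detection per (camera_id, label, frame_index), the highest
    confidence winning -- and rejects wild coordinates outside
    ``[-W, 2W] x [-H, 2H]``.
    """

    def __init__(self, image_width: int, image_height: int,
                 detections: Iterable[Detection] = (), report: ParseReport | None = None):
        self.image_width = int(image_width)
        self.image_height = int(image_height)
        self.report = report or ParseReport()
        rows = []
        for det in detections:
            geo = det.geometry
            if isinstance(geo, BoundingBox):
                c = box_center(geo)
                row = dict(kind="box", u=c.u, v=c.v, x1=geo.x1, y1=geo.y1, x2=geo.x2, y2=geo.y2)
            else:
                row = dict(kind="point", u=geo.u, v=geo.v, x1=np.nan, y1=np.nan, x2=np.nan, y2=np.nan)
            row.update(camera_id=det.camera_id, label=det.label,
                       frame_index=det.frame_index, confidence=det.confidence)
            rows.append(row)
        df = pd.DataFrame(rows, columns=COLUMNS)
        # reject wild geometry, tolerate slightly out-of-frame detections
        W, H = self.image_width, self.image_height
        ok = (df["u"].between(-W, 2 * W)) & (df["v"].between(-H, 2 * H))
        n_wild = int((~ok).sum())
        if n_wild:
            self.report.skipped += n_wild
            self.report.messages.append(f"{n_wild} detections outside [-W,2W]x[-H,2H] rejected")
            df = df[ok]
        # dedup: highest confidence per (camera, label, frame)
        before = len(df)
        df = (
            df.sort_values(["camera_id", "label", "frame_index", "confidence"])
            .drop_duplicates(["camera_id", "label", "frame_index"], keep="last")
            .sort_values(["camera_id", "label", "frame_index"], kind="stable")
            .reset_index(drop=True)
        )
        self.report.deduplicated += before - len(df)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def labels(self) -> list[str]:
        return sorted(self.df["label"].unique())

    def select(self, camera_id: str | None = None, label: str | None = None) -> pd.DataFrame:
        df = self.df
        if camera_id is not None:
            df = df[df["camera_id"] == camera_id]
        if label is not None:
            df = df[df["label"] == label]
        return df

    def centers(self, camera_id: str | None, label: str) -> pd.DataFrame:
        """Frame-indexed (u, v, confidence) for one label, sorted by frame."""
        df = self.select(camera_id, label)
        return df.set_index("frame_index")[["u", "v", "confidence"]].sort_index()


_TRAILING_INT = re.compile(r"(\d+)(?=\D*$)")


def _frame_from_identifier(ident: object, fallback: int) -> int:
    m = _TRAILING_INT.search(str(ident)) if ident is not None else None
    return int(m.group(1)) if m else fallback


def _get_alias(rec: Mapping, *names, default=None):
    for n in names:
        if n in rec:
            return rec[n]
    return default


def _iter_records(raw) -> Iterable[tuple[object, Mapping]]:
    """Yield (image identifier or None, record) from array or mapping layouts."""
    if isinstance(raw, list):
        for rec in raw:
            yield (_get_alias(rec, "image", "image_id", "file", "frame") if isinstance(rec, Mapping) else None), rec
    elif isinstance(raw, Mapping):
        for key, rec in raw.items():
            yield key, rec
    else:
        raise FormatError(f"expected a JSON array or object, got {type(raw).__name__}")


def read_box_json(path: str | Path, camera_id: str, label: str,
                  image_width: int = 448, image_height: int = 460) -> DetectionTable:
    """Read the single-box dialect: absolute corner coordinates per image.

    Records missing a confidence (manual labels) default to 1.0. Boxes with
    swapped corners are repaired and counted; malformed records are skipped
    and counted in ``table.report``.
    """
    raw = json.loads(Path(path).read_text())
    report = ParseReport()
    detections: list[Detection] = []
    first_bad: str | None = None
    for order, (ident, rec) in enumerate(_iter_records(raw)):
        report.n_records += 1
        try:
            x1 = float(rec["x1"])
            y1 = float(rec["y1"])
            x2 = float(rec["x2"])
            y2 = float(rec["y2"])
            conf = float(_get_alias(rec, "conf", "confidence", "score", default=1.0))
            box, was_repaired = BoundingBox.repaired(x1, y1, x2, y2)
            if was_repaired:
                report.repaired += 1
                report.messages.append(f"record {order}: swapped corners repaired")
            frame = _frame_from_identifier(ident, order)
            detections.append(Detection(camera_id, frame, label, box, conf))
            report.n_parsed += 1
        except (KeyError, TypeError, ValueError) as exc:
            report.skipped += 1
            if first_bad is None:
                first_bad = f"record {order}: {exc}"
    if not detections:
        raise FormatError(f"{path}: no parseable records ({first_bad or 'file empty'})")
    return DetectionTable(image_width, image_height, detections, report)


def read_normalized_box_json(path: str | Path, camera_id: str, image_width: int,
                             image_height: int, class_names: list[str],
                             norm_tolerance: float = 0.05) -> DetectionTable:
    """Read the normalized-box dialect: class id + center/size relative to the image.

    Pixel box = ((cx - w/2) W, (cy - h/2) H, (cx + w/2) W, (cy + h/2) H).
    A class id outside ``class_names`` is a format error; normalized values
    outside [0, 1] by more than ``norm_tolerance`` skip the record.
    """
    if len(class_names) > 80:
        raise FormatError("at most 80 classes are supported")
    raw = json.loads(Path(path).read_text())
    report = ParseReport()
    detections: list[Detection] = []
    W, H = float(image_width), float(image_height)
    for order, (ident, rec) in enumerate(_iter_records(raw)):
        report.n_records += 1
        try:
            cls = int(_get_alias(rec, "class", "class_id"))
            cx = float(_get_alias(rec, "cx", "x"))
            cy = float(_get_alias(rec, "cy", "y"))
            w = float(rec["w"])
            h = float(rec["h"])
            conf = float(_get_alias(rec, "conf", "confidence", "score", default=1.0))
        except (KeyError, TypeError, ValueError):
            report.skipped += 1
            continue
        if not 0 <= cls < len(class_names):
            raise FormatError(f"{path}: record {order} has class id {cls} "
                              f"outside the {len(class_names)} configured classes")
        if any(v < -norm_tolerance or v > 1 + norm_tolerance for v in (cx, cy, w, h)):
            report.skipped += 1
            report.messages.append(f"record {order}: normalized values out of [0,1]")
            continue
        box, was_repaired = BoundingBox.repaired((cx - w / 2) * W, (cy - h / 2) * H,
                                                 (cx + w / 2) * W, (cy + h / 2) * H)
        if was_repaired:
            report.repaired += 1
        frame = _frame_from_identifier(ident, order)
        detections.append(Detection(camera_id, frame, class_names[cls], box, conf))
        report.n_parsed += 1
    if not detections:
        raise FormatError(f"{path}: no parseable records")
    return DetectionTable(image_width, image_height, detections, report)


def _person_keypoints(person: Mapping, keypoint_names: Mapping[str, tuple[str, int]]) -> dict[str, tuple[float, float, float]]:
    sources = {
        "pose": person.get("pose_keypoints_2d", []),
        "hand_left": person.get("hand_left_keypoints_2d", []),
        "hand_right": person.get("hand_right_keypoints_2d", []),
    }
    out = {}
    for name, (source, idx) in keypoint_names.items():
        flat = sources.get(source, [])
        if 3 * idx + 2 < len(flat):
            out[name] = (float(flat[3 * idx]), float(flat[3 * idx + 1]), float(flat[3 * idx + 2]))
    return out


def read_keypoint_json(dir_path: str | Path, camera_id: str,
                       keypoint_names: Mapping[str, tuple[str, int]],
                       image_width: int = 1280, image_height: int = 1024,
                       person_policy: str = "best_mean_confidence") -> DetectionTable:
    """Read a directory of per-frame keypoint files (one JSON per frame).

    ``keypoint_names`` maps output labels to (source, index) pairs, e.g.
    ``{"r_wrist": ("pose", 4), "r_index_mcp": ("hand_right", 5)}``.
    A ``(0, 0, 0)`` triplet marks an undetected keypoint and yields no
    detection (a gap). With several people in frame, the person with the
    highest mean confidence over the named keypoints is kept.
    """
    if person_policy not in ("best_mean_confidence", "first"):
        raise ValueError(f"unknown person policy {person_policy!r}")
    files = sorted(Path(dir_path).glob("*.json"))
    if not files:
        raise FormatError(f"{dir_path}: no keypoint JSON files found")
    report = ParseReport()
    detections: list[Detection] = []
    for order, f in enumerate(files):
        report.n_records += 1
        try:
            data = json.loads(f.read_text())
            people = data.get("people", [])
        except (json.JSONDecodeError, AttributeError):
            report.skipped += 1
            continue
        if not people:
            continue
        frame = _frame_from_identifier(f.stem, order)
        candidates = [_person_keypoints(p, keypoint_names) for p in people]
        if person_policy == "first" or len(candidates) == 1:
            chosen = candidates[0]
        else:
            def mean_conf(kps: dict) -> float:
                confs = [c for (_, _, c) in kps.values()]
                return float(np.mean(confs)) if confs else 0.0
            chosen = max(candidates, key=mean_conf)
        for name, (x, y, c) in chosen.items():
            if c <= 0.0:
                continue  # undetected sentinel -> gap
            detections.append(Detection(camera_id, frame, name, PixelPoint(x, y), min(c, 1.0)))
            report.n_parsed += 1
    return DetectionTable(image_width, image_height, detections, report)


# ---------------------------------------------------------------------------
# trajectory CSV round-trip

_FLOAT_FMT = "%.9g"


def write_trajectory_csv(traj: Trajectory3D, path: str | Path) -> None:
    """Write a trajectory as CSV with a commented header (label, units, fps).

    Gap frames are written as empty x/y/z cells so the file remains a dense
    frame-by-frame record.
    """
    lines = [
        "# behavekin-trajectory v1",
        f"# label: {traj.label}",
        f"# units: {traj.units}",
        f"# fps: {_FLOAT_FMT % traj.fps}",
        "frame,x,y,z,confidence",
    ]
    for i, frame in enumerate(traj.frames):
        p = traj.points[i]
        if np.isnan(p).any():
            lines.append(f"{frame},,,,{_FLOAT_FMT % traj.confidence[i]}")
        else:
            xyz = ",".join(_FLOAT_FMT % v for v in p)
            lines.append(f"{frame},{xyz},{_FLOAT_FMT % traj.confidence[i]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory_csv(path: str | Path) -> Trajectory3D:
    """Read a trajectory CSV written by :func:`write_trajectory_csv`."""
    text = Path(path).read_text().splitlines()
    meta: dict[str, str] = {}
    for line in text:
        if not line.startswith("#"):
            break
        stripped = line.lstrip("# ")
        if ":" in stripped:
            key, _, val = stripped.partition(":")
            meta[key.strip()] = val.strip()
    for required in ("label", "units", "fps"):
        if required not in meta:
            raise FormatError(f"{path}: trajectory header missing {required!r}")
    df = pd.read_csv(Path(path), comment="#")
    frames = df["frame"].to_numpy(dtype=int)
    points = df[["x", "y", "z"]].to_numpy(dtype=float)
    conf = df["confidence"].to_numpy(dtype=float)
    return Trajectory3D(label=meta["label"], fps=float(meta["fps"]), frames=frames,
                        points=points, confidence=conf, units=meta["units"])
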