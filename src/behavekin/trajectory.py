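"""Gap-aware 3D trajectory container shared across the toolbox.

A trajectory is a dense, frame-indexed time series of 3D positions for one
labeled part (a paw, a wrist, ...). Frames where the part could not be
reconstructed -- a detector miss in either camera, a low-confidence
detection, a rejected triangulation -- are *gaps*, stored as NaN rows so
that downstream code (interpolation, smoothing, differentiation) can treat
them uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory3D", "gap_runs", "is_gap"]


def is_gap(points: np.ndarray) -> np.ndarray:
    """Boolean gap mask for an (n, 3) point array (NaN anywhere in a row)."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        return np.isnan(points).any()
    return np.isnan(points).any(axis=1)


def gap_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs in a boolean mask as (start, stop) half-open pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


@dataclass
class Trajectory3D:
    """Dense 3D trajectory of one part at a known frame rate.

    Parameters
    ----------
    label : str
        Part name (e.g. ``"paw"``, ``"r_wrist"``).
    fps : float
        Frames per second; must be positive.
    frames : ndarray of int, shape (n,)
        Strictly increasing frame indices.
    points : ndarray of float, shape (n, 3)
        World positions in ``units``; NaN rows mark gaps.
    confidence : ndarray of float, shape (n,)
        Per-sample confidence in [0, 1]; 0 for interpolated samples.
    units : str
        Length unit of ``points`` (default ``"mm"``).
    """

    label: str
    fps: float
    frames: np.ndarray
    points: np.ndarray
    confidence: np.ndarray = field(default=None)  # type: ignore[assignment]
    units: str = "mm"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.confidence is None:
            self.confidence = np.ones(len(self.frames))
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if len(self.points) != len(self.frames) or len(self.confidence) != len(self.frames):
            raise ValueError("frames, points and confidence must have equal length")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trajectory3D):
            return NotImplemented
        return (
            self.label == other.label
            and self.units == other.units
            and np.isclose(self.fps, other.fps)
            and np.array_equal(self.frames, other.frames)
            and np.array_equal(self.points, other.points, equal_nan=True)
            and np.allclose(self.confidence, other.confidence, atol=1e-9)
        )

    @property
    def gap_mask(self) -> np.ndarray:
        return is_gap(self.points)

    @property
    def n_gaps(self) -> int:
        return int(self.gap_mask.sum())

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (frame_index / fps)."""
        return self.frames / self.fps

    def copy(self) -> "Trajectory3D":
        return Trajectory3D(
            label=self.label,
            fps=self.fps,
            frames=self.frames.copy(),
            points=self.points.copy(),
            confidence=self.confidence.copy(),
            units=self.units,
        )
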