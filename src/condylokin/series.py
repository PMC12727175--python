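"""Core data containers for dynamic 2D image series and condylar trajectories.

Coordinate conventions
----------------------
Image grids are indexed ``(row, col)``.  In-plane physical coordinates are
``x = col * pixel_spacing_col`` and ``y = row * pixel_spacing_row`` (pixel
centres sit on the integer grid, so the pixel at ``(row=12, col=10)`` with
0.36 mm spacing has centre ``(x, y) = (3.60, 4.32)`` mm).

Timestamps are in milliseconds and refer to frame start; frame indexing is
0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

PLANES = ("axial", "sagittal_right", "sagittal_left")
SIDES = ("right", "left")


class TrackRejectedError(ValueError):
    """Raised when a centroid track fails the minimum-validity requirement."""


def _as_increasing_ms(timestamps) -> np.ndarray:
    t = np.asarray(timestamps, dtype=float)
    if t.ndim != 1:
        raise ValueError("timestamps_ms must be 1-D")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("timestamps_ms must be strictly increasing")
    return t


@dataclass
class FrameSeries:
    """A dynamic series of 2D intensity frames from one imaging plane."""

    frames: np.ndarray  # (T, H, W)
    pixel_spacing_mm: tuple[float, float]  # (row, col)
    timestamps_ms: np.ndarray
    plane: str

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (T, H, W)")
        self.timestamps_ms = _as_increasing_ms(self.timestamps_ms)
        if len(self.timestamps_ms) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        sy, sx = self.pixel_spacing_mm
        if sy <= 0 or sx <= 0:
            raise ValueError("pixel spacing must be strictly positive")
        self.pixel_spacing_mm = (float(sy), float(sx))
        if self.plane not in PLANES:
            raise ValueError(f"plane must be one of {PLANES}, got {self.plane!r}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def frame_period_ms(self) -> float:
        """Median inter-frame period."""
        if self.n_frames < 2:
            raise ValueError("need at least two frames for a frame period")
        return float(np.median(np.diff(self.timestamps_ms)))


@dataclass
class MaskSeries(FrameSeries):
    """Binary condyle masks with the geometry/timing of the parent series.

    ``valid`` flags frames on which segmentation produced the expected
    component count; invalid frames carry all-background masks.
    """

    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        self.frames = self.frames.astype(bool)
        if self.valid is None:
            self.valid = np.ones(self.n_frames, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (self.n_frames,):
                raise ValueError("valid must have one flag per frame")


@dataclass
class ReferenceLine:
    """An anatomical reference line in image coordinates (mm).

    ``direction`` is normalized on construction.  The unit normal is the
    direction rotated by +90 degrees, ``n = (-dy, dx)``; for the mid-sagittal
    line drawn with direction (0, 1) on an axial image, points on the image
    left (subject right under radiological convention) have positive signed
    offset.
    """

    point_mm: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.point_mm = np.asarray(self.point_mm, dtype=float).reshape(2)
        d = np.asarray(self.direction, dtype=float).reshape(2)
        norm = float(np.linalg.norm(d))
        if norm == 0:
            raise ValueError("direction must be non-zero")
        self.direction = d / norm

    @property
    def normal(self) -> np.ndarray:
        dx, dy = self.direction
        return np.array([-dy, dx])

    def projection(self, points_mm: np.ndarray) -> np.ndarray:
        """Scalar coordinate of points along the line direction."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (p - self.point_mm) @ self.direction

    def signed_offset(self, points_mm: np.ndarray) -> np.ndarray:
        """Signed distance of points from the line (positive along normal)."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (p - self.point_mm) @ self.normal

    @classmethod
    def vertical(cls, x_mm: float) -> "ReferenceLine":
        return cls(point_mm=np.array([x_mm, 0.0]), direction=np.array([0.0, 1.0]))

    @classmethod
    def horizontal(cls, y_mm: float) -> "ReferenceLine":
        return cls(point_mm=np.array([0.0, y_mm]), direction=np.array([1.0, 0.0]))


@dataclass
class CondyleTrack:
    """Per-frame in-plane centroid positions of one condyle."""

    side: str
    plane: str
    timestamps_ms: np.ndarray
    positions_mm: np.ndarray  # (N, 2) as (x, y) mm
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if self.plane not in PLANES:
            raise ValueError(f"plane must be one of {PLANES}")
        self.timestamps_ms = _as_increasing_ms(self.timestamps_ms)
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        if self.positions_mm.shape != (len(self.timestamps_ms), 2):
            raise ValueError("positions_mm must have shape (n_frames, 2)")
        if self.valid is None:
            self.valid = np.ones(len(self.timestamps_ms), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (len(self.timestamps_ms),):
                raise ValueError("valid must have one flag per frame")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps_ms)

    @property
    def valid_fraction(self) -> float:
        return float(np.mean(self.valid))

    def trimmed(self) -> "CondyleTrack":
        """Drop leading/trailing invalid frames; interior gaps must be filled."""
        idx = np.flatnonzero(self.valid)
        if idx.size == 0:
            raise TrackRejectedError(f"track {self.plane}/{self.side}: no valid frames")
        lo, hi = idx[0], idx[-1] + 1
        if not np.all(self.valid[lo:hi]):
            raise TrackRejectedError(
                f"track {self.plane}/{self.side}: unfilled interior gap"
            )
        return replace(
            self,
            timestamps_ms=self.timestamps_ms[lo:hi],
            positions_mm=self.positions_mm[lo:hi],
            valid=self.valid[lo:hi],
        )


@dataclass
class DisplacementSignal:
    """Scalar displacement of one condyle along a reference direction.

    Displacement is relative to the position at the projection origin, so a
    signal always starts near zero; the sign convention makes jaw opening
    positive.
    """

    timestamps_ms: np.ndarray
    displacement_mm: np.ndarray
    side: str
    plane: str

    def __post_init__(self) -> None:
        self.timestamps_ms = _as_increasing_ms(self.timestamps_ms)
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        if self.displacement_mm.shape != self.timestamps_ms.shape:
            raise ValueError("displacement and timestamps must align")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")

    @property
    def n_samples(self) -> int:
        return len(self.timestamps_ms)

    @property
    def frame_period_ms(self) -> float:
        if self.n_samples < 2:
            raise ValueError("need at least two samples for a frame period")
        return float(np.median(np.diff(self.timestamps_ms)))


@dataclass
class MotionPhase:
    """One detected opening or closing interval on a displacement signal."""

    kind: str  # "opening" | "closing"
    start_index: int
    end_index: int  # inclusive
    t_start_ms: float
    t_end_ms: float

    def __post_init__(self) -> None:
        if self.kind not in ("opening", "closing"):
            raise ValueError("kind must be 'opening' or 'closing'")
        if self.start_index >= self.end_index:
            raise ValueError("phase must span at least two samples")
        if self.t_end_ms <= self.t_start_ms:
            raise ValueError("phase must have positive duration")

    @property
    def duration_ms(self) -> float:
        return self.t_end_ms - self.t_start_ms


@dataclass
class PhasePair:
    """A right/left pair of phases of the same kind with overlapping support."""

    kind: str
    right_phase: MotionPhase
    left_phase: MotionPhase
    cycle_index: int

    def __post_init__(self) -> None:
        if self.right_phase.kind != self.kind or self.left_phase.kind != self.kind:
            raise ValueError("paired phases must share the pair's kind")
        overlap = min(self.right_phase.t_end_ms, self.left_phase.t_end_ms) - max(
            self.right_phase.t_start_ms, self.left_phase.t_start_ms
        )
        if overlap <= 0:
            raise ValueError("paired phases must overlap in time")
        if self.cycle_index < 0:
            raise ValueError("cycle_index must be non-negative")

    @property
    def mean_duration_ms(self) -> float:
        return 0.5 * (self.right_phase.duration_ms + self.left_phase.duration_ms)
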