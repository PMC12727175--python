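"""Fusion of axial and sagittal 2D tracks into 3D trajectories, plus the
automatic 3D trajectory symmetry score.

The anatomical frame has axes AP (anteroposterior), ML (mediolateral) and
CC (craniocaudal).  The mediolateral coordinate is only visible in the
axial plane (orthogonal to the mid-sagittal line), the craniocaudal one
only in the sagittal plane (orthogonal to the Frankfurt horizontal line);
the anteroposterior coordinate is seen by both planes and is taken as the
mean of the two projections.  All coordinates are relative to each track's
first sample, which makes the fusion invariant to constant in-plane
offsets — the two planes are acquired in separate runs, so absolute
positions are not comparable across them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .series import CondyleTrack, ReferenceLine

AXES = ("AP", "ML", "CC")
AP_DISAGREEMENT_WARN_MM = 3.0


@dataclass
class Track3D:
    """3D condylar trajectory in the anatomical frame (AP, ML, CC), mm."""

    side: str
    timestamps_ms: np.ndarray
    positions_mm: np.ndarray  # (N, 3)
    ap_rms_disagreement_mm: float | None = None

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        if self.timestamps_ms.size > 1 and not np.all(
            np.diff(self.timestamps_ms) > 0
        ):
            raise ValueError("timestamps must be strictly increasing")
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        if self.positions_mm.shape != (len(self.timestamps_ms), 3):
            raise ValueError("positions_mm must have shape (n, 3)")


@dataclass
class SymmetryScore:
    """Binary trajectory-symmetry score with the lagging side."""

    value: int  # 0 | 1
    lagging: str  # "none" | "right" | "left"

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError("score value must be 0 or 1")
        if (self.value == 0) != (self.lagging == "none"):
            raise ValueError("score 0 if and only if lagging is 'none'")


def resample_to_common_clock(tracks: list[CondyleTrack]) -> list[CondyleTrack]:
    """Linear interpolation onto a shared uniform grid at the finest period.

    The grid is restricted to the intersection of the tracks' time
    supports; tracks are trimmed to their valid extent first.
    """
    tracks = [t.trimmed() for t in tracks]
    t0 = max(t.timestamps_ms[0] for t in tracks)
    t1 = min(t.timestamps_ms[-1] for t in tracks)
    if t1 <= t0:
        raise ValueError("tracks have no overlapping time support")
    dt = min(float(np.median(np.diff(t.timestamps_ms))) for t in tracks)
    n = int(np.floor((t1 - t0) / dt)) + 1
    grid = t0 + dt * np.arange(n)
    out = []
    for tr in tracks:
        pos = np.column_stack(
            [
                np.interp(grid, tr.timestamps_ms, tr.positions_mm[:, 0]),
                np.interp(grid, tr.timestamps_ms, tr.positions_mm[:, 1]),
            ]
        )
        out.append(
            CondyleTrack(
                side=tr.side,
                plane=tr.plane,
                timestamps_ms=grid,
                positions_mm=pos,
            )
        )
    return out


def fuse_3d(
    axial_track: CondyleTrack,
    sagittal_track: CondyleTrack,
    axial_line: ReferenceLine,
    sagittal_line: ReferenceLine,
) -> Track3D:
    """Fuse one side's axial and sagittal tracks into a 3D trajectory.

    Both tracks must already share a common clock (see
    :func:`resample_to_common_clock`).  The two planes' AP projections are
    sign-aligned before averaging (the acquisition does not fix a shared
    handedness); an RMS disagreement above 3 mm between them is recorded
    and warned about, not raised.
    """
    if axial_track.side != sagittal_track.side:
        raise ValueError("axial and sagittal tracks must describe the same side")
    if len(axial_track.timestamps_ms) != len(sagittal_track.timestamps_ms) or not np.allclose(
        axial_track.timestamps_ms, sagittal_track.timestamps_ms
    ):
        raise ValueError("tracks must be resampled to a common clock first")

    ml = axial_line.signed_offset(axial_track.positions_mm)
    ap_ax = axial_line.projection(axial_track.positions_mm)
    cc = sagittal_line.signed_offset(sagittal_track.positions_mm)
    ap_sag = sagittal_line.projection(sagittal_track.positions_mm)

    ml = ml - ml[0]
    cc = cc - cc[0]
    ap_ax = ap_ax - ap_ax[0]
    ap_sag = ap_sag - ap_sag[0]
    if float(np.dot(ap_ax, ap_sag)) < 0:
        ap_sag = -ap_sag
    ap = 0.5 * (ap_ax + ap_sag)
    rms = float(np.sqrt(np.mean((ap_ax - ap_sag) ** 2)))
    if rms > AP_DISAGREEMENT_WARN_MM:
        warnings.warn(
            f"AP projections of the two planes disagree "
            f"(RMS {rms:.2f} mm > {AP_DISAGREEMENT_WARN_MM} mm) for side "
            f"{axial_track.side}",
            stacklevel=2,
        )
    return Track3D(
        side=axial_track.side,
        timestamps_ms=axial_track.timestamps_ms,
        positions_mm=np.column_stack([ap, ml, cc]),
        ap_rms_disagreement_mm=rms,
    )


def amplitude_per_axis(track: Track3D) -> np.ndarray:
    """Peak-to-peak motion amplitude (mm) along AP, ML, CC."""
    if len(track.timestamps_ms) < 2:
        raise ValueError("need at least two samples")
    return np.ptp(track.positions_mm, axis=0)


def score_3dtc(
    amp_right: np.ndarray,
    amp_left: np.ndarray,
    threshold_mm: float = 1.0,
) -> SymmetryScore:
    """Automatic 3D trajectory symmetry score.

    Score 1 when the per-axis amplitude difference exceeds ``threshold_mm``
    on at least two of the three axes, with the smaller-amplitude side
    (summed over the exceeding axes) lagging; score 0 otherwise — in
    particular when exactly one axis exceeds the threshold.
    """
    amp_right = np.asarray(amp_right, dtype=float).reshape(3)
    amp_left = np.asarray(amp_left, dtype=float).reshape(3)
    if (amp_right < 0).any() or (amp_left < 0).any():
        raise ValueError("amplitudes must be non-negative")
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be positive")
    delta = np.abs(amp_right - amp_left)
    exceeding = delta > threshold_mm
    if exceeding.sum() < 2:
        return SymmetryScore(value=0, lagging="none")
    sum_r = float(amp_right[exceeding].sum())
    sum_l = float(amp_left[exceeding].sum())
    if sum_r != sum_l:
        lagging = "right" if sum_r < sum_l else "left"
    elif float(amp_right.sum()) != float(amp_left.sum()):
        lagging = "right" if amp_right.sum() < amp_left.sum() else "left"
    else:
        lagging = "left"
    return SymmetryScore(value=1, lagging=lagging)
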