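"""Readers and writers for series, tracks and result tables.

Image/mask series round-trip through multi-page TIFF (masks) and NIfTI
(images, pixel spacing in the header zooms).  Because the alternating-slice
sagittal acquisition puts the two sides on offset time bases that a plain
image container cannot carry, every series written here gets a JSON sidecar
(``<stem>.meta.json``) holding plane, pixel spacing and per-frame
timestamps; readers use the sidecar when present and otherwise fall back to
a uniform clock built from a caller-supplied frame period.

All tables are UTF-8 CSV with '.' decimal separator and LF newlines so
repeated runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .series import CondyleTrack, FrameSeries, MaskSeries, MotionPhase

FLOAT_FMT = "%.6f"


def _sidecar_path(path: Path) -> Path:
    stem = path.name
    for suffix in (".nii.gz", ".nii", ".tif", ".tiff"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return path.with_name(stem + ".meta.json")


def _write_sidecar(path: Path, series: FrameSeries) -> None:
    meta = {
        "plane": series.plane,
        "pixel_spacing_mm": list(series.pixel_spacing_mm),
        "timestamps_ms": [float(t) for t in series.timestamps_ms],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1) + "\n")


def write_mask_series(path: str | Path, masks: MaskSeries) -> Path:
    """Write a mask series as multi-page TIFF (uint8 0/1) plus sidecar."""
    path = Path(path)
    tifffile.imwrite(path, masks.frames.astype(np.uint8))
    _write_sidecar(path, masks)
    return path


def write_image_series(path: str | Path, series: FrameSeries) -> Path:
    """Write an image series as NIfTI (H, W, T) with spacing in the header."""
    path = Path(path)
    sy, sx = series.pixel_spacing_mm
    data = np.moveaxis(series.frames.astype(np.float32), 0, -1)
    img = nib.Nifti1Image(data, affine=np.diag([sx, sy, 1.0, 1.0]))
    try:
        period = series.frame_period_ms
    except ValueError:
        period = 1.0
    img.header.set_zooms((sx, sy, period))
    nib.save(img, path)
    _write_sidecar(path, series)
    return path


def _read_meta(path: Path, plane, frame_period_ms, n_frames):
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        return (
            meta["plane"],
            tuple(meta["pixel_spacing_mm"]),
            np.asarray(meta["timestamps_ms"], dtype=float),
        )
    if plane is None or frame_period_ms is None:
        raise ValueError(
            f"no sidecar for {path}; plane and frame_period_ms are required"
        )
    return plane, None, frame_period_ms * np.arange(n_frames, dtype=float)


def read_mask_series(
    path: str | Path,
    plane: str | None = None,
    pixel_spacing_mm: float | None = None,
    frame_period_ms: float | None = None,
) -> MaskSeries:
    path = Path(path)
    frames = np.asarray(tifffile.imread(path)) > 0
    if frames.ndim == 2:
        frames = frames[None]
    plane, spacing, timestamps = _read_meta(path, plane, frame_period_ms, len(frames))
    if spacing is None:
        if pixel_spacing_mm is None:
            raise ValueError("pixel_spacing_mm required without a sidecar")
        spacing = (pixel_spacing_mm, pixel_spacing_mm)
    return MaskSeries(
        frames=frames, pixel_spacing_mm=spacing, timestamps_ms=timestamps, plane=plane
    )


def read_image_series(
    path: str | Path,
    plane: str | None = None,
    frame_period_ms: float | None = None,
) -> FrameSeries:
    path = Path(path)
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.get_fdata(), dtype=float), -1, 0)
    plane_m, spacing, timestamps = _read_meta(path, plane, frame_period_ms, len(data))
    if spacing is None:
        zooms = img.header.get_zooms()
        spacing = (float(zooms[1]), float(zooms[0]))
    return FrameSeries(
        frames=data,
        pixel_spacing_mm=spacing,
        timestamps_ms=timestamps,
        plane=plane_m,
    )


def write_track_csv(path: str | Path, track: CondyleTrack) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "frame": np.arange(track.n_frames),
            "t_ms": track.timestamps_ms,
            "x_mm": track.positions_mm[:, 0],
            "y_mm": track.positions_mm[:, 1],
            "valid": track.valid.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")
    return path


def read_track_csv(path: str | Path, side: str, plane: str) -> CondyleTrack:
    df = pd.read_csv(path)
    return CondyleTrack(
        side=side,
        plane=plane,
        timestamps_ms=df["t_ms"].to_numpy(float),
        positions_mm=df[["x_mm", "y_mm"]].to_numpy(float),
        valid=df["valid"].to_numpy(bool) if "valid" in df else None,
    )


def write_phases_csv(path: str | Path, phases: list[MotionPhase]) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "kind": p.kind,
                "start_idx": p.start_index,
                "end_idx": p.end_index,
                "t_start_ms": p.t_start_ms,
                "duration_ms": p.duration_ms,
            }
            for p in phases
        ],
        columns=["kind", "start_idx", "end_idx", "t_start_ms", "duration_ms"],
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")
    return path


def write_params_csv(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")
    return path


def read_score_table(path: str | Path) -> pd.DataFrame:
    from .agreement import validate_score_table

    return validate_score_table(pd.read_csv(path))


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return path
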