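"""End-to-end orchestration: simulate -> track -> params -> fuse -> score.

A run is fully described by a :class:`RunConfig` (YAML-serializable, unknown
keys rejected, every parameter range-checked) and a seed; two runs with the
same config produce byte-identical artifacts.  Randomness is drawn from a
single root seed, forked per stage by a stable hash of the stage name so
that reordering stages never silently changes fixtures.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .agreement import DEFAULT_KAPPA_SCHEME, DEFAULT_RHO_SCHEME
from .fusion import amplitude_per_axis, fuse_3d, resample_to_common_clock, score_3dtc
from .io import (
    write_image_series,
    write_json,
    write_mask_series,
    write_params_csv,
    write_phases_csv,
    write_track_csv,
)
from .symmetry import analyze_bilateral
from .synthetic import SyntheticConfig, simulate_subject
from .tracking import (
    detect_phases,
    extract_centroids,
    odd_window_frames,
    project_displacement,
    segment_condyles,
    smooth_track,
)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (root_seed ^ zlib.crc32(stage.encode())) % (2**31 - 1)


class TrackingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    segment_threshold: float = Field(default=0.5, gt=0.0, lt=1.0)
    min_area_px: int = Field(default=20, ge=1)
    k_frames: int = Field(default=20, ge=1)
    smoothing_window_ms: float = Field(default=1100.0, gt=0.0)
    smoothing_poly_order: int = Field(default=2, ge=0)


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    onset_threshold_fraction: float = Field(default=0.10, gt=0.0, lt=1.0)
    min_phase_amplitude_mm: float = Field(default=2.0, gt=0.0)
    min_phase_duration_ms: float = Field(default=500.0, gt=0.0)


class FusionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    enabled: bool = True
    score_threshold_mm: float = Field(default=1.0, gt=0.0)


class BandsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kappa_scheme: str = DEFAULT_KAPPA_SCHEME
    rho_scheme: str = DEFAULT_RHO_SCHEME


class RunConfig(BaseModel):
    """Complete, validated description of one pipeline run."""

    model_config = ConfigDict(extra="forbid")

    subject: str = "S01"
    seed: int = 0
    use_images: bool = True
    snr: float | None = Field(default=None, gt=0.0)  # None => noiseless images
    planes: list[str] = Field(
        default_factory=lambda: ["axial", "sagittal_right", "sagittal_left"]
    )
    simulation: SyntheticConfig = Field(default_factory=SyntheticConfig)
    tracking: TrackingConfig = Field(default_factory=TrackingConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    fusion: FusionConfig = Field(default_factory=FusionConfig)
    bands: BandsConfig = Field(default_factory=BandsConfig)

    def serialize(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)


def validate_config(source) -> RunConfig:
    """Build a RunConfig from YAML text, a path, a dict or a RunConfig.

    Defaults are filled, ranges checked and unknown keys rejected; an empty
    document yields the all-defaults configuration.
    """
    if isinstance(source, RunConfig):
        raw = source.model_dump(mode="json")
    elif isinstance(source, dict):
        raw = source
    else:
        if isinstance(source, Path):
            text = source.read_text()
        elif (
            isinstance(source, str)
            and source.strip()
            and "\n" not in source
            and Path(source).is_file()
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        raw = yaml.safe_load(text) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        key = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ValueError(f"invalid config: {key}: {first['msg']}") from exc


@dataclass
class RunReport:
    """Machine-readable record of one run (regenerable from config + seed)."""

    data: dict

    def to_dict(self) -> dict:
        return self.data

    def save(self, path) -> Path:
        return write_json(path, self.data)


def _signals_for_plane(
    plane: str, sim: dict, config: RunConfig, warnings_log: list[str]
) -> dict:
    """Run tracking on one plane; returns side -> smoothed DisplacementSignal."""
    masks = sim["masks"][plane]
    if config.use_images:
        images = sim["images"][plane]
        masks = segment_condyles(
            images,
            threshold=config.tracking.segment_threshold,
            min_area_px=config.tracking.min_area_px,
        )
    line = (
        sim["reference_lines"]["axial"]
        if plane == "axial"
        else sim["reference_lines"]["sagittal"]
    )
    tracks = extract_centroids(
        masks, mid_sagittal=line if plane == "axial" else None
    )
    out = {}
    for track in tracks:
        window = odd_window_frames(
            float(np.median(np.diff(track.timestamps_ms))),
            config.tracking.smoothing_window_ms,
            config.tracking.smoothing_poly_order,
            track.n_frames,
        )
        smoothed = smooth_track(
            track, window_frames=window, poly_order=config.tracking.smoothing_poly_order
        )
        out[track.side] = {
            "track": smoothed,
            "signal": project_displacement(smoothed, line, origin_index=0),
        }
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute every stage on a simulated subject and assemble the report.

    Raises with the stage name and series identifier when a stage fails.
    When ``out_dir`` is given, all stage artifacts (tracks, phases, params,
    3D track, score, report) are written there.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    warn_log: list[str] = []

    needed = set(config.planes)
    if config.fusion.enabled:
        missing = {"axial", "sagittal_right", "sagittal_left"} - needed
        if missing:
            raise ValueError(
                f"fusion requires all three planes; missing: {sorted(missing)}"
            )

    sim_cfg = config.simulation.model_copy(update={"seed": stage_seed(config.seed, "simulate")})
    snr = config.snr if config.snr is not None else math.inf
    try:
        sim = simulate_subject(sim_cfg, snr=snr)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    per_plane: dict[str, dict] = {}
    for plane in config.planes:
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                per_plane[plane] = _signals_for_plane(plane, sim, config, warn_log)
            warn_log.extend(f"track[{plane}]: {w.message}" for w in caught)
        except Exception as exc:
            raise RuntimeError(f"stage 'track' failed on plane {plane!r}: {exc}") from exc

    # Bilateral parameter analysis per plane orientation.
    results: dict[str, dict] = {}
    plane_pairs = {}
    if "axial" in per_plane:
        plane_pairs["axial"] = (
            per_plane["axial"]["right"]["signal"],
            per_plane["axial"]["left"]["signal"],
        )
    if "sagittal_right" in per_plane and "sagittal_left" in per_plane:
        plane_pairs["sagittal"] = (
            per_plane["sagittal_right"]["right"]["signal"],
            per_plane["sagittal_left"]["left"]["signal"],
        )
    rows = []
    for orientation, (sig_r, sig_l) in plane_pairs.items():
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                params, summary = analyze_bilateral(
                    sig_r,
                    sig_l,
                    threshold_fraction=config.analysis.onset_threshold_fraction,
                    min_amplitude_mm=config.analysis.min_phase_amplitude_mm,
                    min_duration_ms=config.analysis.min_phase_duration_ms,
                )
            warn_log.extend(f"params[{orientation}]: {w.message}" for w in caught)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'params' failed on plane {orientation!r}: {exc}"
            ) from exc
        results[orientation] = {"params": params, "summary": summary}
        for p in params:
            row = {"subject": config.subject, "plane": orientation}
            row.update(p.as_row())
            rows.append(row)
    params_table = pd.DataFrame(rows)

    # 3D fusion and the automatic trajectory score.
    score = None
    track3d = {}
    if config.fusion.enabled:
        try:
            amps = {}
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                for side in ("right", "left"):
                    ax = per_plane["axial"][side]["track"]
                    sag = per_plane[f"sagittal_{side}"][side]["track"]
                    ax_r, sag_r = resample_to_common_clock([ax, sag])
                    fused = fuse_3d(
                        ax_r,
                        sag_r,
                        sim["reference_lines"]["axial"],
                        sim["reference_lines"]["sagittal"],
                    )
                    track3d[side] = fused
                    amps[side] = amplitude_per_axis(fused)
            warn_log.extend(f"fuse: {w.message}" for w in caught)
            score = score_3dtc(
                amps["right"], amps["left"], threshold_mm=config.fusion.score_threshold_mm
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'fuse' failed: {exc}") from exc

    report = {
        "software": {"name": "condylokin", "version": __version__},
        "config": config.model_dump(mode="json"),
        "subject": config.subject,
        "ground_truth": sim["ground_truth"].to_dict(),
        "parameters": {
            orientation: {
                "per_cycle": [p.as_row() for p in res["params"]],
                "means": res["summary"].means,
                "n_cycles": res["summary"].n_cycles,
            }
            for orientation, res in results.items()
        },
        "score_3dtc": (
            {"value": score.value, "lagging": score.lagging} if score else None
        ),
        "warnings": warn_log,
    }

    if out_path is not None:
        for plane, sides in per_plane.items():
            for side, d in sides.items():
                write_track_csv(out_path / f"track_{plane}_{side}.csv", d["track"])
                phases = detect_phases(
                    d["signal"],
                    config.analysis.min_phase_amplitude_mm,
                    config.analysis.min_phase_duration_ms,
                )
                write_phases_csv(out_path / f"phases_{plane}_{side}.csv", phases)
        if len(params_table):
            write_params_csv(out_path / "params.csv", params_table)
        if track3d:
            rows3d = []
            for side, tr in track3d.items():
                for t, (ap, ml, cc) in zip(tr.timestamps_ms, tr.positions_mm):
                    rows3d.append(
                        {"side": side, "t_ms": t, "AP_mm": ap, "ML_mm": ml, "CC_mm": cc}
                    )
            write_params_csv(out_path / "track3d.csv", pd.DataFrame(rows3d))
        if score is not None:
            write_json(
                out_path / "score.json",
                {"value": score.value, "lagging": score.lagging},
            )
        write_json(out_path / "report.json", report)

    return RunReport(data=report)


def write_simulation(config: SyntheticConfig, out_dir: str | Path, snr: float = 10.0) -> Path:
    """Write a simulated subject's raw artifacts (tracks, masks, images, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_subject(config, snr=snr)
    for plane in ("axial", "sagittal_right", "sagittal_left"):
        short = "axial" if plane == "axial" else plane.replace("sagittal_", "sagittal-")
        for track in sim["tracks"][plane]:
            write_track_csv(out / f"tracks_{track.side}_{short}.csv", track)
        write_mask_series(out / f"masks_{short}.tif", sim["masks"][plane])
        write_image_series(out / f"images_{short}.nii.gz", sim["images"][plane])
    write_json(out / "ground_truth.json", sim["ground_truth"].to_dict())
    return out
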