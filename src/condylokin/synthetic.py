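"""Synthetic bilateral condylar-motion phantom with known injected asymmetry.

The phantom emulates the acquisition used for real-time TMJ imaging: slow jaw
opening and closing movements of roughly 5 s each, repeated over several
cycles, imaged in one axial plane (both condyles, ~21 ms frame period,
1.41 mm pixels) and two sagittal planes acquired by alternating slices (one
condyle each, time bases offset by half the per-side period, 0.36 mm pixels).

Each side's displacement along its in-plane reference direction follows a
raised-cosine position ramp per phase

    d(t) = A * (1 - cos(pi * t / T)) / 2        (opening, mirrored closing)

which has zero endpoint velocity and a closed-form velocity peak at
mid-phase — so onset latency and velocity-peak delay have analytic ground
truth.  Asymmetry is injected on the configured lagging side:

* onset latency   — the lagging side's phases start ``latency_fraction * T``
  later (phase durations preserved);
* velocity-peak delay — a C2-smooth monotone time reparameterization of
  the phase shifts only the velocity peak by ``vpd_fraction * T`` while
  onset, end and amplitude are preserved;
* amplitude       — per-side amplitudes are set independently.

Additive Gaussian noise is applied to displacement samples (the tracking
stage consumes centroids, not raw k-space, so image-domain Rician noise is
out of scope); image noise is modelled separately in
:func:`render_image_series`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal

import numpy as np
from scipy.integrate import cumulative_trapezoid
from pydantic import BaseModel, ConfigDict, Field, model_validator
from pydantic import ValidationError as PydanticValidationError

from .series import (
    SIDES,
    CondyleTrack,
    FrameSeries,
    MaskSeries,
    ReferenceLine,
)

# Phantom scene geometry (mm). Field-of-view values follow the acquisition
# protocol; baseline positions place the condyles well inside the image.
AXIAL_FOV_MM = 192.0
SAGITTAL_FOV_MM = 100.0
AXIAL_LATERAL_OFFSET_MM = 30.0  # each condyle this far from the mid-sagittal line
AXIAL_BASELINE_Y_MM = 60.0
SAGITTAL_BASELINE_X_MM = 25.0
SAGITTAL_BASELINE_Y_MM = 50.0


class InvalidConfigError(ValueError):
    """Raised when a phantom configuration is internally inconsistent."""


class SyntheticConfig(BaseModel):
    """Ground-truth description of one simulated subject.

    Durations are seconds, periods milliseconds, spatial quantities mm.
    ``latency_fraction_*`` and ``vpd_fraction`` are fractions of the
    respective phase duration; ``lagging_side`` selects which condyle
    receives the temporal asymmetry.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    def __init__(self, **data):
        try:
            super().__init__(**data)
        except PydanticValidationError as exc:
            raise InvalidConfigError(str(exc)) from exc

    amplitude_right_mm: float = Field(default=15.0, gt=0)
    amplitude_left_mm: float = Field(default=15.0, gt=0)
    open_duration_s: float = Field(default=5.0, gt=0)
    close_duration_s: float = Field(default=5.0, gt=0)
    n_cycles: int = Field(default=3, ge=1)
    latency_fraction_open: float = Field(default=0.0, ge=0.0, le=0.5)
    latency_fraction_close: float = Field(default=0.0, ge=0.0, le=0.5)
    vpd_fraction: float = Field(default=0.0, ge=0.0, le=0.5)
    lagging_side: Literal["left", "right", "none"] = "none"
    noise_sd_mm: float = Field(default=0.0, ge=0.0)
    seed: int = 0
    axial_frame_period_ms: float = Field(default=21.0, gt=0)
    sagittal_frame_period_ms: float = Field(default=51.0, gt=0)
    pixel_spacing_axial_mm: float = Field(default=1.41, gt=0)
    pixel_spacing_sagittal_mm: float = Field(default=0.36, gt=0)
    condyle_semiaxes_mm: tuple[float, float] = (5.0, 7.0)

    @model_validator(mode="after")
    def _check_consistency(self) -> "SyntheticConfig":
        a, b = self.condyle_semiaxes_mm
        if a <= 0 or b <= 0:
            raise InvalidConfigError("condyle_semiaxes_mm must be positive")
        if self.lagging_side == "none":
            asym = (
                self.latency_fraction_open,
                self.latency_fraction_close,
                self.vpd_fraction,
            )
            if any(f != 0 for f in asym):
                raise InvalidConfigError(
                    "lagging_side='none' requires zero latency/vpd fractions"
                )
            if self.amplitude_right_mm != self.amplitude_left_mm:
                raise InvalidConfigError(
                    "lagging_side='none' requires equal amplitudes"
                )
        if self.latency_fraction_open + self.vpd_fraction > 0.5 + 1e-12:
            raise InvalidConfigError(
                "latency_fraction_open + vpd_fraction must not exceed 0.5 "
                "(onset shift plus velocity-peak shift exceeds the phase)"
            )
        if self.latency_fraction_close + self.vpd_fraction > 0.5 + 1e-12:
            raise InvalidConfigError(
                "latency_fraction_close + vpd_fraction must not exceed 0.5"
            )
        delay_open_s = self.latency_fraction_open * self.open_duration_s
        delay_close_s = self.latency_fraction_close * self.close_duration_s
        if delay_close_s < delay_open_s - 1e-9:
            raise InvalidConfigError(
                "the closing onset delay cannot be smaller than the opening "
                "onset delay (closing would start before opening completes)"
            )
        if self.n_cycles > 1 and not math.isclose(
            delay_open_s, delay_close_s, abs_tol=1e-9
        ):
            # Back-to-back cycles leave no idle time: a lagging side whose
            # phases keep their full duration must carry one common onset
            # shift, or consecutive phases would overlap.
            raise InvalidConfigError(
                "with n_cycles > 1 the opening and closing onset delays must "
                "be equal in absolute time "
                f"({delay_open_s:.3f} s vs {delay_close_s:.3f} s)"
            )
        return self

    @property
    def cycle_duration_s(self) -> float:
        return self.open_duration_s + self.close_duration_s

    def total_duration_s(self) -> float:
        delay = max(
            self.latency_fraction_open * self.open_duration_s,
            self.latency_fraction_close * self.close_duration_s,
        )
        return self.n_cycles * self.cycle_duration_s + delay


@dataclass(frozen=True)
class GroundTruthRecord:
    """Analytic ground truth for parameter-recovery oracles."""

    true_latency_norm: float
    true_vpd_norm: float
    true_mda_mm: float
    true_mdd_mm: float
    lagging_side: str

    def __post_init__(self) -> None:
        vals = (
            self.true_latency_norm,
            self.true_vpd_norm,
            self.true_mda_mm,
            self.true_mdd_mm,
        )
        if any(v < 0 for v in vals):
            raise ValueError("ground-truth values must be non-negative")
        if self.lagging_side == "none" and any(v != 0 for v in vals):
            raise ValueError("lagging_side='none' implies all-zero ground truth")

    def to_dict(self) -> dict:
        return {
            "true_latency_norm": self.true_latency_norm,
            "true_vpd_norm": self.true_vpd_norm,
            "true_mda_mm": self.true_mda_mm,
            "true_mdd_mm": self.true_mdd_mm,
            "lagging_side": self.lagging_side,
        }


def _raised_cosine(u: np.ndarray) -> np.ndarray:
    """Position ramp 0 -> 1 over phase fraction u in [0, 1]."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0.0, 1.0)))


def _smoothstep5(x: np.ndarray) -> np.ndarray:
    """C2 smoothstep 0 -> 1 (quintic; zero slope and curvature at both ends)."""
    x = np.clip(x, 0.0, 1.0)
    return x**3 * (10.0 - 15.0 * x + 6.0 * x**2)


@lru_cache(maxsize=64)
def _shifted_shape_table(vpd_fraction: float, n: int = 4097):
    """Dense lookup table of the peak-shifted position ramp on [0, 1].

    The raised-cosine profile is reparameterized with a C2 monotone warp
    ``phi(u) = u - v * g(u)`` where ``g`` is a quintic smoothstep bump that
    equals 1 exactly at ``u* = 0.5 + v`` with zero slope and curvature
    there.  The speed along the warped phase is proportional to
    ``sin(pi * phi(u))``, which peaks exactly where ``phi = 0.5``, i.e. at
    ``u*`` — and because the warp is C2, the speed maximum is smooth and
    survives symmetric filtering without displacement.  The position ramp
    is the normalized integral of the speed, tabulated densely.
    """
    v = vpd_fraction
    uu = np.linspace(0.0, 1.0, n)
    t1 = 0.5 + v
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(
            uu <= t1,
            _smoothstep5(uu / t1),
            _smoothstep5((1.0 - uu) / max(1.0 - t1, 1e-12)),
        )
    phi = uu - v * g
    speed = np.sin(np.pi * phi)
    shape = cumulative_trapezoid(speed, uu, initial=0.0)
    shape /= shape[-1]
    return uu, shape


def _phase_shape(u: np.ndarray, vpd_fraction: float) -> np.ndarray:
    """Normalized position ramp 0 -> 1 with a smoothly shifted velocity peak.

    For ``vpd_fraction = 0`` this is the raised-cosine ramp; otherwise the
    C2 time-warped ramp whose speed peak sits exactly at phase fraction
    ``0.5 + vpd_fraction`` while onset, end, endpoint velocities and total
    amplitude are preserved.
    """
    if vpd_fraction == 0.0:
        return _raised_cosine(u)
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    uu, shape = _shifted_shape_table(float(vpd_fraction))
    return np.interp(u, uu, shape)


def _side_displacement(
    t_s: np.ndarray,
    amplitude_mm: float,
    open_s: float,
    close_s: float,
    n_cycles: int,
    delay_open_s: float = 0.0,
    delay_close_s: float = 0.0,
    vpd_fraction: float = 0.0,
) -> np.ndarray:
    """Noiseless displacement of one side, evaluated at arbitrary times."""
    t = np.asarray(t_s, dtype=float)
    cycle = open_s + close_s
    k = np.clip(np.floor(t / cycle).astype(int), 0, n_cycles - 1)
    u = t - k * cycle  # time within the assigned cycle (may exceed `cycle`)

    frac_open = (u - delay_open_s) / open_s
    frac_close = (u - open_s - delay_close_s) / close_s
    # A lagging side's closing from the previous cycle spills into the first
    # delay_open_s of the current one.
    frac_close_prev = (u + close_s - delay_close_s) / close_s

    d_open = amplitude_mm * _phase_shape(frac_open, vpd_fraction)
    d_close = amplitude_mm * (1.0 - _phase_shape(frac_close, vpd_fraction))
    d_close_prev = amplitude_mm * (
        1.0 - _phase_shape(frac_close_prev, vpd_fraction)
    )

    before_open = u < delay_open_s
    in_prev_close = before_open & (k > 0) & (frac_close_prev < 1.0)
    in_close = frac_close >= 0.0

    out = np.where(frac_open >= 1.0, amplitude_mm, d_open)
    out = np.where(in_close, np.where(frac_close >= 1.0, 0.0, d_close), out)
    out = np.where(before_open, 0.0, out)
    out = np.where(in_prev_close, d_close_prev, out)
    out = np.where(t < 0, 0.0, out)
    return out


def _side_params(config: SyntheticConfig, side: str) -> dict:
    """Profile arguments for one side (the lagging side carries the shifts)."""
    amplitude = (
        config.amplitude_right_mm if side == "right" else config.amplitude_left_mm
    )
    lagging = config.lagging_side == side
    return dict(
        amplitude_mm=amplitude,
        open_s=config.open_duration_s,
        close_s=config.close_duration_s,
        n_cycles=config.n_cycles,
        delay_open_s=(
            config.latency_fraction_open * config.open_duration_s if lagging else 0.0
        ),
        delay_close_s=(
            config.latency_fraction_close * config.close_duration_s if lagging else 0.0
        ),
        vpd_fraction=config.vpd_fraction if lagging else 0.0,
    )


def displacement_profile(
    config: SyntheticConfig, side: str, t_s: np.ndarray
) -> np.ndarray:
    """Noiseless closed-form displacement (mm) of one side at times ``t_s``."""
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    return _side_displacement(t_s, **_side_params(config, side))


def _true_mdd_mm(config: SyntheticConfig, n_grid: int = 20001) -> float:
    """Largest |d_R - d_L| with each side referenced to its own phase start.

    Evaluated on a dense grid per phase kind over the first cycle's paired
    windows (later cycles repeat the same geometry by construction).
    """
    if config.lagging_side == "none":
        return 0.0
    T_o, T_c = config.open_duration_s, config.close_duration_s
    delay_o = config.latency_fraction_open * T_o
    delay_c = config.latency_fraction_close * T_c
    worst = 0.0
    # Opening: both sides start from displacement 0 at their phase start.
    t = np.linspace(0.0, T_o + delay_o, n_grid)
    d_r = displacement_profile(config, "right", t)
    d_l = displacement_profile(config, "left", t)
    worst = max(worst, float(np.max(np.abs(d_r - d_l))))
    # Closing: each side starts at its own amplitude.
    t = np.linspace(T_o, T_o + T_c + delay_c, n_grid)
    d_r = displacement_profile(config, "right", t) - config.amplitude_right_mm
    d_l = displacement_profile(config, "left", t) - config.amplitude_left_mm
    worst = max(worst, float(np.max(np.abs(d_r - d_l))))
    return worst


def ground_truth_record(config: SyntheticConfig) -> GroundTruthRecord:
    """Fill the ground truth analytically from the configuration."""
    if config.lagging_side == "none":
        return GroundTruthRecord(0.0, 0.0, 0.0, 0.0, "none")
    return GroundTruthRecord(
        true_latency_norm=config.latency_fraction_open,
        true_vpd_norm=config.vpd_fraction,
        true_mda_mm=abs(config.amplitude_right_mm - config.amplitude_left_mm),
        true_mdd_mm=_true_mdd_mm(config),
        lagging_side=config.lagging_side,
    )


def make_interleaved_timestamps(
    n_frames: int, per_side_period_ms: float, side_offset_ms: float = 0.0
) -> np.ndarray:
    """Frame-start times ``t_k = side_offset + k * per_side_period`` (ms).

    Alternating-slice sagittal acquisition gives the right and left series
    offsets of 0 and half the per-side period respectively.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if per_side_period_ms <= 0:
        raise ValueError("per_side_period_ms must be positive")
    if side_offset_ms < 0:
        raise ValueError("side_offset_ms must be non-negative")
    return side_offset_ms + per_side_period_ms * np.arange(n_frames, dtype=float)


def nominal_frame_period(tr_ms: float, n_spokes: int) -> int:
    """Nominal frame period of a radial acquisition, floor(TR x spokes) in ms."""
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    if n_spokes < 1:
        raise ValueError("n_spokes must be >= 1")
    return int(math.floor(tr_ms * n_spokes))


def plane_timestamps(config: SyntheticConfig, plane: str) -> np.ndarray:
    """Sampling times (ms) of one plane over the whole simulated run."""
    total_ms = config.total_duration_s() * 1000.0
    if plane == "axial":
        period, offset = config.axial_frame_period_ms, 0.0
    elif plane == "sagittal_right":
        period, offset = 2.0 * config.sagittal_frame_period_ms, 0.0
    elif plane == "sagittal_left":
        period, offset = (
            2.0 * config.sagittal_frame_period_ms,
            config.sagittal_frame_period_ms,
        )
    else:
        raise ValueError(f"unknown plane {plane!r}")
    n = int(math.floor((total_ms - offset) / period)) + 1
    return make_interleaved_timestamps(n, period, offset)


def generate_displacement_profiles(
    config: SyntheticConfig,
    plane: str = "axial",
    timestamps_ms: np.ndarray | None = None,
) -> tuple[
    "DisplacementSignalPair",
    GroundTruthRecord,
]:
    """Sample both sides' displacement signals plus their ground truth.

    On the axial plane both sides share one time base; on the sagittal
    planes each side is sampled on its own interleaved time base.  Seeded
    zero-mean Gaussian noise of sd ``noise_sd_mm`` is added independently
    per sample.
    """
    from .series import DisplacementSignal

    rng = np.random.default_rng(config.seed)
    signals = {}
    for side in SIDES:
        if timestamps_ms is not None:
            t_ms = np.asarray(timestamps_ms, dtype=float)
            sig_plane = plane
        elif plane == "axial":
            t_ms = plane_timestamps(config, "axial")
            sig_plane = "axial"
        else:
            sig_plane = f"sagittal_{side}"
            t_ms = plane_timestamps(config, sig_plane)
        d = displacement_profile(config, side, t_ms / 1000.0)
        if config.noise_sd_mm > 0:
            d = d + rng.normal(0.0, config.noise_sd_mm, size=d.shape)
        signals[side] = DisplacementSignal(
            timestamps_ms=t_ms, displacement_mm=d, side=side, plane=sig_plane
        )
    return (signals["right"], signals["left"]), ground_truth_record(config)


# Backwards-friendly alias used in annotations above.
DisplacementSignalPair = tuple


def _plane_geometry(config: SyntheticConfig, plane: str):
    if plane == "axial":
        spacing = config.pixel_spacing_axial_mm
        n_px = int(round(AXIAL_FOV_MM / spacing))
    else:
        spacing = config.pixel_spacing_sagittal_mm
        n_px = int(round(SAGITTAL_FOV_MM / spacing))
    return spacing, (n_px, n_px)


def ground_truth_tracks(config: SyntheticConfig, plane: str) -> list[CondyleTrack]:
    """Noiseless ground-truth 2D centroid tracks for one plane.

    Axial: both condyles mirror-symmetric about the mid-sagittal line,
    moving along +y (the mid-sagittal direction).  Sagittal: one condyle per
    plane moving along +x (the Frankfurt-horizontal direction).
    """
    spacing, (n_rows, n_cols) = _plane_geometry(config, plane)
    tracks = []
    if plane == "axial":
        t_ms = plane_timestamps(config, "axial")
        mid_x = (n_cols - 1) / 2.0 * spacing
        for side, sign in (("right", -1.0), ("left", +1.0)):
            d = displacement_profile(config, side, t_ms / 1000.0)
            x = np.full_like(d, mid_x + sign * AXIAL_LATERAL_OFFSET_MM)
            y = AXIAL_BASELINE_Y_MM + d
            tracks.append(
                CondyleTrack(
                    side=side,
                    plane=plane,
                    timestamps_ms=t_ms,
                    positions_mm=np.column_stack([x, y]),
                )
            )
    else:
        side = plane.split("_", 1)[1]
        t_ms = plane_timestamps(config, plane)
        d = displacement_profile(config, side, t_ms / 1000.0)
        x = SAGITTAL_BASELINE_X_MM + d
        y = np.full_like(d, SAGITTAL_BASELINE_Y_MM)
        tracks.append(
            CondyleTrack(
                side=side,
                plane=plane,
                timestamps_ms=t_ms,
                positions_mm=np.column_stack([x, y]),
            )
        )
    return tracks


def phantom_reference_lines(config: SyntheticConfig) -> dict[str, ReferenceLine]:
    """Mid-sagittal (axial) and Frankfurt-horizontal (sagittal) lines."""
    spacing, (n_rows, n_cols) = _plane_geometry(config, "axial")
    mid_x = (n_cols - 1) / 2.0 * spacing
    return {
        "axial": ReferenceLine.vertical(mid_x),
        "sagittal": ReferenceLine.horizontal(SAGITTAL_BASELINE_Y_MM),
    }


def render_mask_series(
    tracks: list[CondyleTrack] | CondyleTrack,
    config: SyntheticConfig,
    plane: str,
) -> MaskSeries:
    """Rasterize filled ellipses at the ground-truth positions, per frame.

    Axial frames contain two ellipses (right and left condyle), sagittal
    frames one.  Pixel (row, col) is foreground when its centre
    (col*spacing, row*spacing) falls inside the ellipse.
    """
    if isinstance(tracks, CondyleTrack):
        tracks = [tracks]
    expected = 2 if plane == "axial" else 1
    if len(tracks) != expected:
        raise ValueError(f"plane {plane!r} requires {expected} track(s)")
    spacing, (n_rows, n_cols) = _plane_geometry(config, plane)
    a, b = config.condyle_semiaxes_mm
    t_ms = tracks[0].timestamps_ms
    for tr in tracks[1:]:
        if not np.array_equal(tr.timestamps_ms, t_ms):
            raise ValueError("all tracks must share the plane's time base")

    xs = np.arange(n_cols) * spacing
    ys = np.arange(n_rows) * spacing
    x_max, y_max = xs[-1], ys[-1]
    masks = np.zeros((len(t_ms), n_rows, n_cols), dtype=bool)
    for i in range(len(t_ms)):
        for tr in tracks:
            cx, cy = tr.positions_mm[i]
            if cx - a < 0 or cx + a > x_max or cy - b < 0 or cy + b > y_max:
                raise ValueError(
                    f"condyle ellipse leaves the field of view at frame {i} "
                    f"({tr.plane}/{tr.side})"
                )
            ellipse = ((xs[None, :] - cx) / a) ** 2 + (
                (ys[:, None] - cy) / b
            ) ** 2 <= 1.0
            masks[i] |= ellipse
    return MaskSeries(
        frames=masks,
        pixel_spacing_mm=(spacing, spacing),
        timestamps_ms=t_ms,
        plane=plane,
    )


def render_image_series(
    masks: MaskSeries, snr: float, seed: int = 0
) -> FrameSeries:
    """Foreground-1 / background-0 images with additive noise of sd 1/snr.

    ``snr = math.inf`` renders noiseless images.  Intensities are clipped to
    be non-negative; output is deterministic for a fixed seed.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    img = masks.frames.astype(float)
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, 1.0 / snr, size=img.shape)
        img = np.clip(img, 0.0, None)
    return FrameSeries(
        frames=img,
        pixel_spacing_mm=masks.pixel_spacing_mm,
        timestamps_ms=masks.timestamps_ms,
        plane=masks.plane,
    )


def simulate_subject(
    config: SyntheticConfig, snr: float = math.inf
) -> dict:
    """Render one subject's full acquisition: masks + images for all planes.

    Returns a dict with per-plane ground-truth tracks, mask series, image
    series, the reference lines and the :class:`GroundTruthRecord`.
    """
    lines = phantom_reference_lines(config)
    out = {
        "config": config,
        "ground_truth": ground_truth_record(config),
        "reference_lines": lines,
        "tracks": {},
        "masks": {},
        "images": {},
    }
    rng = np.random.default_rng(config.seed)
    for plane in ("axial", "sagittal_right", "sagittal_left"):
        tracks = ground_truth_tracks(config, plane)
        masks = render_mask_series(tracks, config, plane)
        image_seed = int(rng.integers(0, 2**31 - 1))
        out["tracks"][plane] = tracks
        out["masks"][plane] = masks
        out["images"][plane] = render_image_series(masks, snr, seed=image_seed)
    return out
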