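"""Bilateral symmetry parameters of condylar motion, per matched phase.

Four parameters quantify right/left asymmetry within one paired opening or
closing phase:

* **L** (latency) — normalized offset between the sides' motion onsets,
  with onset defined as the first instant the speed reaches 10% of the
  phase's peak speed;
* **VPD** (velocity peak delay) — normalized offset between the sides'
  maximum-speed instants;
* **MDA** (maximal difference of amplitudes, mm) — absolute difference of
  the sides' peak-to-peak displacement amplitudes;
* **MDD** (maximal displacement difference) — largest instantaneous
  difference between the sides' displacement curves, each referenced to its
  own phase-start position; reported both in mm and normalized by the
  largest motion amplitude in the whole series.

Temporal parameters are normalized by the mean of the two phase durations
(symmetric in the sides, and equal to the common duration when the sides
agree).  The two condyles sit ~100 mm apart, so MDD deliberately compares
phase-start-relative displacements, not absolute positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import DisplacementSignal, MotionPhase, PhasePair
from .tracking import compute_velocity, detect_phases, pair_phases

PARAM_COLUMNS = ["L", "VPD", "MDD_mm", "MDD_norm", "MDA_mm"]


class FlatPhaseError(ValueError):
    """Raised when a phase has no measurable motion (zero peak velocity)."""


@dataclass
class SymmetryParameters:
    """The four symmetry parameters for one paired phase."""

    phase_kind: str
    latency_norm: float
    vpd_norm: float
    mdd_mm: float
    mdd_norm: float
    mda_mm: float
    lagging_side_latency: str  # "right" | "left" | "none"
    cycle_index: int = 0

    def __post_init__(self) -> None:
        for name in ("latency_norm", "vpd_norm", "mdd_mm", "mdd_norm", "mda_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("latency_norm", "vpd_norm"):
            v = getattr(self, name)
            if v > 1.0:
                warnings.warn(
                    f"{name}={v:.3f} exceeds 1; clipping to 1", stacklevel=2
                )
                setattr(self, name, 1.0)

    def as_row(self) -> dict:
        return {
            "cycle": self.cycle_index,
            "phase_kind": self.phase_kind,
            "L": self.latency_norm,
            "VPD": self.vpd_norm,
            "MDD_mm": self.mdd_mm,
            "MDD_norm": self.mdd_norm,
            "MDA_mm": self.mda_mm,
            "lagging_side": self.lagging_side_latency,
        }


@dataclass
class SubjectSummary:
    """Cycle-averaged parameters per phase kind, plus the per-cycle table."""

    means: dict  # {phase_kind: {param: mean}}
    n_cycles: int
    table: pd.DataFrame

    def mean(self, param: str, phase_kind: str | None = None) -> float:
        if phase_kind is not None:
            return self.means[phase_kind][param]
        vals = [m[param] for m in self.means.values() if param in m]
        return float(np.mean(vals))


def phase_onset_time(
    signal: DisplacementSignal,
    velocity: np.ndarray,
    phase: MotionPhase,
    threshold_fraction: float = 0.10,
) -> float:
    """Motion onset (ms): first time |v| reaches the threshold within the phase.

    The threshold is ``threshold_fraction`` of the peak speed over the phase;
    the crossing is located by linear interpolation between samples.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    t = signal.timestamps_ms
    lo, hi = phase.start_index, phase.end_index + 1
    speed = np.abs(velocity[lo:hi])
    vmax = speed.max()
    if vmax <= 0:
        raise FlatPhaseError(
            f"flat phase: zero peak velocity in {phase.kind} phase at "
            f"t={phase.t_start_ms:.0f} ms"
        )
    thr = threshold_fraction * vmax
    above = np.flatnonzero(speed >= thr)
    i = int(above[0])
    if i == 0:
        return float(t[lo])
    t0, t1 = t[lo + i - 1], t[lo + i]
    v0, v1 = speed[i - 1], speed[i]
    frac = (thr - v0) / (v1 - v0) if v1 > v0 else 1.0
    return float(t0 + frac * (t1 - t0))


def _peak_speed_time(
    signal: DisplacementSignal,
    velocity: np.ndarray,
    phase: MotionPhase,
    refine_fraction: float = 0.95,
) -> float:
    """Time (ms) of maximum speed within a phase, with sub-sample refinement.

    A least-squares parabola is fitted to the samples around the discrete
    peak whose speed stays above ``refine_fraction`` of it, truncated to a
    window symmetric about the peak sample; its vertex (clamped to the
    window) is returned.  Fitting the near-peak run rather than three
    points averages noise; keeping the window symmetric avoids the vertex
    being dragged toward the flatter flank of an asymmetric speed profile.
    """
    t = signal.timestamps_ms
    lo, hi = phase.start_index, phase.end_index + 1
    speed = np.abs(velocity[lo:hi])
    vmax = speed.max()
    if vmax <= 0:
        raise FlatPhaseError(
            f"flat phase: zero peak velocity in {phase.kind} phase at "
            f"t={phase.t_start_ms:.0f} ms"
        )
    ipk = int(np.argmax(speed))
    a = ipk
    while a > 0 and speed[a - 1] >= refine_fraction * vmax:
        a -= 1
    b = ipk
    while b < len(speed) - 1 and speed[b + 1] >= refine_fraction * vmax:
        b += 1
    half = max(min(ipk - a, b - ipk), 1)
    a = max(0, ipk - half)
    b = min(len(speed) - 1, ipk + half)
    if b - a < 2:
        return float(t[lo + ipk])
    tt = t[lo + a : lo + b + 1] - t[lo + ipk]
    vv = speed[a : b + 1]
    coeffs = np.polyfit(tt, vv, 2)
    if coeffs[0] >= 0:  # not concave; fall back to the discrete peak
        return float(t[lo + ipk])
    vertex = -coeffs[1] / (2 * coeffs[0])
    vertex = float(np.clip(vertex, tt[0], tt[-1]))
    return float(t[lo + ipk] + vertex)


def compute_latency(
    pair: PhasePair,
    right_signal: DisplacementSignal,
    right_velocity: np.ndarray,
    left_signal: DisplacementSignal,
    left_velocity: np.ndarray,
    threshold_fraction: float = 0.10,
) -> tuple[float, str]:
    """Normalized onset latency and the lagging side for one paired phase.

    ``L = |onset_R - onset_L| / mean(duration_R, duration_L)``.  Raw onset
    differences below half the coarsest frame period are below the temporal
    resolution floor and reported as (0, "none").
    """
    onset_r = phase_onset_time(
        right_signal, right_velocity, pair.right_phase, threshold_fraction
    )
    onset_l = phase_onset_time(
        left_signal, left_velocity, pair.left_phase, threshold_fraction
    )
    delta = onset_r - onset_l
    floor = 0.5 * max(right_signal.frame_period_ms, left_signal.frame_period_ms)
    if abs(delta) < floor:
        return 0.0, "none"
    latency = abs(delta) / pair.mean_duration_ms
    lagging = "right" if delta > 0 else "left"
    return float(latency), lagging


def compute_vpd(
    pair: PhasePair,
    right_signal: DisplacementSignal,
    right_velocity: np.ndarray,
    left_signal: DisplacementSignal,
    left_velocity: np.ndarray,
) -> float:
    """Normalized velocity-peak delay for one paired phase."""
    tp_r = _peak_speed_time(right_signal, right_velocity, pair.right_phase)
    tp_l = _peak_speed_time(left_signal, left_velocity, pair.left_phase)
    return float(abs(tp_r - tp_l) / pair.mean_duration_ms)


def _phase_values(signal: DisplacementSignal, phase: MotionPhase) -> np.ndarray:
    return signal.displacement_mm[phase.start_index : phase.end_index + 1]


def compute_mda(
    pair: PhasePair,
    right_signal: DisplacementSignal,
    left_signal: DisplacementSignal,
) -> float:
    """Absolute difference of per-side peak-to-peak amplitudes (mm)."""
    amp_r = float(np.ptp(_phase_values(right_signal, pair.right_phase)))
    amp_l = float(np.ptp(_phase_values(left_signal, pair.left_phase)))
    return abs(amp_r - amp_l)


def series_amplitude_mm(*signals: DisplacementSignal) -> float:
    """Largest peak-to-peak displacement over whole signals."""
    return max(float(np.ptp(s.displacement_mm)) for s in signals)


def compute_mdd(
    pair: PhasePair,
    right_signal: DisplacementSignal,
    left_signal: DisplacementSignal,
    series_amplitude: float | None = None,
) -> tuple[float, float]:
    """Maximal displacement difference (mm, and normalized).

    Both sides are linearly resampled onto the union of sample times over
    the paired phases, each referenced to its displacement at its own phase
    start.  The normalization denominator is the largest peak-to-peak
    amplitude over both full signals.
    """
    if series_amplitude is None:
        series_amplitude = series_amplitude_mm(right_signal, left_signal)
    if series_amplitude <= 0:
        raise ValueError("zero series amplitude: cannot normalize MDD")
    t0 = min(pair.right_phase.t_start_ms, pair.left_phase.t_start_ms)
    t1 = max(pair.right_phase.t_end_ms, pair.left_phase.t_end_ms)
    t_r, d_r = right_signal.timestamps_ms, right_signal.displacement_mm
    t_l, d_l = left_signal.timestamps_ms, left_signal.displacement_mm
    grid = np.union1d(
        t_r[(t_r >= t0) & (t_r <= t1)], t_l[(t_l >= t0) & (t_l <= t1)]
    )
    rel_r = np.interp(grid, t_r, d_r) - d_r[pair.right_phase.start_index]
    rel_l = np.interp(grid, t_l, d_l) - d_l[pair.left_phase.start_index]
    mdd_mm = float(np.max(np.abs(rel_r - rel_l)))
    return mdd_mm, mdd_mm / series_amplitude


def evaluate_pair(
    pair: PhasePair,
    right_signal: DisplacementSignal,
    right_velocity: np.ndarray,
    left_signal: DisplacementSignal,
    left_velocity: np.ndarray,
    threshold_fraction: float = 0.10,
    series_amplitude: float | None = None,
) -> SymmetryParameters:
    """All four symmetry parameters for one paired phase."""
    latency, lagging = compute_latency(
        pair, right_signal, right_velocity, left_signal, left_velocity,
        threshold_fraction,
    )
    vpd = compute_vpd(pair, right_signal, right_velocity, left_signal, left_velocity)
    mda = compute_mda(pair, right_signal, left_signal)
    mdd_mm, mdd_norm = compute_mdd(
        pair, right_signal, left_signal, series_amplitude
    )
    return SymmetryParameters(
        phase_kind=pair.kind,
        latency_norm=latency,
        vpd_norm=vpd,
        mdd_mm=mdd_mm,
        mdd_norm=mdd_norm,
        mda_mm=mda,
        lagging_side_latency=lagging,
        cycle_index=pair.cycle_index,
    )


def summarize_subject(params: list[SymmetryParameters]) -> SubjectSummary:
    """Arithmetic means of each parameter per phase kind across cycles."""
    if not params:
        raise ValueError("no per-cycle parameters to summarize")
    table = pd.DataFrame([p.as_row() for p in params])
    means = {}
    for kind, group in table.groupby("phase_kind"):
        means[kind] = {c: float(group[c].mean()) for c in PARAM_COLUMNS}
    n_cycles = int(table.groupby("phase_kind")["cycle"].count().max())
    return SubjectSummary(means=means, n_cycles=n_cycles, table=table)


def analyze_bilateral(
    right_signal: DisplacementSignal,
    left_signal: DisplacementSignal,
    threshold_fraction: float = 0.10,
    min_amplitude_mm: float = 2.0,
    min_duration_ms: float = 500.0,
) -> tuple[list[SymmetryParameters], SubjectSummary]:
    """Detect phases on smoothed signals, pair them and evaluate all cycles."""
    vel_r = compute_velocity(right_signal)
    vel_l = compute_velocity(left_signal)
    phases_r = detect_phases(right_signal, min_amplitude_mm, min_duration_ms)
    phases_l = detect_phases(left_signal, min_amplitude_mm, min_duration_ms)
    pairs = pair_phases(phases_r, phases_l)
    if not pairs:
        raise ValueError("no paired motion phases detected")
    series_amp = series_amplitude_mm(right_signal, left_signal)
    params = [
        evaluate_pair(
            p, right_signal, vel_r, left_signal, vel_l,
            threshold_fraction, series_amp,
        )
        for p in pairs
    ]
    return params, summarize_subject(params)
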