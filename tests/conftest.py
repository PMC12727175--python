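"""Shared fixtures and helpers: signal-level recovery chains, tiny phantoms."""

from __future__ import annotations

import numpy as np
import pytest

import condylokin as ck
from condylokin.tracking import odd_window_frames, smooth_signal

SMOOTHING_WINDOW_MS = 1100.0


def make_config(**overrides) -> ck.SyntheticConfig:
    return ck.SyntheticConfig(**overrides)


def smoothed_signal_pair(config: ck.SyntheticConfig, plane: str = "axial"):
    """Generate both sides' displacement signals and smooth them."""
    (sig_r, sig_l), gt = ck.generate_displacement_profiles(config, plane=plane)
    out = []
    for sig in (sig_r, sig_l):
        w = odd_window_frames(sig.frame_period_ms, SMOOTHING_WINDOW_MS, 2, sig.n_samples)
        out.append(smooth_signal(sig, w))
    return out[0], out[1], gt


def signal_level_summary(
    latency: float = 0.0,
    vpd: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    lagging: str = "left",
    **config_overrides,
):
    """Full signal-level analysis chain on a phantom with injected asymmetry."""
    asym = latency > 0 or vpd > 0 or config_overrides.get(
        "amplitude_right_mm"
    ) != config_overrides.get("amplitude_left_mm")
    cfg = make_config(
        lagging_side=lagging if asym else "none",
        latency_fraction_open=latency,
        latency_fraction_close=latency,
        vpd_fraction=vpd,
        noise_sd_mm=noise_sd,
        seed=seed,
        **config_overrides,
    )
    sig_r, sig_l, gt = smoothed_signal_pair(cfg)
    params, summary = ck.analyze_bilateral(sig_r, sig_l)
    return params, summary, gt


@pytest.fixture(scope="session")
def symmetric_config() -> ck.SyntheticConfig:
    return make_config(n_cycles=2)


@pytest.fixture(scope="session")
def symmetric_mask_series(symmetric_config):
    """Noiseless axial mask series of a symmetric 2-cycle phantom."""
    tracks = ck.synthetic.ground_truth_tracks(symmetric_config, "axial")
    return ck.render_mask_series(tracks, symmetric_config, "axial"), tracks
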