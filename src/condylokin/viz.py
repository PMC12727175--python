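"""Minimal plotting helpers (time-coded trajectories, displacement traces)."""

from __future__ import annotations

import numpy as np

from .fusion import Track3D
from .series import DisplacementSignal


def plot_displacement(signals: list[DisplacementSignal], ax=None):
    """Overlay displacement traces of both sides against time (s)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for sig in signals:
        ax.plot(sig.timestamps_ms / 1000.0, sig.displacement_mm, label=sig.side)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("displacement (mm)")
    ax.legend()
    return ax


def plot_track3d(track: Track3D, ax=None):
    """3D trajectory colour-coded by time progression."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    ap, ml, cc = track.positions_mm.T
    t = track.timestamps_ms
    c = (t - t[0]) / max(t[-1] - t[0], 1.0)
    ax.scatter(ap, ml, cc, c=c, s=4)
    ax.set_xlabel("AP (mm)")
    ax.set_ylabel("ML (mm)")
    ax.set_zlabel("CC (mm)")
    ax.set_title(f"{track.side} condyle")
    return ax
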