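"""Quick-look figures: stacked ROI traces with event markers, asymmetry KDE."""

from __future__ import annotations

import numpy as np

from . import analysis

EVENT_COLOURS = {
    "forwards_wave": "tab:green",
    "backwards_wave": "black",
    "posterior_burst": "tab:orange",
    "anterior_burst": "magenta",
    "head_sweep_L": "tab:olive",
    "head_sweep_R": "tab:blue",
    "synchronous_network_event": "tab:red",
}


def plot_traces(frame, events=(), offset=None, ax=None):
    """Stacked hemisegment traces (posterior at bottom) with event dots."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 6))
    t = frame["time_ms"].to_numpy() / 1000.0
    channels = [c for c in frame.columns if c != "time_ms"]
    if offset is None:
        offset = 1.2 * max(np.ptp(frame[c].to_numpy()) for c in channels)
    for i, ch in enumerate(channels):
        ax.plot(t, frame[ch].to_numpy() + i * offset, lw=0.6, color="0.2")
        ax.text(t[0], i * offset + frame[ch].iloc[0], ch, ha="right",
                va="center", fontsize=8)
    y_top = (len(channels) + 0.5) * offset + frame[channels[-1]].iloc[0]
    for e in events:
        ax.plot([(e.start + e.end) / 2000.0], [y_top], marker="o",
                color=EVENT_COLOURS.get(e.kind, "grey"), ms=5)
    ax.set_xlabel("time (s)")
    ax.set_yticks([])
    return ax


def plot_asymmetry_kde(left, right, bandwidth_factor=4.0, ax=None, **kw):
    """Kernel density of the left-right difference distribution."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    grid, dens = analysis.asymmetry_kde(left, right,
                                        bandwidth_factor=bandwidth_factor)
    ax.fill_between(grid, dens, alpha=0.4, **kw)
    ax.axvline(0.0, color="0.5", lw=0.5)
    ax.set_xlabel("left - right")
    ax.set_ylabel("density")
    return ax
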