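"""Presentation helpers: track overlays, activity series, reliability curves."""

from __future__ import annotations

import numpy as np

from .census import SizeHistogram
from .imaging import BackgroundModel
from .tracking import ActivitySeries, Trajectory


def plot_track(trajectory: Trajectory, background: BackgroundModel | np.ndarray | None = None,
               ax=None):
    """Plot a single-animal track, optionally over the background image."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if background is not None:
        img = background.image if isinstance(background, BackgroundModel) else background
        ax.imshow(img, cmap="gray", vmin=0, vmax=255)
    if trajectory.points:
        pts = np.array([(r, c) for _, r, c in trajectory.points])
        ax.plot(pts[:, 1], pts[:, 0], "-o", color="tab:red", markersize=2, linewidth=1)
    ax.set_xlabel("column (px)")
    ax.set_ylabel("row (px)")
    return ax


def plot_activity(series: ActivitySeries, ax=None, block: int = 1):
    """Plot an activity time series, optionally block-averaged."""
    import matplotlib.pyplot as plt

    from .tracking import block_mean

    if ax is None:
        _, ax = plt.subplots()
    df = block_mean(series, block)
    ax.plot(df["t_seconds"], df["mean_count"], lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("active count")
    return ax


def plot_reliability_curve(curve, ax=None):
    """Plot biosurface vs number of pictures (prefix subsets)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pref = curve[curve["subset"] == "prefix"]
    ax.plot(pref["n"], pref["biosurface_mm2"], "-o")
    ax.set_xlabel("number of pictures in the stack")
    ax.set_ylabel("biosurface (mm$^2$)")
    return ax


def plot_size_histogram(hist: SizeHistogram, ax=None):
    """Bar plot of a fixed-bin size distribution."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    width = hist.bin_edges[1] - hist.bin_edges[0]
    ax.bar(hist.bin_edges[:-1], hist.counts, width=width, align="edge")
    ax.set_xlabel("length (mm)")
    ax.set_ylabel("count")
    return ax
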