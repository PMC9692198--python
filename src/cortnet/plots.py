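"""Figure helpers: connectivity spectra, density curves, adjacency heatmaps."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_connectivity_spectrum(means, path: str | Path, title: str = "") -> Path:
    """Group-mean connectivity vs band fc (log-x), one line per group."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for group, df in means.groupby("group"):
        df = df.sort_values("band_fc")
        ax.plot(df["band_fc"], df["mean"], marker="o", ms=3, label=str(group))
    ax.set_xscale("log")
    ax.set_xlabel("center frequency (Hz)")
    ax.set_ylabel("mean connectivity")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_density_curve(density_df, path: str | Path, title: str = "") -> Path:
    """Network density K vs band fc per comparison direction."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for direction, df in density_df.groupby("direction"):
        df = df.sort_values("band_fc")
        ax.plot(df["band_fc"], df["K"], marker="o", ms=3, label=str(direction))
    ax.set_xscale("log")
    ax.set_xlabel("center frequency (Hz)")
    ax.set_ylabel("network density K")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_adjacency(matrix: np.ndarray, path: str | Path, title: str = "") -> Path:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(4, 3.4))
    im = ax.imshow(matrix, cmap="viridis")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(title)
    ax.set_xlabel("parcel")
    ax.set_ylabel("parcel")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
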