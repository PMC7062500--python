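"""Optional figure rendering (raster plots, synchronization heatmaps)."""

from __future__ import annotations

import numpy as np


def _pyplot():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def raster_plot(trains, path, title="somatic spike raster"):
    """Raster of spike trains (one row per cell) saved to ``path``."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(8, 3))
    for i, tr in enumerate(trains):
        times = tr.times if hasattr(tr, "times") else np.asarray(tr)
        ax.vlines(times, i + 0.6, i + 1.4, color="k", lw=0.8)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("cell")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def sync_heatmap(matrix, path, title="SPIKE-synchronization"):
    """Pairwise synchronization heatmap saved to ``path``."""
    plt = _pyplot()
    m = np.asarray(matrix)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(m, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(m)), [f"{i+1}" for i in range(len(m))])
    ax.set_yticks(range(len(m)), [f"{i+1}" for i in range(len(m))])
    ax.set_xlabel("cell")
    ax.set_ylabel("cell")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="sync")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
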