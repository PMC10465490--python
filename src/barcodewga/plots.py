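"""Diagnostic plots: Lorenz coverage-uniformity curves and rainfall plots."""

from __future__ import annotations

import numpy as np

from .cna import lorenz_auc
from .svkat import rainfall


def plot_lorenz(counts, ax=None, label: str | None = None):
    """Lorenz curve of per-bin read counts; diagonal = perfect uniformity."""
    import matplotlib.pyplot as plt

    curve, auc = lorenz_auc(counts)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve[:, 0], curve[:, 1],
            label=f"{label or 'sample'} (AUC={auc:.3f})")
    ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=0.8)
    ax.set_xlabel("cumulative fraction of bins")
    ax.set_ylabel("cumulative fraction of reads")
    ax.legend()
    return ax


def plot_rainfall(positions: dict[str, np.ndarray], ax=None):
    """Inter-mutation distance vs position, log-scaled; kataegis shows as dips."""
    import matplotlib.pyplot as plt

    df = rainfall(positions)
    if ax is None:
        _, ax = plt.subplots()
    offset = 0
    for chrom, grp in df.groupby("chrom", sort=True):
        ax.scatter(grp["pos"] + offset, np.maximum(grp["imd"], 1), s=6, label=chrom)
        offset += int(grp["pos"].max()) if len(grp) else 0
    ax.set_yscale("log")
    ax.set_xlabel("genomic position (concatenated)")
    ax.set_ylabel("distance to previous mutation (bp)")
    ax.legend()
    return ax
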