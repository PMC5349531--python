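"""Diagnostic plots: barcode rank (knee) curve and two-marker scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .barcode_groups import GroupTable


def barcode_rank_plot(table: GroupTable, path, cumulative_fraction: float = 0.95) -> None:
    """Descending read counts per barcode with the cumulative-share knee."""
    counts = np.array([g.read_count for g in table.groups], dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    if counts.size:
        ranks = np.arange(1, counts.size + 1)
        ax.loglog(ranks, counts, drawstyle="steps-post", color="black")
        cum = np.cumsum(counts) / counts.sum()
        knee = int(np.searchsorted(cum, cumulative_fraction - 1e-9)) + 1
        ax.axvline(knee, color="grey", linestyle="--", label=f"knee (rank {knee})")
        inset = ax.inset_axes([0.1, 0.1, 0.35, 0.35])
        inset.plot(ranks, cum, color="tab:blue")
        inset.set_ylabel("cumulative", fontsize=7)
        inset.tick_params(labelsize=6)
        ax.legend(fontsize=8)
    ax.set_xlabel("barcode rank")
    ax.set_ylabel("read count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def marker_scatter_plot(
    matrix: pd.DataFrame, marker_x: str, marker_y: str, path
) -> None:
    """Two-marker UMI-count scatter on log axes with pseudo-count 1."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    x = matrix[marker_x] + 1
    y = matrix[marker_y] + 1
    ax.scatter(x, y, s=8, alpha=0.5, color="tab:blue", edgecolors="none")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(f"{marker_x} UMIs + 1")
    ax.set_ylabel(f"{marker_y} UMIs + 1")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
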