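"""Volcano and heatmap figures for differential results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .diffstats import SIG_P01, SIG_P05

_CLASS_COLOURS = {SIG_P01: "#c0392b", SIG_P05: "#e6b800", "ns": "#9e9e9e"}


def volcano_figure(results: pd.DataFrame, title: str = "") -> plt.Figure:
    """Volcano plot: log2 fold change vs −log10 P, coloured by tier.

    Red points pass P < 0.01, yellow P < 0.05 (both with the fold-change
    gate); grey points are not significant.
    """
    fig, ax = plt.subplots(figsize=(5, 4))
    x = results["log2fc"].to_numpy()
    y = -np.log10(results["p_value"].to_numpy())
    for sig in ("ns", SIG_P05, SIG_P01):
        mask = results["sig_class"] == sig
        ax.scatter(x[mask], y[mask], s=8, c=_CLASS_COLOURS[sig], label=sig, alpha=0.7)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 P value")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def heatmap_figure(fold_changes: pd.DataFrame, title: str = "") -> plt.Figure:
    """Heatmap of per-comparison log2 fold changes (blue down, red up)."""
    n_rows = max(len(fold_changes), 1)
    fig, ax = plt.subplots(figsize=(4, 0.25 * n_rows + 1.5))
    data = fold_changes.to_numpy() if len(fold_changes) else np.zeros((1, 1))
    vmax = max(np.abs(data).max(), 1e-9)
    im = ax.imshow(data, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(fold_changes.columns)), fold_changes.columns, fontsize=8)
    ax.set_yticks(range(len(fold_changes.index)), fold_changes.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="log2 fold change")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig


def save_figure(fig: plt.Figure, path: str | Path) -> Path:
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
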