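"""Plain figure exports: volcano, enrichment bars, expression heatmap.

Intentionally minimal styling; these are working exports for inspection,
not publication figures.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult

__all__ = ["plot_volcano", "plot_enrichment_bars", "plot_expression_heatmap"]


def plot_volcano(
    points: pd.DataFrame,
    path: str | Path,
    log2_theta: float = 2.0,
    alpha: float = 0.001,
) -> None:
    """Volcano plot of per-feature log2 fold change vs -log10 p.

    Down-selected features are drawn green, up-selected red, the rest
    grey; dashed lines mark the fold-change and significance boundaries.
    """
    fig, ax = plt.subplots(figsize=(5, 4))
    sel = points["selected"].to_numpy(dtype=bool)
    down = sel & (points["log2_fc"] < 0)
    up = sel & (points["log2_fc"] > 0)
    ax.scatter(points.loc[~sel, "log2_fc"], points.loc[~sel, "neg_log10_p"],
               s=6, c="0.7", linewidths=0)
    ax.scatter(points.loc[down, "log2_fc"], points.loc[down, "neg_log10_p"],
               s=10, c="green", linewidths=0, label="down")
    ax.scatter(points.loc[up, "log2_fc"], points.loc[up, "neg_log10_p"],
               s=10, c="red", linewidths=0, label="up")
    for x in (-log2_theta, log2_theta):
        ax.axvline(x, color="k", lw=0.8, ls="--")
    ax.axhline(-np.log10(alpha), color="k", lw=0.8, ls="--")
    ax.set_xlabel("log2 fold change (TME - control)")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_enrichment_bars(
    results: list[EnrichmentResult], path: str | Path
) -> None:
    """Horizontal bars of -log10 p per category, most significant on top."""
    fig, ax = plt.subplots(figsize=(5, 0.3 * max(len(results), 4) + 1))
    names = [r.category_id for r in results][::-1]
    neglog = [-np.log10(r.p_value) for r in results][::-1]
    ax.barh(names, neglog, color="steelblue")
    ax.set_xlabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_expression_heatmap(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    path: str | Path,
    title: str = "",
) -> None:
    """Heatmap of log2 expression, samples grouped by condition."""
    order = annot.sort_values(["condition", "cell_type", "replicate"])
    sub = matrix[list(order["sample_id"])]
    fig, ax = plt.subplots(
        figsize=(0.4 * sub.shape[1] + 2, 0.18 * sub.shape[0] + 1.5)
    )
    im = ax.imshow(sub.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(sub.shape[1]), sub.columns, rotation=90, fontsize=6)
    if sub.shape[0] <= 60:
        ax.set_yticks(range(sub.shape[0]), sub.index, fontsize=6)
    else:
        ax.set_yticks([])
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, label="log2 expression")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
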