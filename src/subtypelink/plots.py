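"""Optional diagnostic figures.

Correlation and pathway-score heatmaps use a yellow/blue diverging palette
(yellow = positive, blue = negative) centered on zero. matplotlib is
imported lazily so headless library use never touches a display backend.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _imports():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap, TwoSlopeNorm

    cmap = LinearSegmentedColormap.from_list(
        "blue_yellow", ["#1f4e9c", "#ffffff", "#f5d000"]
    )
    return plt, cmap, TwoSlopeNorm


def heatmap(
    matrix: pd.DataFrame,
    path: str | Path,
    title: str = "",
    xlabel: str = "",
    ylabel: str = "",
) -> None:
    """Zero-centered yellow/blue heatmap of a numeric matrix."""
    plt, cmap, TwoSlopeNorm = _imports()
    data = matrix.to_numpy(dtype=float)
    vmax = float(np.nanmax(np.abs(data))) or 1.0
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.12 * data.shape[1]), max(3.0, 0.12 * data.shape[0]))
    )
    im = ax.imshow(
        data, cmap=cmap, norm=TwoSlopeNorm(vcenter=0.0, vmin=-vmax, vmax=vmax),
        aspect="auto", interpolation="nearest",
    )
    small = data.shape[0] <= 30 and data.shape[1] <= 30
    if small:
        ax.set_xticks(range(data.shape[1]), matrix.columns, rotation=90,
                      fontsize=6)
        ax.set_yticks(range(data.shape[0]), matrix.index, fontsize=6)
    else:
        ax.set_xticks([])
        ax.set_yticks([])
    ax.set_title(title)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def correlation_heatmap(rho: pd.DataFrame, path: str | Path,
                        title: str = "between-sample Spearman rho") -> None:
    heatmap(rho, path, title=title, xlabel="samples", ylabel="samples")


def pathway_heatmap(scores: pd.DataFrame, path: str | Path,
                    title: str = "ssGSEA pathway profile") -> None:
    heatmap(scores, path, title=title, xlabel="samples", ylabel="gene sets")
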