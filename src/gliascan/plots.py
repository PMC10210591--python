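"""Minimal static plots: abundance heatmap and ranking bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .ahp_ranking import RankingResult

__all__ = ["plot_heatmap", "plot_ranking"]


def plot_heatmap(table: pd.DataFrame, path, title: str = "") -> None:
    """Scaled-abundance heatmap (variables x genotypes)."""
    z = (table - table.mean()) / table.std(ddof=0).replace(0, 1)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * z.shape[1] + 2), max(3, 0.3 * z.shape[0] + 1))
    )
    im = ax.imshow(z.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(z.shape[1]), z.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(z.shape[0]), z.index, fontsize=6)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ranking(result: RankingResult, path, title: str = "") -> None:
    """Bar chart of mean immunogenic-potential score with standard error."""
    order = result.mean.sort_values(ascending=False)
    fig, ax = plt.subplots(figsize=(max(4, 0.35 * len(order)), 3.5))
    ax.bar(
        range(len(order)), order.to_numpy(),
        yerr=result.se.reindex(order.index).to_numpy(),
        color="#777799", capsize=2,
    )
    ax.set_xticks(range(len(order)), order.index, rotation=90, fontsize=6)
    ax.set_ylabel("immunogenic potential score")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
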