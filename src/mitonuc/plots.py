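"""Optional matplotlib renderings of the standard pipeline figures.

Kept deliberately thin: each function takes already-computed results and an
output path.  Nothing in the analysis depends on this module.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.stats import norm

from .embed import Embedding
from .survey import CountMatrix
from .variant_io import PopulationPanel


def mds_scatter(
    emb: Embedding, panel: PopulationPanel, path: str | Path, title: str = ""
) -> None:
    """Two-component MDS scatter, colored by continental group."""
    groups = [panel.group_of[s] for s in emb.labels]
    uniq = sorted(set(groups))
    cmap = plt.get_cmap("tab10")
    fig, ax = plt.subplots(figsize=(6, 5))
    for i, g in enumerate(uniq):
        idx = [j for j, gg in enumerate(groups) if gg == g]
        ax.scatter(
            emb.coords[idx, 0], emb.coords[idx, 1], s=8, label=g, color=cmap(i % 10)
        )
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    ax.legend(fontsize=7, markerscale=2)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def concordance_scatter(diffs: pd.DataFrame, path: str | Path) -> None:
    """Nuclear-vs-mtDNA distance density scatter with outliers in black."""
    d = diffs["diff"].to_numpy()
    sd = d.std(ddof=0)
    z = np.zeros_like(d) if sd == 0 else (d - d.mean()) / sd
    out = np.abs(z) > 3
    fig, ax = plt.subplots(figsize=(5.5, 5))
    ax.hexbin(diffs["d_nuclear"], diffs["d_mito"], gridsize=50, cmap="Blues", mincnt=1)
    ax.scatter(
        diffs.loc[out, "d_nuclear"], diffs.loc[out, "d_mito"], s=4, color="k"
    )
    ax.set_xlabel("nuclear allele-sharing distance")
    ax.set_ylabel("mtDNA allele-sharing distance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def rank_difference_hist(diffs: pd.DataFrame, path: str | Path) -> None:
    """Distribution of normalized rank differences with a fitted normal."""
    d = diffs["diff"].to_numpy()
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.hist(d, bins=60, density=True, color="0.7")
    xs = np.linspace(d.min(), d.max(), 400)
    sd = d.std(ddof=0)
    if sd > 0:
        ax.plot(xs, norm.pdf(xs, d.mean(), sd), color="r")
    ax.set_xlabel("rank distance-difference (normalized)")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def count_heatmap(
    M: CountMatrix,
    row_order: list[str],
    col_order: list[str],
    status: pd.DataFrame,
    path: str | Path,
) -> None:
    """Clustered haplogroup-count heatmap with matched/mismatched shading.

    ``status`` is the cell table from :func:`mitonuc.survey.classify_matches`.
    Matched nonzero cells render green, mismatched orange.
    """
    stat = status.set_index(["pop", "haplogroup"])["status"]
    tab = M.table.loc[row_order, col_order]
    rgb = np.ones(tab.shape + (3,))
    for i, pop in enumerate(tab.index):
        for j, hg in enumerate(tab.columns):
            if tab.iloc[i, j] > 0:
                rgb[i, j] = (
                    (0.55, 0.8, 0.55)
                    if stat.get((pop, hg), "matched") == "matched"
                    else (1.0, 0.65, 0.3)
                )
    fig, ax = plt.subplots(figsize=(0.5 * len(col_order) + 2, 0.35 * len(row_order) + 2))
    ax.imshow(rgb, aspect="auto")
    for i in range(tab.shape[0]):
        for j in range(tab.shape[1]):
            if tab.iloc[i, j] > 0:
                ax.text(j, i, str(tab.iloc[i, j]), ha="center", va="center", fontsize=7)
    ax.set_xticks(range(len(col_order)), col_order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(row_order)), row_order, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
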