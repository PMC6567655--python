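"""Static publication-style figures (SVG by default, PNG on request).

Rendering is deterministic: matplotlib's ``svg.hashsalt`` is pinned and
no creation date is written, so identical inputs give byte-identical SVG
— a requirement for reproducible reports.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .overview import GeneSummary, SampleDistanceMatrix
from .pca import PCAResult

_HASHSALT = "pcascope"


def _render(fig: plt.Figure, fmt: str = "svg") -> bytes:
    buf = _stdio.BytesIO()
    with plt.rc_context({"svg.hashsalt": _HASHSALT}):
        fig.savefig(buf, format=fmt, metadata={"Date": None} if fmt == "svg" else None,
                    bbox_inches="tight")
    plt.close(fig)
    return buf.getvalue()


def save_figure(data: bytes, path: str | Path) -> None:
    Path(path).write_bytes(data)


def pca_scatter(
    pca: PCAResult, pc_x: int = 1, pc_y: int = 2,
    color_by: Optional[pd.Series] = None, title: str = "PCA",
    show_arrows: bool = False, fmt: str = "svg",
) -> bytes:
    """Score scatter on two PCs, optionally colored by a factor and with
    biplot arrows for gene-space results."""
    cx, cy = pca._check_pc(pc_x), pca._check_pc(pc_y)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    s = pca.scores
    if color_by is not None:
        for level in dict.fromkeys(color_by):
            idx = color_by[color_by == level].index
            sub = s.loc[[i for i in s.index if i in set(idx)]]
            ax.scatter(sub[cx], sub[cy], label=str(level), s=25)
        ax.legend(fontsize=7, frameon=False)
    else:
        ax.scatter(s[cx], s[cy], s=12, color="#36648b", alpha=0.7)
    if show_arrows and pca.biplot_arrows is not None:
        for name, row in pca.biplot_arrows.iterrows():
            ax.annotate("", xy=(row[cx], row[cy]), xytext=(0, 0),
                        arrowprops=dict(arrowstyle="->", color="firebrick", lw=0.8))
            ax.text(row[cx], row[cy], str(name), fontsize=6, color="firebrick")
    ve = pca.variance_explained
    ax.set_xlabel(f"{cx} ({100 * ve[pc_x - 1]:.1f}%)")
    ax.set_ylabel(f"{cy} ({100 * ve[pc_y - 1]:.1f}%)")
    ax.set_title(title, fontsize=10)
    return _render(fig, fmt)


def scree_plot(scree_table: pd.DataFrame, fmt: str = "svg") -> bytes:
    """Variance explained per component with the cumulative curve."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    x = np.arange(1, len(scree_table) + 1)
    ax.bar(x, scree_table["variance_explained"], color="#36648b")
    ax.plot(x, scree_table["cumulative"], "o-", color="firebrick", ms=3, lw=1)
    ax.set_xlabel("principal component")
    ax.set_ylabel("variance explained")
    ax.set_xticks(x[:: max(1, len(x) // 15)])
    return _render(fig, fmt)


def distance_heatmap(sdm: SampleDistanceMatrix, fmt: str = "svg") -> bytes:
    """Sample-distance heatmap in dendrogram leaf order."""
    order = sdm.dendrogram_order
    m = sdm.values.loc[order, order]
    fig, ax = plt.subplots(figsize=(4.8, 4.2))
    im = ax.imshow(m.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=6)
    ax.set_yticks(range(len(order)), order, fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8, label=f"{sdm.metric} distance")
    return _render(fig, fmt)


def profile_plot(profile: pd.DataFrame, fmt: str = "svg") -> bytes:
    """One line per gene across samples (centered transformed values)."""
    fig, ax = plt.subplots(figsize=(5.5, 3.2))
    for _, row in profile.iterrows():
        ax.plot(range(profile.shape[1]), row.to_numpy(), lw=0.6, alpha=0.6)
    ax.set_xticks(range(profile.shape[1]), list(profile.columns),
                  rotation=90, fontsize=6)
    ax.set_ylabel("centered expression")
    return _render(fig, fmt)


def gene_boxplot(summary: GeneSummary, fmt: str = "svg") -> bytes:
    """Grouped boxplot with jittered points for one gene."""
    groups = list(summary.groups.index)
    data = [summary.points.loc[summary.points["group"] == g, "value"].to_numpy()
            for g in groups]
    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(groups), 3.4))
    ax.boxplot(data, tick_labels=groups)
    rng = np.random.default_rng(0)  # jitter is cosmetic; fixed for determinism
    for i, v in enumerate(data, start=1):
        ax.scatter(i + rng.uniform(-0.12, 0.12, len(v)), v, s=12,
                   color="#36648b", alpha=0.8, zorder=3)
    ax.set_ylabel("transformed expression")
    ax.set_title(summary.gene_id, fontsize=10)
    return _render(fig, fmt)
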