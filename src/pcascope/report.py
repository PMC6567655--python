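"""Self-contained HTML report from a saved analysis session.

The report mirrors the analysis stages section by section (overview,
sample PCA, gene PCA, PC functional annotation, multifactor PCA), embeds
every figure inline (SVG by default) and prints every parameter value, so
the document alone suffices to audit what was run.  Given the same
session state, rendering is deterministic; the timestamp occupies a
single isolated line.
"""

from __future__ import annotations

import base64
import html
import io as _stdio
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .plots import _render
from .session import SessionState

ALL_SECTIONS = ("overview", "samples_pca", "genes_pca", "pca2go", "multifactor")

_SECTION_NEEDS = {
    "overview": ["library_sizes", "detected_genes", "sample_distances",
                 "sample_correlation"],
    "samples_pca": ["samples_pca_scores", "samples_scree", "hi_loadings"],
    "genes_pca": ["genes_pca_scores", "genes_pca_arrows", "genes_scree"],
    "pca2go": ["enrichment"],
    "multifactor": ["multifactor_scores"],
}

_STYLE = """
body { font-family: sans-serif; margin: 2em auto; max-width: 60em; color: #222; }
h1 { border-bottom: 2px solid #36648b; } h2 { color: #36648b; }
table { border-collapse: collapse; font-size: 0.85em; }
th, td { border: 1px solid #ccc; padding: 2px 8px; text-align: right; }
th { background: #eef3f8; }
.figure { margin: 1em 0; }
"""


@dataclass
class ReportSpec:
    """Which sections to render and in which figure format."""

    sections: tuple[str, ...] = ALL_SECTIONS
    figure_format: str = "svg"
    title: str = "Exploratory analysis report"
    max_table_rows: int = 25

    def __post_init__(self) -> None:
        bad = [s for s in self.sections if s not in ALL_SECTIONS]
        if bad:
            raise ValueError(f"unknown report sections: {bad}")
        if self.figure_format not in ("svg", "png"):
            raise ValueError("figure_format must be 'svg' or 'png'")


def _embed(data: bytes, fmt: str) -> str:
    if fmt == "svg":
        return f'<div class="figure">{data.decode("utf-8")}</div>'
    b64 = base64.b64encode(data).decode("ascii")
    return f'<div class="figure"><img src="data:image/png;base64,{b64}"/></div>'


def _table_html(df: pd.DataFrame, max_rows: int) -> str:
    shown = df.head(max_rows)
    note = ""
    if len(df) > max_rows:
        note = f"<p><em>showing {max_rows} of {len(df)} rows</em></p>"
    return shown.to_html(float_format=lambda v: f"{v:.6g}", border=0) + note


def _scores_scatter(scores: pd.DataFrame, ve: pd.Series | None,
                    labels: pd.Series | None, title: str, fmt: str) -> str:
    fig, ax = plt.subplots(figsize=(5, 4.5))
    if labels is not None:
        for level in dict.fromkeys(labels):
            sub = scores.loc[labels[labels == level].index.intersection(scores.index)]
            ax.scatter(sub["PC1"], sub["PC2"], label=str(level), s=25)
        ax.legend(fontsize=7, frameon=False)
    else:
        ax.scatter(scores["PC1"], scores["PC2"], s=10, color="#36648b", alpha=0.6)
    if ve is not None:
        ax.set_xlabel(f"PC1 ({100 * ve.iloc[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * ve.iloc[1]:.1f}%)")
    else:
        ax.set_xlabel("PC1"), ax.set_ylabel("PC2")
    ax.set_title(title, fontsize=10)
    return _embed(_render(fig, fmt), fmt)


def _scree_fig(scree: pd.DataFrame, fmt: str) -> str:
    fig, ax = plt.subplots(figsize=(5, 3))
    x = np.arange(1, len(scree) + 1)
    ax.bar(x, scree["variance_explained"], color="#36648b")
    ax.plot(x, scree["cumulative"], "o-", color="firebrick", ms=3, lw=1)
    ax.set_xlabel("principal component"); ax.set_ylabel("variance explained")
    return _embed(_render(fig, fmt), fmt)


def _heatmap_fig(m: pd.DataFrame, label: str, fmt: str) -> str:
    fig, ax = plt.subplots(figsize=(4.8, 4.2))
    im = ax.imshow(m.to_numpy(dtype=float), cmap="viridis")
    ax.set_xticks(range(len(m.columns)), list(m.columns), rotation=90, fontsize=6)
    ax.set_yticks(range(len(m.index)), list(m.index), fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8, label=label)
    return _embed(_render(fig, fmt), fmt)


def render_report(state: SessionState, spec: ReportSpec | None = None) -> str:
    """Render the session to a self-contained HTML string."""
    spec = spec or ReportSpec(
        sections=tuple(s for s in ALL_SECTIONS
                       if all(t in state.tables for t in _SECTION_NEEDS[s]))
    )
    missing = {
        s: [t for t in _SECTION_NEEDS[s] if t not in state.tables]
        for s in spec.sections
    }
    missing = {s: t for s, t in missing.items() if t}
    if missing:
        raise ValueError(
            "cannot render sections with missing artifacts; compute first: "
            + "; ".join(f"{s} needs {t}" for s, t in missing.items())
        )
    fmt, mr = spec.figure_format, spec.max_table_rows
    labels = None
    if "metadata" in state.tables and state.tables["metadata"].shape[1] > 0:
        labels = state.tables["metadata"].iloc[:, 0].astype(str)

    parts = [
        "<!DOCTYPE html>", "<html><head><meta charset='utf-8'/>",
        f"<title>{html.escape(spec.title)}</title>",
        f"<style>{_STYLE}</style></head><body>",
        f"<h1>{html.escape(spec.title)}</h1>",
        f"<p id='timestamp'>Generated: {html.escape(state.timestamp)}</p>",
        f"<p>pcascope version {html.escape(state.version)}</p>",
    ]

    if "overview" in spec.sections:
        parts.append("<h2>Data overview</h2>")
        parts.append("<h3>Library sizes</h3>")
        parts.append(_table_html(state.tables["library_sizes"], mr))
        robust = state.params.get("derived", {}).get("robust_detected_genes")
        parts.append("<h3>Detected genes</h3>")
        if robust is not None:
            parts.append(f"<p>Robustly detected genes: <b>{robust}</b></p>")
        parts.append(_table_html(state.tables["detected_genes"], mr))
        parts.append("<h3>Sample distances</h3>")
        parts.append(_heatmap_fig(state.tables["sample_distances"],
                                  "euclidean distance", fmt))
        parts.append("<h3>Sample correlation</h3>")
        parts.append(_table_html(state.tables["sample_correlation"], mr))

    if "samples_pca" in spec.sections:
        scree = state.tables["samples_scree"]
        parts.append("<h2>Samples PCA</h2>")
        parts.append(_scores_scatter(state.tables["samples_pca_scores"],
                                     scree["variance_explained"], labels,
                                     "samples", fmt))
        parts.append(_scree_fig(scree, fmt))
        parts.append("<h3>Genes with highest loadings</h3>")
        parts.append(_table_html(state.tables["hi_loadings"], mr))

    if "genes_pca" in spec.sections:
        parts.append("<h2>Genes PCA (biplot view)</h2>")
        parts.append(_scores_scatter(state.tables["genes_pca_scores"],
                                     state.tables["genes_scree"]["variance_explained"],
                                     None, "genes", fmt))
        parts.append("<h3>Sample arrows</h3>")
        parts.append(_table_html(state.tables["genes_pca_arrows"], mr))

    if "pca2go" in spec.sections:
        parts.append("<h2>Functional annotation of principal components</h2>")
        parts.append(_table_html(state.tables["enrichment"], mr))

    if "multifactor" in spec.sections:
        parts.append("<h2>Multifactor PCA</h2>")
        parts.append(_scores_scatter(state.tables["multifactor_scores"], None,
                                     None, "gene x factor-level observations", fmt))

    parts.append("<h2>Session parameters</h2><table>")
    parts.append("<tr><th>parameter</th><th>value</th></tr>")
    for key in sorted(state.params):
        if key == "derived":
            continue
        parts.append(
            f"<tr><td>{html.escape(str(key))}</td>"
            f"<td>{html.escape(repr(state.params[key]))}</td></tr>"
        )
    parts.append("</table>")
    parts.append("<h3>Input digests</h3><table>")
    for key in sorted(state.input_digests):
        parts.append(f"<tr><td>{html.escape(key)}</td>"
                     f"<td>{html.escape(state.input_digests[key])}</td></tr>")
    parts.append("</table>")
    parts.append("</body></html>")
    return "\n".join(parts)
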