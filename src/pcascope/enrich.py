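"""Functional annotation of principal components.

For each PC and each loading direction, the genes with the most extreme
loadings (a top quantile, default the extreme 2.5% per direction) are
tested for over-representation of GO terms against the PCA gene universe
with a one-sided hypergeometric (Fisher-exact) test, followed by
Benjamini-Hochberg FDR across the tested terms.

The universe defaults to the variables of the PCA (the ntop most-variable
genes) intersected with the annotated genes: enrichment is conditional on
the genes actually driving the components.  Pass ``universe="annotated"``
to test against all annotated genes instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GOAnnotation, ValidationError
from .pca import GeneSubsetSelection, PCAResult

logger = logging.getLogger(__name__)

_ENRICH_COLUMNS = [
    "term_id", "term_name", "n_annotated_universe", "n_annotated_selected",
    "expected", "p_value", "fdr",
]


@dataclass
class PCEnrichmentSet:
    """Per-(PC, direction) enrichment tables plus the selections made."""

    tables: dict[tuple[int, str], pd.DataFrame]
    selections: dict[tuple[int, str], GeneSubsetSelection]
    params: dict = field(default_factory=dict)

    def combined(self) -> pd.DataFrame:
        """All tables stacked long-format with pc/direction columns,
        ordered by (pc, direction, p-value)."""
        frames = []
        for (pc, direction) in sorted(self.tables, key=lambda k: (k[0], k[1])):
            t = self.tables[(pc, direction)].copy()
            t.insert(0, "direction", direction)
            t.insert(0, "pc", pc)
            frames.append(t)
        if not frames:
            return pd.DataFrame(columns=["pc", "direction", *_ENRICH_COLUMNS])
        return pd.concat(frames, ignore_index=True)


def select_loading_quantile(
    pca: PCAResult, pc: int, direction: str, top_fraction: float = 0.025
) -> GeneSubsetSelection:
    """The ceil(top_fraction * n_variables) genes with the most extreme
    loadings in one direction; wrong-sign genes are excluded even when
    within the count, so the selection may be smaller or empty."""
    if not (0 < top_fraction <= 0.5):
        raise ValidationError(f"top_fraction must be in (0, 0.5], got {top_fraction}")
    if direction not in ("positive", "negative"):
        raise ValidationError(f"direction must be positive|negative, got {direction!r}")
    col = pca._check_pc(pc)
    load = pca.loadings[col]
    m = math.ceil(top_fraction * len(load))
    sign = 1 if direction == "positive" else -1
    ordered = load.sort_values(ascending=(sign < 0), kind="stable")
    top = ordered.iloc[:m]
    top = top[sign * top > 0]
    if top.empty:
        logger.warning("no %s-loading genes on PC%d; empty selection", direction, pc)
    by_mag = top.sort_values(key=lambda s: s.abs(), ascending=False, kind="stable")
    return GeneSubsetSelection(pc, direction, list(by_mag.index), list(by_mag))


def enrich_fisher(
    selected: Iterable[str],
    universe: Iterable[str],
    go: GOAnnotation,
    min_term_size: int = 5,
    max_term_size: int = 500,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per GO term.

    With N = |universe|, K = |term ∩ universe|, n = |selected| and
    k = |term ∩ selected|, the p-value is the upper tail P(X >= k) of
    Hypergeom(N, K, n); only terms with min_term_size <= K <=
    max_term_size are tested.  FDR is Benjamini-Hochberg across the
    tested terms; rows are sorted by p-value, ties by term ID.

    The universe is taken at face value; restricting it to annotated
    genes (so unannotated genes do not dilute the draws) is the caller's
    choice and is what :func:`pca2go_all` does.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        raise ValidationError("selected genes must be a subset of the universe")
    if selected and not universe & set(go.annotated_genes):
        raise ValidationError("universe shares no genes with the GO annotation")
    N = len(universe)
    n = len(selected)
    rows = []
    for term in sorted(go.term_to_genes):
        in_universe = go.term_to_genes[term] & universe
        K = len(in_universe)
        if not (min_term_size <= K <= max_term_size):
            continue
        k = len(in_universe & selected)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "term_id": term,
            "term_name": go.name_of(term),
            "n_annotated_universe": K,
            "n_annotated_selected": k,
            "expected": n * K / N,
            "p_value": min(p, 1.0),
        })
    if not rows or not selected:
        return pd.DataFrame(columns=_ENRICH_COLUMNS)
    table = pd.DataFrame(rows)
    table["fdr"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table = table.sort_values(
        ["p_value", "term_id"], kind="stable"
    ).reset_index(drop=True)
    return table[_ENRICH_COLUMNS]


def pca2go_all(
    pca: PCAResult,
    go: GOAnnotation,
    pcs: Sequence[int] = (1, 2, 3, 4),
    top_fraction: float = 0.025,
    min_term_size: int = 5,
    max_term_size: int = 500,
    universe: str = "ntop",
) -> PCEnrichmentSet:
    """Loading-quantile selection + Fisher test for every (PC, direction).

    ``universe="ntop"`` (default) tests against the PCA variables
    intersected with annotated genes; ``universe="annotated"`` against all
    annotated genes.
    """
    pcs = [pc for pc in pcs if 1 <= pc <= pca.n_components]
    annotated = set(go.annotated_genes)
    if not set(pca.variable_ids) & annotated:
        raise ValidationError("GO annotation shares no genes with the PCA variables")
    if universe == "ntop":
        uni = set(pca.variable_ids) & annotated
    elif universe == "annotated":
        uni = annotated
    else:
        raise ValidationError(f"unknown universe mode {universe!r}")
    tables, selections = {}, {}
    for pc in pcs:
        for direction in ("positive", "negative"):
            sel = select_loading_quantile(pca, pc, direction, top_fraction)
            selections[(pc, direction)] = sel
            tables[(pc, direction)] = enrich_fisher(
                [g for g in sel.gene_ids if g in uni], uni, go,
                min_term_size, max_term_size,
            )
    return PCEnrichmentSet(tables, selections, {
        "pcs": list(pcs), "top_fraction": top_fraction,
        "min_term_size": min_term_size, "max_term_size": max_term_size,
        "universe": universe, "universe_size": len(uni),
    })
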