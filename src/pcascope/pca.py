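"""PCA on samples and on genes over the most-variable genes.

The observation matrix is centered (and optionally scaled) column-wise and
decomposed by SVD.  Scores are ``U @ diag(S)``, loadings the right singular
vectors; every loading column is flipped so its largest-absolute entry is
positive, which makes the output deterministic across SVD implementations.
Variance explained per component is ``S_k^2 / sum(S^2)`` and sums to one
over all retained components.

Besides the plain sample PCA this module provides the gene-space view
(genes as observations, with sample "arrows" in the correlation-biplot
convention: variable loadings scaled by the square root of the component
eigenvalue), outlier-removal recomputation, rectangle selection of genes
in score space, profile data for a gene subset, and a two-factor PCA that
stacks one row per (gene, factor1-level) pair against columns of
(factor2-level, replicate) so that both factors enter a single
decomposition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import SampleMetadata, ValidationError
from .normalize import TransformedMatrix

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Scores, loadings and variance explained of one decomposition."""

    scores: pd.DataFrame        # observations x components
    loadings: pd.DataFrame      # variables x components
    variance_explained: np.ndarray  # fraction per component, sums to 1
    ntop: int
    centered: bool = True
    scaled: bool = False
    biplot_arrows: Optional[pd.DataFrame] = None  # variables x components, scaled

    @property
    def observation_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def variable_ids(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def _check_pc(self, pc: int) -> str:
        if not (1 <= pc <= self.n_components):
            raise ValidationError(
                f"PC {pc} out of range (1..{self.n_components})"
            )
        return f"PC{pc}"


@dataclass
class GeneSubsetSelection:
    """Genes with extreme loadings on one PC, one sign direction."""

    pc: int
    direction: str  # "positive" | "negative"
    gene_ids: list[str]  # ordered by |loading| descending
    loadings: list[float] = field(default_factory=list)


def select_top_variable(transformed: TransformedMatrix, ntop: int = 500) -> list[str]:
    """IDs of the ntop genes with highest row variance of transformed values.

    Ties are broken by input row order; if ntop exceeds the gene count all
    genes are returned.  All-zero variance triggers a warning (the ranking
    is then just input order).
    """
    if ntop < 2:
        raise ValidationError(f"ntop must be >= 2, got {ntop}")
    var = transformed.values.var(axis=1, ddof=1).to_numpy()
    if np.all(var == 0):
        logger.warning("all gene variances are zero; returning input order")
    order = np.argsort(-var, kind="stable")  # stable => ties keep row order
    keep = order[: min(ntop, len(order))]
    return [transformed.gene_ids[i] for i in keep]


def _decompose(
    X: pd.DataFrame, ntop: int, center: Optional[str] = "variables",
    scaled: bool = False,
) -> PCAResult:
    """Run SVD-based PCA on X (observations x variables).

    ``center="variables"`` subtracts each variable's mean across
    observations (the sample-PCA convention); ``center="observations"``
    subtracts each observation's mean across variables (the gene-PCA
    convention, where each gene row is centered across samples).
    """
    M = X.to_numpy(dtype=float)
    if center == "variables":
        M = M - M.mean(axis=0, keepdims=True)
    elif center == "observations":
        M = M - M.mean(axis=1, keepdims=True)
    elif center is not None:
        raise ValueError(f"unknown centering mode {center!r}")
    if scaled:
        sd = M.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            logger.warning(
                "dropping %d zero-variance variables before scaling", int(zero.sum())
            )
            X = X.loc[:, ~zero]
            M = M[:, ~zero]
            sd = sd[~zero]
        M = M / sd
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    # sign convention: largest-|v| entry of each loading column positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    total = float(np.sum(S**2))
    ve = S**2 / total if total > 0 else np.zeros_like(S)
    comps = [f"PC{i+1}" for i in range(len(S))]
    scores = pd.DataFrame(U * S, index=X.index, columns=comps)
    loadings = pd.DataFrame(Vt.T, index=X.columns, columns=comps)
    return PCAResult(scores, loadings, ve, ntop, center is not None, scaled)


def pca_samples(
    transformed: TransformedMatrix, ntop: int = 500, scale: bool = False
) -> PCAResult:
    """PCA with samples as observations over the ntop most-variable genes."""
    if len(transformed.sample_ids) < 2:
        raise ValidationError("sample PCA needs at least 2 samples")
    genes = select_top_variable(transformed, ntop)
    X = transformed.values.loc[genes].T  # samples x genes
    return _decompose(X, ntop=len(genes), scaled=scale)


def scree(pca: PCAResult) -> pd.DataFrame:
    """Variance explained per component with its running (cumulative) sum."""
    ve = pca.variance_explained
    return pd.DataFrame(
        {
            "component": list(pca.scores.columns),
            "variance_explained": ve,
            "cumulative": np.cumsum(ve),
        }
    ).set_index("component")


def hi_loadings(
    pca: PCAResult, pc: int, n_per_direction: int = 10
) -> tuple[GeneSubsetSelection, GeneSubsetSelection]:
    """The genes with the most extreme loadings on a PC, per direction.

    Returns (positive, negative) selections, each ordered by |loading|
    descending; fewer genes are returned when not enough have that sign.
    """
    col = pca._check_pc(pc)
    load = pca.loadings[col]
    out = []
    for direction, sign in (("positive", 1), ("negative", -1)):
        sub = load[sign * load > 0].sort_values(key=np.abs, ascending=False, kind="stable")
        sub = sub.iloc[:n_per_direction]
        out.append(GeneSubsetSelection(pc, direction, list(sub.index), list(sub)))
    return out[0], out[1]


def pca_remove_samples(
    transformed: TransformedMatrix, drop: Iterable[str], ntop: int = 500,
    scale: bool = False,
) -> PCAResult:
    """Recompute sample PCA (including the variable-gene ranking) after
    removing the named samples — not a projection of the old fit."""
    drop = list(drop)
    unknown = [s for s in drop if s not in transformed.sample_ids]
    if unknown:
        raise ValidationError(f"unknown sample IDs to drop: {unknown}")
    keep = [s for s in transformed.sample_ids if s not in set(drop)]
    if len(keep) < 2:
        raise ValidationError("removing those samples leaves fewer than 2")
    reduced = TransformedMatrix(
        transformed.values[keep], transformed.method, transformed.params,
        type(transformed.size_factors)(
            transformed.size_factors.values.loc[keep], transformed.size_factors.method
        ),
    )
    return pca_samples(reduced, ntop=ntop, scale=scale)


def pca_genes(transformed: TransformedMatrix, ntop: int = 500) -> PCAResult:
    """Gene-space PCA: the ntop genes are observations, samples variables.

    Rows (genes) are centered across samples.  Sample arrows for the
    biplot are the variable loadings scaled by sqrt of the component
    eigenvalue (correlation-biplot convention).
    """
    if len(transformed.sample_ids) < 2:
        raise ValidationError("gene PCA needs at least 2 samples")
    genes = select_top_variable(transformed, ntop)
    X = transformed.values.loc[genes]  # genes x samples
    res = _decompose(X, ntop=len(genes), center="observations")
    n_obs = X.shape[0]
    sv = np.sqrt(np.sum(res.scores.to_numpy() ** 2, axis=0))  # singular values
    eig_sqrt = sv / math.sqrt(max(n_obs - 1, 1))
    res.biplot_arrows = res.loadings * eig_sqrt
    return res


def select_genes_in_box(
    pca_genes_result: PCAResult, pc_x: int, pc_y: int,
    x_range: tuple[float, float], y_range: tuple[float, float],
) -> list[str]:
    """Genes whose (PCx, PCy) scores fall in the closed rectangle, ordered
    by their PCx score."""
    cx = pca_genes_result._check_pc(pc_x)
    cy = pca_genes_result._check_pc(pc_y)
    s = pca_genes_result.scores
    inside = (
        (s[cx] >= min(x_range)) & (s[cx] <= max(x_range))
        & (s[cy] >= min(y_range)) & (s[cy] <= max(y_range))
    )
    return list(s[inside].sort_values(cx, kind="stable").index)


def profile_data(
    transformed: TransformedMatrix, gene_ids: Sequence[str], center: bool = True
) -> pd.DataFrame:
    """Per-gene rows of transformed values, optionally mean-centered, in the
    bundle's sample order."""
    unknown = [g for g in gene_ids if g not in transformed.values.index]
    if unknown:
        raise ValidationError(f"unknown gene IDs: {unknown}")
    prof = transformed.values.loc[list(gene_ids)].copy()
    if center:
        prof = prof.sub(prof.mean(axis=1), axis=0)
    return prof


def pca_multifactor(
    transformed: TransformedMatrix, metadata: SampleMetadata,
    factor1: str, factor2: str, ntop: int = 500,
) -> PCAResult:
    """Two-factor PCA on a stacked gene x factor1-level matrix.

    Requires a balanced design (every factor1 x factor2 combination has
    the same number of samples >= 1).  The observation matrix has one row
    per (gene, factor1 level) pair, labelled ``gene::level``, and one
    column per (factor2 level, replicate index); entries are the
    transformed values of the corresponding sample.  Rows are centered, so
    a gene that responds only to factor2 contributes near-identical rows
    for its factor1 levels.
    """
    for f in (factor1, factor2):
        if f not in metadata.factor_names:
            raise ValidationError(f"unknown factor {f!r}")
    fac = metadata.factors.loc[transformed.sample_ids]
    l1 = list(dict.fromkeys(fac[factor1]))
    l2 = list(dict.fromkeys(fac[factor2]))
    cells: dict[tuple[str, str], list[str]] = {}
    for s in transformed.sample_ids:
        cells.setdefault((fac.at[s, factor1], fac.at[s, factor2]), []).append(s)
    sizes = {k: len(v) for k, v in cells.items()}
    want = {(a, b) for a in l1 for b in l2}
    if set(sizes) != want or len(set(sizes.values())) != 1:
        raise ValidationError(
            f"unbalanced {factor1} x {factor2} design; samples per combination: "
            f"{ {k: sizes.get(k, 0) for k in sorted(want)} }"
        )
    n_rep = next(iter(sizes.values()))
    genes = select_top_variable(transformed, ntop)
    cols = [f"{b}::rep{r+1}" for b in l2 for r in range(n_rep)]
    blocks = []
    index = []
    vals = transformed.values
    for a in l1:
        samples = [cells[(a, b)][r] for b in l2 for r in range(n_rep)]
        block = vals.loc[genes, samples].to_numpy(dtype=float)
        blocks.append(block)
        index.extend(f"{g}::{a}" for g in genes)
    X = pd.DataFrame(np.vstack(blocks), index=index, columns=cols)
    return _decompose(X, ntop=len(genes), center="observations")
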