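"""Dataset summaries: library sizes, detected genes, sample distances and
correlations, and per-gene grouped statistics (gene finder).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .io import CountMatrix, ExperimentBundle, ValidationError
from .normalize import TransformedMatrix

logger = logging.getLogger(__name__)


@dataclass
class SampleDistanceMatrix:
    """Pairwise Euclidean distances between samples, with a dendrogram
    leaf order from average-linkage hierarchical clustering."""

    values: pd.DataFrame  # samples x samples, symmetric, zero diagonal
    metric: str
    dendrogram_order: list[str]


@dataclass
class GeneSummary:
    """Grouped summary statistics for one gene (boxplot-ready)."""

    gene_id: str
    groups: pd.DataFrame     # index = group label; n/median/q1/q3/min/max
    points: pd.DataFrame     # columns: sample, group, value


def library_sizes(counts: CountMatrix) -> pd.DataFrame:
    """Total counts per sample, also in millions."""
    totals = counts.values.sum(axis=0)
    empty = totals.index[totals == 0].tolist()
    if empty:
        logger.warning("samples with zero total counts: %s", empty)
    return pd.DataFrame(
        {"total_counts": totals, "millions": totals / 1e6},
    ).rename_axis("sample")


def detected_genes(
    counts: CountMatrix, min_count: int = 5, min_samples: int = 1
) -> tuple[pd.DataFrame, int]:
    """Per-sample detected-gene counts and the robust total.

    A gene is detected in a sample when its count is >= min_count; the
    robust total counts genes detected in >= min_samples samples.
    """
    if min_count < 1 or min_samples < 1:
        raise ValidationError("min_count and min_samples must be >= 1")
    hits = counts.values >= min_count
    per_sample = pd.DataFrame(
        {"detected": hits.sum(axis=0)}
    ).rename_axis("sample")
    robust_total = int((hits.sum(axis=1) >= min_samples).sum())
    return per_sample, robust_total


def sample_distances(transformed: TransformedMatrix) -> SampleDistanceMatrix:
    """Euclidean distances between samples over all genes of the
    transformed matrix; dendrogram order by average linkage."""
    ids = transformed.sample_ids
    if len(ids) < 2:
        raise ValidationError("need at least 2 samples for distances")
    X = transformed.values.to_numpy(dtype=float).T  # samples x genes
    cond = pdist(X, metric="euclidean")
    dm = pd.DataFrame(squareform(cond), index=ids, columns=ids)
    order = leaves_list(average(cond))
    return SampleDistanceMatrix(dm, "euclidean", [ids[i] for i in order])


def sample_correlation(
    normalized: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise correlation of per-sample normalized count vectors.

    Zero-variance samples get missing rows/columns with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    if normalized.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    X = normalized.to_numpy(dtype=float)
    if method == "spearman":
        X = np.apply_along_axis(rankdata, 0, X)
    sd = X.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        logger.warning(
            "zero-variance samples set to missing in correlation: %s",
            list(normalized.columns[zero]),
        )
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr[zero, :] = np.nan
    corr[:, zero] = np.nan
    np.fill_diagonal(corr, np.where(zero, np.nan, 1.0))
    return pd.DataFrame(corr, index=normalized.columns, columns=normalized.columns)


def _resolve_gene(bundle: ExperimentBundle, query: str) -> str:
    gene_ids = bundle.counts.gene_ids
    if query in gene_ids:
        return query
    if bundle.annotation is not None:
        hits = [h for h in bundle.annotation.resolve(query) if h in gene_ids]
        if len(hits) == 1:
            return hits[0]
        if len(hits) > 1:
            raise ValidationError(
                f"ambiguous query {query!r}: matches primary IDs {sorted(hits)}"
            )
    near = [g for g in gene_ids if g.startswith(query)][:5]
    hint = f"; did you mean {near}?" if near else ""
    raise ValidationError(f"no gene matches {query!r}{hint}")


def gene_finder(
    bundle: ExperimentBundle,
    transformed: TransformedMatrix,
    query: str,
    group_by: Optional[Sequence[str]] = None,
) -> GeneSummary:
    """Grouped distribution summary of one gene's transformed values.

    The query may be a primary gene ID or any annotated alternative ID;
    an ambiguous symbol is an error listing the candidates.  Samples are
    partitioned by the cross-product of the named factors (labels joined
    with ":"); quartiles use the linear-interpolation (type-7) convention.
    """
    gene = _resolve_gene(bundle, query)
    group_by = list(group_by or [])
    unknown = [f for f in group_by if f not in bundle.metadata.factor_names]
    if unknown:
        raise ValidationError(f"unknown factors: {unknown}")
    vals = transformed.values.loc[gene]
    if group_by:
        labels = bundle.metadata.factors[group_by].astype(str).agg(":".join, axis=1)
    else:
        labels = pd.Series("all", index=bundle.metadata.factors.index)
    labels = labels.loc[vals.index]
    points = pd.DataFrame({"sample": vals.index, "group": labels.values,
                           "value": vals.values}).set_index("sample")
    rows = {}
    for label in dict.fromkeys(labels):  # first-appearance order
        v = vals[labels == label].to_numpy(dtype=float)
        rows[label] = {
            "n": len(v),
            "median": float(np.median(v)),
            "q1": float(np.quantile(v, 0.25)),  # type-7 interpolation
            "q3": float(np.quantile(v, 0.75)),
            "min": float(v.min()),
            "max": float(v.max()),
        }
    groups = pd.DataFrame.from_dict(rows, orient="index").rename_axis("group")
    return GeneSummary(gene, groups, points)
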