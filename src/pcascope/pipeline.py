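"""End-to-end pipeline: read -> bind -> normalize -> transform -> PCA ->
overview -> optional PC functional annotation, collected into a
:class:`~pcascope.session.SessionState`.

Every stage logs its parameters at INFO level and any failure is
re-raised with the stage name prefixed, so a config error is traceable to
the step that rejected it.  The pipeline is deterministic: identical
inputs and configuration reproduce every derived table bit-identically.
"""

from __future__ import annotations

import hashlib
import logging
from contextlib import contextmanager
from typing import Optional

import numpy as np
import pandas as pd

from . import enrich, io, normalize, overview, pca
from .session import SessionState, file_digest

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "counts": None,            # path to counts TSV/CSV (or in-memory bundle)
    "metadata": None,          # path to metadata table
    "annotation": None,        # optional gene-annotation path
    "go_annotation": None,     # optional gene->GO path
    "go_format": "two-column-tsv",
    "dialect": None,
    "transform": "vst",        # "vst" | "shifted_log"
    "pseudocount": 1.0,
    "min_mean": 1.0,
    "ntop": 500,
    "scale": False,
    "pcs": [1, 2, 3, 4],
    "n_hi_loadings": 10,
    "top_fraction": 0.025,
    "min_term_size": 5,
    "max_term_size": 500,
    "universe": "ntop",
    "min_count": 5,
    "min_samples": 1,
    "correlation_method": "pearson",
    "factor1": None,           # optional multifactor PCA
    "factor2": None,
    "seed": 0,
}


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name."""


@contextmanager
def _stage(name: str):
    logger.info("stage %s: starting", name)
    try:
        yield
    except Exception as exc:  # noqa: BLE001 - deliberately prefix and re-raise
        raise PipelineError(f"[{name}] {exc}") from exc


def _content_digest(text: str) -> str:
    return "sha256:" + hashlib.sha256(text.encode("utf-8")).hexdigest()


def run_pipeline(config: dict, bundle: Optional[io.ExperimentBundle] = None,
                 go: Optional[io.GOAnnotation] = None) -> SessionState:
    """Execute the full analysis described by *config*.

    Inputs are taken from the paths in the config, or from an in-memory
    *bundle* (and optional *go* annotation) for scripted use; digests of
    whichever inputs were used are recorded in the returned session.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise PipelineError(f"[config] unknown configuration keys: {sorted(unknown)}")
    digests: dict[str, str] = {}
    tables: dict[str, pd.DataFrame] = {}
    derived: dict = {}

    if bundle is None:
        with _stage("read_counts"):
            if not cfg["counts"]:
                raise ValueError("config key 'counts' is required")
            counts = io.read_counts(cfg["counts"], cfg["dialect"])
            digests["counts"] = file_digest(cfg["counts"])
        with _stage("read_metadata"):
            if not cfg["metadata"]:
                raise ValueError("config key 'metadata' is required")
            meta = io.read_metadata(cfg["metadata"], cfg["dialect"])
            digests["metadata"] = file_digest(cfg["metadata"])
        annotation = None
        if cfg["annotation"]:
            with _stage("read_annotation"):
                annotation = io.read_gene_annotation(cfg["annotation"], cfg["dialect"])
                digests["annotation"] = file_digest(cfg["annotation"])
        with _stage("bind_experiment"):
            bundle = io.bind_experiment(counts, meta, annotation)
    else:
        digests["counts"] = _content_digest(io.table_to_tsv(bundle.counts.values))
        digests["metadata"] = _content_digest(io.table_to_tsv(bundle.metadata.factors))

    if go is None and cfg["go_annotation"]:
        with _stage("read_go_annotation"):
            go = io.read_go_annotation(cfg["go_annotation"], cfg["go_format"])
            digests["go_annotation"] = file_digest(cfg["go_annotation"])

    tables["metadata"] = bundle.metadata.factors

    with _stage("estimate_size_factors"):
        sf = normalize.estimate_size_factors(bundle.counts)
        logger.info("size factors: %s", np.round(sf.values.to_numpy(), 4))
        tables["size_factors"] = sf.values.to_frame("size_factor").rename_axis("sample")

    with _stage("normalize"):
        norm = normalize.normalize_counts(bundle.counts, sf)

    with _stage("transform"):
        if cfg["transform"] == "vst":
            trend = normalize.fit_dispersion_trend(bundle.counts, sf, cfg["min_mean"])
            logger.info("dispersion trend: a0=%.4g a1=%.4g (n=%d genes)",
                        trend.a0, trend.a1, trend.n_genes_used)
            tables["dispersion_trend"] = pd.DataFrame(
                {"value": [trend.a0, trend.a1, trend.n_genes_used]},
                index=pd.Index(["a0", "a1", "n_genes_used"], name="parameter"),
            )
            transformed = normalize.vst(bundle.counts, sf, trend)
        elif cfg["transform"] == "shifted_log":
            transformed = normalize.shifted_log(bundle.counts, sf, cfg["pseudocount"])
        else:
            raise PipelineError(
                f"[transform] unknown transform {cfg['transform']!r} "
                "(expected 'vst' or 'shifted_log')"
            )

    with _stage("overview"):
        tables["library_sizes"] = overview.library_sizes(bundle.counts)
        det, robust = overview.detected_genes(
            bundle.counts, cfg["min_count"], cfg["min_samples"]
        )
        tables["detected_genes"] = det
        derived["robust_detected_genes"] = robust
        sdm = overview.sample_distances(transformed)
        order = sdm.dendrogram_order
        tables["sample_distances"] = sdm.values.loc[order, order].rename_axis("sample")
        tables["sample_correlation"] = overview.sample_correlation(
            norm, cfg["correlation_method"]
        ).rename_axis("sample")

    with _stage("pca_samples"):
        spca = pca.pca_samples(transformed, cfg["ntop"], cfg["scale"])
        tables["samples_pca_scores"] = spca.scores.rename_axis("sample")
        tables["samples_pca_loadings"] = spca.loadings.rename_axis("gene")
        tables["samples_scree"] = pca.scree(spca)
        hi_rows = []
        for pc_i in cfg["pcs"]:
            if pc_i > spca.n_components:
                continue
            pos, neg = pca.hi_loadings(spca, pc_i, cfg["n_hi_loadings"])
            for sel in (pos, neg):
                hi_rows += [
                    {"pc": sel.pc, "direction": sel.direction, "gene": g, "loading": l}
                    for g, l in zip(sel.gene_ids, sel.loadings)
                ]
        tables["hi_loadings"] = pd.DataFrame(
            hi_rows, columns=["pc", "direction", "gene", "loading"]
        )

    with _stage("pca_genes"):
        gpca = pca.pca_genes(transformed, cfg["ntop"])
        tables["genes_pca_scores"] = gpca.scores.rename_axis("gene")
        tables["genes_pca_arrows"] = gpca.biplot_arrows.rename_axis("sample")
        tables["genes_scree"] = pca.scree(gpca)

    if cfg["factor1"] and cfg["factor2"]:
        with _stage("pca_multifactor"):
            mpca = pca.pca_multifactor(
                transformed, bundle.metadata, cfg["factor1"], cfg["factor2"],
                cfg["ntop"],
            )
            tables["multifactor_scores"] = mpca.scores.rename_axis("gene_level")

    if go is not None:
        with _stage("pca2go"):
            enr = enrich.pca2go_all(
                spca, go, cfg["pcs"], cfg["top_fraction"],
                cfg["min_term_size"], cfg["max_term_size"], cfg["universe"],
            )
            tables["enrichment"] = enr.combined()

    params = {k: v for k, v in cfg.items()}
    params["derived"] = derived
    return SessionState(params=params, input_digests=digests, tables=tables)
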