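"""Synthetic RNA-seq experiments with known ground truth.

Counts are drawn from a negative binomial with variance mu + d * mu^2,
matching the dispersion-trend model used by the VST: gene *i* in sample
*j* has mean ``s_j * mu_i * 2^(beta_i * x_j)`` and dispersion
``d_i = a0 + a1 / mu_i``, where ``s_j`` is a library-size multiplier,
``mu_i`` a log-normal baseline mean, ``x_j`` the indicator of the
non-reference level of the effect factor, and ``beta_i`` a planted log2
fold-change, nonzero for a chosen fraction of genes.  Two-factor designs
additionally support interaction genes whose effect acts only in one
factor-combination cell.

Ground truth (planted genes, betas, library multipliers, group labels)
is returned as plain tables so downstream recovery checks never reach
into generator internals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, ExperimentBundle, GOAnnotation, SampleMetadata, ValidationError


@dataclass
class SimulationDesign:
    """Parameters of a synthetic experiment.

    ``factor_levels`` holds 1 or 2 level counts; the *last* factor carries
    the planted differential effect.  ``n_replicates`` is the number of
    samples per factor-level combination.  Baseline means are log-normal
    (defaults: median ~55 counts, quartiles roughly 15-200, with both
    near-silent and very highly expressed genes, as in real libraries);
    the dispersion trend defaults to (0.1, 5): moderately overdispersed
    at high counts with strong extra-Poisson noise for weak genes.
    """

    n_genes: int = 2000
    n_replicates: int = 6
    factor_levels: tuple[int, ...] = (2,)
    factor_names: tuple[str, ...] = ()
    frac_affected: float = 0.1
    log2_fc: float = 2.0
    frac_up: float = 0.5
    frac_interaction: float = 0.0
    mean_log: float = 4.0
    sd_log: float = 2.0
    trend_a0: float = 0.1
    trend_a1: float = 5.0
    library_multipliers: Optional[Sequence[float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.factor_levels) not in (1, 2):
            raise ValidationError("factor_levels must name 1 or 2 factors")
        if not self.factor_names:
            self.factor_names = (
                ("condition",) if len(self.factor_levels) == 1 else ("tissue", "condition")
            )
        for frac in (self.frac_affected, self.frac_up, self.frac_interaction):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("fractions must be in [0, 1]")
        if self.trend_a0 <= 0 or self.trend_a1 < 0:
            raise ValidationError("need trend_a0 > 0 and trend_a1 >= 0")
        if self.seed is None:
            raise ValidationError("seed is mandatory")

    @property
    def n_samples(self) -> int:
        return self.n_replicates * int(np.prod(self.factor_levels))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """NB with var = mean + disp * mean^2 (disp > 0)."""
    size_param = 1.0 / disp
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_counts(design: SimulationDesign) -> tuple[ExperimentBundle, dict[str, pd.DataFrame]]:
    """Draw a count matrix plus metadata and ground-truth tables.

    Returns (bundle, truth) where truth has a ``genes`` table (baseline
    mean, dispersion, beta, affected/interaction flags) and a ``samples``
    table (factor levels, size multiplier).
    """
    rng = np.random.default_rng(design.seed)
    n_g, n_s = design.n_genes, design.n_samples
    gene_ids = [f"gene{i+1:05d}" for i in range(n_g)]
    sample_ids = [f"S{j+1:02d}" for j in range(n_s)]

    # factor layout: replicates nested in the cross of factor levels
    level_names = [
        [chr(ord("A") + l) for l in range(n)] for n in design.factor_levels
    ]
    combos = [(a,) for a in level_names[0]]
    if len(level_names) == 2:
        combos = [(a, b) for a in level_names[0] for b in level_names[1]]
    assignment = [c for c in combos for _ in range(design.n_replicates)]
    meta = pd.DataFrame(assignment, index=sample_ids, columns=list(design.factor_names))

    if design.library_multipliers is None:
        s = np.ones(n_s)
    else:
        s = np.asarray(design.library_multipliers, dtype=float)
        if s.shape != (n_s,):
            raise ValidationError(
                f"library_multipliers must have length {n_s}, got {len(s)}"
            )

    mu = rng.lognormal(design.mean_log, design.sd_log, size=n_g)
    disp = design.trend_a0 + design.trend_a1 / mu

    n_aff = round(design.frac_affected * n_g)
    affected_idx = rng.choice(n_g, size=n_aff, replace=False)
    beta = np.zeros(n_g)
    signs = np.where(rng.random(n_aff) < design.frac_up, 1.0, -1.0)
    beta[affected_idx] = signs * design.log2_fc

    # effect factor = last factor; x = indicator of non-reference level
    eff_factor = design.factor_names[-1]
    x = (meta[eff_factor] != level_names[-1][0]).to_numpy(dtype=float)

    inter_beta = np.zeros(n_g)
    cell = np.zeros(n_s)
    if len(design.factor_levels) == 2 and design.frac_interaction > 0:
        pool = np.setdiff1d(np.arange(n_g), affected_idx)
        n_int = round(design.frac_interaction * n_g)
        inter_idx = rng.choice(pool, size=n_int, replace=False)
        inter_signs = np.where(rng.random(n_int) < design.frac_up, 1.0, -1.0)
        inter_beta[inter_idx] = inter_signs * design.log2_fc
        # interaction acts only in the (last level, last level) cell
        cell = (
            (meta[design.factor_names[0]] == level_names[0][-1])
            & (meta[design.factor_names[1]] == level_names[1][-1])
        ).to_numpy(dtype=float)

    mean = (
        s[None, :] * mu[:, None]
        * np.exp2(beta[:, None] * x[None, :] + inter_beta[:, None] * cell[None, :])
    )
    counts = _nb_draw(rng, mean, np.broadcast_to(disp[:, None], mean.shape))

    bundle = ExperimentBundle(
        CountMatrix(pd.DataFrame(counts.astype(np.int64), index=gene_ids,
                                 columns=sample_ids)),
        SampleMetadata(meta),
    )
    truth = {
        "genes": pd.DataFrame({
            "mu": mu, "dispersion": disp, "beta": beta,
            "affected": beta != 0, "interaction_beta": inter_beta,
        }, index=pd.Index(gene_ids, name="gene")),
        "samples": pd.DataFrame({
            **{f: meta[f] for f in design.factor_names},
            "size_multiplier": s,
        }, index=pd.Index(sample_ids, name="sample")),
    }
    return bundle, truth


def simulate_go(
    genes: Sequence[str],
    affected: Sequence[str],
    n_terms: int = 50,
    planted_term_overlap: float = 0.8,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 200,
) -> tuple[GOAnnotation, str]:
    """Random GO annotation with one planted enriched term.

    ``n_terms`` background terms get sizes log-uniform in
    [min_size, max_size] and random gene sets.  The planted term has the
    size of ``affected`` and draws the stated fraction of its genes from
    ``affected`` and the rest from the complement.  Returns the
    annotation and the planted term's ID.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    affected = list(dict.fromkeys(affected))
    if not set(affected) <= set(genes):
        raise ValidationError("affected genes must be a subset of the gene list")
    others = [g for g in genes if g not in set(affected)]
    n_from_affected = round(planted_term_overlap * len(affected))
    n_from_others = len(affected) - n_from_affected
    if n_from_others > len(others):
        raise ValidationError(
            f"overlap {planted_term_overlap} infeasible: needs {n_from_others} "
            f"non-affected genes but only {len(others)} exist"
        )
    planted = set(rng.choice(affected, size=n_from_affected, replace=False))
    planted |= set(rng.choice(others, size=n_from_others, replace=False))

    term_to_genes = {"GO:0000001": frozenset(planted)}
    term_names = {"GO:0000001": "planted term"}
    for t in range(n_terms):
        size = int(round(math.exp(rng.uniform(math.log(min_size), math.log(max_size)))))
        size = min(size, len(genes))
        term_id = f"GO:{t + 2:07d}"
        term_to_genes[term_id] = frozenset(rng.choice(genes, size=size, replace=False))
        term_names[term_id] = f"random term {t + 1}"
    return GOAnnotation(term_to_genes, term_names, "BP"), "GO:0000001"


def go_annotation_to_table(go: GOAnnotation) -> pd.DataFrame:
    """Flatten an annotation to (gene_id, go_id) pairs for TSV export."""
    rows = [
        {"gene_id": g, "go_id": t}
        for t in sorted(go.term_to_genes)
        for g in sorted(go.term_to_genes[t])
    ]
    return pd.DataFrame(rows, columns=["gene_id", "go_id"])
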