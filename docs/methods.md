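# Methods

This note records the statistical procedures pcascope implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make outputs
deterministic.

## Normalization

Sequencing libraries differ in depth, so counts are scaled by per-sample
size factors before any comparison. pcascope uses the median-of-ratios
estimator: with counts *K<sub>ij</sub>* (gene *i*, sample *j*) and
per-gene geometric means *g<sub>i</sub>* across samples,

  s_j = median over { K_ij / g_i : gene i has no zero count }.

Only all-positive genes enter (their geometric mean is positive), which
makes the estimator exact on scaled-replicate data: if column *j* equals
*c<sub>j</sub>* times a fixed vector, then s_j = c_j / geomean(c) and the
product of size factors is 1. The estimator assumes most genes are not
differentially expressed; it degrades when a majority of the
all-positive genes change. A single-sample matrix gets s = 1 with a
warning; a matrix with no all-positive gene is an error (filter or add a
pseudocount upstream).

## Transformations

Count data are heteroscedastic: the negative-binomial variance
μ + d·μ² makes highly expressed genes dominate Euclidean distances and
PCA unless the scale is compressed. Two monotone maps of normalized
counts q are provided.

* **Shifted log**: log2(q + q₀), pseudocount q₀ > 0, default 1 (exposed
  as a parameter; any small positive value is defensible and the default
  simply makes log2 of a zero count equal 0).
* **VST**: the closed-form variance-stabilizing transformation for NB
  counts under the dispersion-mean trend disp(μ) = a0 + a1/μ,

    vst(q) = log2( (1 + a1 + 2·a0·q + 2·√(a0·q·(1 + a1 + a0·q))) / (4·a0) ).

  It is strictly increasing, finite for q ≥ 0, equals
  log2((1 + a1)/(4·a0)) at q = 0, and approaches log2(q) + log2-constant
  for large q, so it reads like a log scale where counts are informative
  while compressing the noisy low-count range.

The regularized-log transform is deliberately not implemented: it
requires a shrinkage estimator that belongs to a different methodological
lineage, and shifted log + VST exercise every downstream stage.

### Dispersion-trend fit

The trend (a0: asymptotic dispersion at large mean, dimensionless;
a1: extra-Poisson term dominating at small mean) is fitted by:

1. per-gene method-of-moments dispersion d = max((var − μ)/μ², 1e-8) on
   normalized counts (mean μ and unbiased variance across samples);
2. unweighted least squares of d on (1, 1/μ) over genes with
   μ > min_mean (default 1 — moment dispersions are unstable below that);
3. one round of outlier trimming (drop genes whose absolute residual
   exceeds 2 × the MAD of the residuals) and a refit;
4. clamping a0 ≥ 1e-8, a1 ≥ 0.

This is a deliberately self-contained approximation to the
gamma-GLM-with-iterative-trimming fits used by dedicated differential
expression engines. Its accuracy limit matters and is characterised by
the test suite: the moment dispersion is biased low for weakly expressed
genes at small sample sizes (at 12 samples, noticeably so below mean
~10), which transfers to an underestimated a1 and a compensating
overestimated a0 in the line fit. At the default simulated design
(2000 genes, 12 samples) recovery of a planted trend is reliable to
roughly ±30–40 % relative, tightening with more samples. Since the
transform only needs the trend's overall shape, this accuracy is ample
for its purpose; it is not a dispersion estimator for inference.

## PCA

All decompositions are SVD-based on the `ntop` most-variable genes
(row variance of the transformed matrix, ties broken by input row order;
default ntop = 500, exposed everywhere).

* **Samples view**: observations = samples, variables = genes, each gene
  centered across samples. Scaling (dividing genes by their SD) is off by
  default because variance-stabilized data are already on a common scale;
  when on, zero-variance genes are dropped with a warning.
* **Genes view**: observations = the ntop genes, each centered across
  samples. Sample arrows for the biplot are the variable loadings scaled
  by the square root of the component eigenvalue (correlation-biplot
  convention — the underlying math is a documented choice, since a biplot
  can be normalized several ways).
* **Two-factor view**: requires a balanced factor1 × factor2 design. The
  observation matrix stacks one row per (gene, factor1 level) pair,
  labelled `gene::level`, against one column per (factor2 level,
  replicate index); rows are centered. A gene responding only to factor2
  therefore contributes near-identical rows for its factor1 levels, while
  interaction effects pull the pair apart — distances between `gene::A`
  and `gene::B` scores read as interaction evidence. This stacked
  construction is this package's own reconstruction of a two-factor PCA
  display; it is not a canonical method and is flagged as such.
* Variance explained is S²ₖ/ΣS² and sums to 1 over all retained
  components; scores are U·S, so inter-sample score distances equal
  distances over the centered data (orthogonal invariance).
* Outlier handling recomputes both the variable-gene ranking and the PCA
  on the reduced sample set, rather than projecting the old fit — the
  ranking itself is sample-dependent, so a true re-analysis is the
  honest comparison.

**Determinism.** Each loading column is flipped so its
largest-magnitude entry is positive (scores flipped alongside), making
output independent of the SVD implementation's sign choices.

## Functional annotation of components

For each requested PC and each direction, the extreme loading quantile
(ceil(top_fraction × ntop) genes, default top_fraction = 0.025 per
direction; wrong-sign genes excluded even when inside the count) is
tested for GO-term over-representation. The test is the one-sided
hypergeometric upper tail with N = universe size, K = term size in the
universe, n = selection size, k = term hits in the selection; expected
hits are n·K/N and Benjamini–Hochberg FDR is applied across tested terms
(terms outside [min_term_size, max_term_size] = [5, 500] are skipped).

The universe defaults to the ntop PCA genes intersected with annotated
genes — enrichment conditional on the genes actually driving the
components — and can be switched to all annotated genes. No GO-graph
decorrelation or ancestry propagation is attempted: annotation files are
taken as given, one Fisher test per term. Both the quantile cutoff and
the universe convention are exposed parameters because neither has a
single canonical value in the literature.

## Overview statistics

Library sizes are column sums. "Robustly detected" genes are those with
count ≥ min_count in ≥ min_samples samples (defaults 5 and 1, both
flags — the phrase has no standard definition, so the rule is explicit).
Sample distances are Euclidean over all genes of the transformed matrix
with average-linkage hierarchical clustering for the heatmap order;
correlations (Pearson or Spearman) are computed on normalized counts,
with zero-variance samples masked as missing. Gene-finder summaries use
type-7 (linear-interpolation) quartiles, stated because boxplot
conventions differ between tools.

## Synthetic data

`simulate_counts` draws K ~ NB(mean = s_j·μ_i·2^(β_i·x_j),
var = mean + d_i·mean²) with log-normal baseline means (meanlog 4,
sdlog 2: median ≈ 55 counts, quartiles ≈ 15–200, with both near-silent
and very abundant genes, matching the shape of real libraries),
dispersion d_i = a0 + a1/μ_i from the design trend (default (0.1, 5)),
library multipliers s_j (default 1), and planted log2 fold-changes β
(default: 10 % of genes at |β| = 2, signs balanced) on the last factor's
non-reference level; two-factor designs can additionally plant
cell-specific interaction effects. Truth tables (per-gene μ, d, β, flags;
per-sample labels and multipliers) are returned alongside so recovery
checks never reach into generator internals.

What it does **not** emulate: single-cell zero inflation, batch/GC/length
biases, correlated genes beyond the planted group structure, outlier
counts, or unbalanced designs. Passing recovery tests on this generator
therefore demonstrates correctness of the algorithms under the NB model,
not robustness to those real-data artifacts. Effects are planted
uniformly over the mean distribution, so a fraction of planted genes is
too weakly expressed to be recoverable by any method — recovery metrics
(e.g. precision of the top-loading selection) are capped accordingly and
hover near that cap.

## Sessions and reports

A session records every parameter, input digests (SHA-256), and every
derived table. The archive is a zip of `manifest.json` plus one TSV per
table; digests are verified on load and a missing or altered table is a
hard corruption error. TSVs store floats at repr precision and parse back
with round-trip float handling, so save → load → save is byte-identical.
The HTML report embeds figures inline (SVG by default, with matplotlib's
hash salt pinned and no creation date, so rendering is deterministic) and
prints all parameters; the timestamp occupies one isolated line.

## Numerical conventions and edge cases

* Base-2 logarithms throughout.
* Missing values export as `NA`; gene IDs are case-sensitive and never
  normalized.
* Delimiter auto-detection tries tab, comma, semicolon in that order and
  requires a consistent column count over the first 50 data lines.
* Counts must be integers; a relaxed mode accepts floats integral to
  within 1e-6 (for quantifiers that emit estimated counts).
* Sample mismatches between counts and metadata are resolved by
  intersecting and keeping counts order, with dropped samples reported —
  a documented choice, since no convention exists.
* Rectangle gene selection is closed on all boundaries.
* Tests sized for routine runs: simulated designs use 2000 genes and
  12–16 samples, enough for all recovery properties to be measurable
  while keeping the suite fast.

## Known limitations

* The dispersion-trend fit is an approximation with the small-sample bias
  described above; do not reuse it for differential testing.
* Enrichment treats GO terms independently; deeply nested term sets will
  produce redundant hits.
* The two-factor PCA requires a balanced design and has no canonical
  reference; treat it as an exploratory display.
* No sparse PCA or t-SNE; the scope is classical PCA.
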