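# Methods

## Measurement model and estimator

Each cell's observed UMI count for a gene is modelled as a binomial
subsample, at capture rate *q*, of the true transcript count in that cell.
Under this model the raw per-gene moments within a sample group map to the
true moments as E[x̄] = qμ and E[s²] = q²σ² + q(1−q)μ, and inverting gives
the capture-corrected estimators used throughout:

    m̂ = x̄ / q,    v̂ = (s² − (1 − q) x̄) / q².

This is the minimal moment-consistent correction under per-molecule capture;
no distributional assumption beyond the thinning is needed, and v̂ is
unbiased whenever the thinning model holds. The sample variance uses the
unbiased (n−1) denominator. v̂ can be non-positive for genes whose raw
variance is at or below the thinning floor (for example a gene with the same
count in every cell); such entries are **flagged undefined rather than
floored**, since flooring would fabricate a dispersion value for exactly the
genes with no measurable residual variance.

*q* is a property of the assay, not fitted: 0.4 for the within-culture
(cardiac-style) design and a more conservative 0.2 for the comparative
design, configurable everywhere.

## Dispersion (mean-corrected residual variance)

Within each sample group a least-squares polynomial (degree 2 by default,
configurable) of log v̂ on log m̂ is fitted across all genes passing the
expression filter, and dispersion is the residual

    d̂ = log v̂ − trend(log m̂).

Degree 2 is flexible enough to flatten the NB-like mean-variance
relationship while remaining deterministic and free of bandwidth tuning; the
synthetic-data tests confirm |Spearman ρ(d̂, m̂)| well below 0.05 at 2,000+
genes. Residualization is done in log space (rather than as a ratio to the
trend) so that a k-fold change in variance moves d̂ by log k regardless of
expression level.

One caveat of per-group trend refitting: the trend is estimated from the
genes themselves, so if a very large fraction of genes shifts dispersion in
one condition, part of that shift is absorbed into the trend and null genes
acquire a small opposite offset. At realistic differential-dispersion
fractions (a few percent of genes) the effect is negligible; the synthetic
generator's defaults keep it so, and the cis/trans example applies an
effect-size floor (|effect| > 0.5) before classifying, because the cis
proportion is a ratio and is unstable for near-zero effects.

### Filters

- Genes with raw mean UMI below 0.07 in **any** group are excluded from
  **all** groups (intersection rule), so cross-group comparisons are never
  driven by one-sided power.
- Cell types require at least 1,000 cells per individual by default
  (`min_cells_per_group`), matching the design's power requirement; the
  option can be relaxed for small simulations.
- The trend fit requires at least 50 genes with positive corrected variance.

## Differential dispersion

**Across cell types.** Per-sample dispersion vectors (one sample = one cell
type × individual) are quantile normalized — each sample's order statistics
are replaced by their across-sample means, ties receiving the mean of the
tied reference values; samples with missing entries are mapped through
interpolation at their own quantile positions. A per-gene one-way
fixed-effect model on cell type yields all pairwise contrasts (effect, SE, t,
two-sided p, BH FDR within contrast). Optional limma-style empirical-Bayes
variance moderation (moment-matched scaled-inverse-chi-square prior on the
residual variances) is available but off by default, since its original
configuration is not recoverable and the permutation calibration below does
not need it.

**Empirical FDR.** Cell-type labels are permuted at the *sample* level
(preserving group sizes and each sample's individual), the fixed-effect model
is refitted, and the |t| statistics of all genes, contrasts and permutations
are pooled into one null. Pooling across genes gives a dense null even at
B = 100 permutations (the default; configurable). Empirical p-values use the
add-one rule p = (1 + #{null ≥ |t|}) / (1 + N_null), and BH is applied to the
empirical p within each contrast. Under a global-null simulation (18 samples,
3,000 genes) the fraction of genes at empirical FDR < 0.05 is at the nominal
level or below.

**Between species (diploid).** Per gene and cell type, a random-intercept
model value ~ species + (1 | individual) fitted by REML, Wald p on the
species effect. With three individuals per species singular fits are common;
a singular or non-converged fit falls back to OLS with the fallback recorded
per gene.

**Between alleles (allotetraploid).** Both genomes share one nucleus, so the
test is a paired two-sample comparison: effect = d̂(genome A) − d̂(genome B)
per gene, with the SE from a cell-level bootstrap that resamples cells with
replacement keeping each cell's two allele rows together and recomputes the
full moment-correction-trend pipeline per replicate (default 200 replicates,
minimum 100). z = effect/SE with a two-sided normal p; a degenerate
bootstrap (zero spread) with zero effect is reported as p = 1.

**Differential mean expression.** Pseudobulk profiles (exact per-sample count
sums) are converted to log2 CPM with a 0.5 pseudocount (scale-invariant in
total depth) and run through the same fixed/mixed machinery. For allelic DE,
a per-gene paired Wilcoxon signed-rank test over cells on (allele A − allele
B) counts: zero differences dropped, exact null up to 25 nonzero pairs,
normal approximation with continuity correction above, missing p below 5
nonzero pairs.

**Variance partition.** Per gene, value ~ technical covariates + (1 | cell
type); the cell-type fraction is the random-intercept variance over the
total, each covariate's fraction is the variance of its fitted component
over the total, and the residual completes the sum to one (the cited
decomposition logic, simplified — cross-covariances between components are
not modelled). Constant covariates are dropped with fraction 0; singular
fits give flagged missing fractions.

## Rankings, shared sets, stability

Genes are ranked within each cell type by the **median dispersion across
individuals** (rank 1 = lowest, average ranks for ties), after excluding any
gene missing a dispersion value anywhere, so all cell types rank the same
universe. Quintile bins place boundary ties in the lower bin. Shared
low/high-dispersion sets are the intersections of first/fifth-quintile
membership across all cell types; under independent rankings the expected
shared-set size is n_genes × fraction^n_cell_types (0.758 genes for 11,847
genes, six cell types, quintiles). Rank-stable genes are those whose rank
never deviates from their cross-cell-type median rank by more than 15% of
the number of ranked genes (interpreting the threshold as a rank distance;
a fraction-of-genes knob exposes alternatives). Within-cell-type low/high
sets use 30% rank cutoffs by default (10%/20% variants available).

## Enrichment

The sliding-window profile reports |set ∩ window| / w along the ranking with
stride s; the 95% band per window is the 2.5/97.5 percentile over 50 (the
default) uniformly resampled sets of the same size. Window parameters
default to w = 500, s = 50 and are exposed as options. Quintile enrichment
uses Fisher's exact test with the sample (cross-product) odds ratio and a
Woolf logit CI (Haldane–Anscombe 0.5 correction when a cell is zero).
Gene-set enrichment is the hypergeometric upper tail against a background,
BH-adjusted, with Storey q-values at fixed λ = 0.5; sets pass at FDR ≤ 0.05
and q ≤ 0.2. Group comparisons use two-sided Mann–Whitney U (midranks) or
Kolmogorov–Smirnov; correlations use Spearman's ρ with midrank ties.

## Cis/trans partitioning

For diploid interspecies effect d and allotetraploid allelic effect t (both
oriented the same way and on the same raw dispersion scale — see numerical
choices), the cis proportion is |t| / (|t| + |d − t|), undefined when both
terms vanish. Per cell type a DD gene is **cis** if the proportion exceeds
0.70, **trans** below 0.30, **neither** otherwise; boundary equality counts
as neither (strict inequalities); non-DD genes are not classified. Gene-level
aggregation: **mixed** when cis and trans co-occur across cell types; else
**cis**/**trans** when called in at least one cell type with all remaining
calls neither/not-DD; else **neither** when called at least once with all
others not-DD; else **not-DD**. Stricter thresholds (e.g. 0.2/0.8) are
options. Recapitulation per cell type is the fraction of diploid DD genes
that are significant in the allotetraploid test with a concordant effect
sign; significance flags are an input column (the package uses its own FDR
on synthetic data), keeping the classification logic independent of any
particular shrinkage engine.

## Synthetic-data generator

The generator emulates exactly the structure the estimator assumes: per-gene
true means drawn log-uniformly on [3, 100] molecules/cell; true counts
negative binomial with variance exp(trend(log μ) + δ) around a global trend
(slope 1.5, intercept 0.5 on the natural-log scale) with per-gene offsets
δ ~ N(0, 0.3²) truncated at three standard deviations; observed counts a
binomial thinning at q. These defaults jointly guarantee overdispersion
(variance > mean) for every gene — a configuration that implies
underdispersion is rejected with a diagnostic, since the NB family cannot
represent it. DD genes receive a dispersion offset (dd_effect, default 1.0
on the log-variance scale) in one randomly chosen cell type (one-species
designs) or in every group of species B (two-species designs); DE genes
receive an analogous log-mean shift. Technical covariates (feature count
from the matrix, an independent mitochondrial fraction) make the
variance-partition null testable.

The allotetraploid mode emits two rows per cell (genome A/B, shared cell
id). For DD genes the allelic dispersion difference is c_g × dd_effect — the
cis share of the diploid interspecies difference on the same log-variance
scale — with per-gene cis fractions c_g configurable as a constant, an
array, or uniform on [0, 1]. Annotations: eGene status is Bernoulli with
log-odds linear in the normalised true-dispersion rank; feature columns
(TATA, TSS count, introns, enhancer length, LOEUF, percent identity) are
drawn with a tunable association to dispersion in the directions the biology
suggests. One master seed expands into named substreams (counts, hybrid,
annotations, covariates), so annotation tables can be regenerated without
re-drawing counts.

What the generator does **not** emulate: biological pathway/correlation
structure between genes, doublets, ambient RNA, batch effects beyond group
labels, cluster-assignment errors, or zero inflation beyond NB + thinning.
Passing tests therefore demonstrate correctness of the estimators and tests
under the assumed measurement model, not robustness to annotation error or
to count distributions outside the NB family.

## Numerical choices and scales

- **Effect scale for cis/trans:** both the diploid mixed-model effect and
  the allotetraploid two-sample effect are computed on the raw residual-
  variance (dispersion) scale, not the quantile-normalized scale, because the
  two-sample allele comparison has no natural multi-sample quantile reference
  and the generator links allelic to diploid effects on the raw scale.
  Quantile normalization remains the default pre-step for the cell-type DD
  analysis, where many samples share one null distribution.
- **Permutation granularity:** sample-level labels (18 in the reference
  design), nulls pooled across genes and permutations; B = 100 by default.
- **Determinism:** every stochastic step (generator, permutations,
  bootstraps, resampled bands) takes an explicit seed; identical inputs and
  seeds give byte-identical outputs, which the pipeline tests verify at the
  file level.
- **Degenerate inputs:** empty groups, single-species designs in the mixed
  model, unpaired allele rows, windows wider than the ranking, fractions
  outside (0, 1], and mismatched gene universes are rejected with
  diagnostics; undefined quantities (negative v̂, all-zero paired
  differences, constant correlation inputs) propagate as flagged missing
  values rather than fabricated numbers.

## Problem sizes

The test suite and the acceptance script use the designs the analyses are
specified at — 18-sample (6 cell types × 3 individuals) fixed-effect
designs, 3,000-gene moment recovery at 2,000 cells per group, B = 100
permutations with 20 global-null replicates, and 300-gene allotetraploid
designs at 2,000 cells per group with 100 bootstrap replicates — chosen so
each property is measured at the scale where its guarantees are stated while
a full run remains a few minutes on one CPU.

## Known limitations

- The mixed models fall back to OLS when the random-intercept variance is
  estimated at zero; with three individuals per species this is common and
  flagged per gene, but p-values from the fallback are mildly
  anti-conservative (normal rather than t reference).
- Multivariate shrinkage across conditions (and hence local-false-sign-rate
  significance) is intentionally out of scope; effect tables expose
  effect/SE columns so an external shrinkage step can be slotted between the
  differential and cis/trans stages, and the significance column consumed by
  the classifier is pluggable.
- The capture model is binomial thinning with a single q per dataset;
  finite-pool (hypergeometric) capture and per-cell efficiency variation are
  not modelled.
- eQTL mapping is not performed; eGene lists are inputs.
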