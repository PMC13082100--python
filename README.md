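# scdisp

Analysis of **gene expression dispersion** — cell-to-cell expression
variability after removing its dependence on mean expression — in single-cell
UMI count data, for researchers studying expression variability as a
regulatory phenotype: within-culture comparisons across cell types and
individuals, and comparative designs in which interspecies differences are
partitioned into *cis* and *trans* components using an allotetraploid
(hybrid) line.

## The model

Observed UMI counts are treated as a binomial subsample of the true per-cell
transcript count at a capture rate *q*. For each gene within a sample group
(cells of one cell type from one individual), the raw mean *x̄* and variance
*s²* are inverted through the thinning to moment-consistent estimates of the
true mean and variance:

```
m̂ = x̄ / q          v̂ = (s² − (1 − q) x̄) / q²
```

Dispersion is the **residual variance**: the residual of log *v̂* against a
polynomial trend of log *v̂* on log *m̂* fitted across genes within the group,

```
d̂ = log v̂ − trend(log m̂)
```

so that by construction d̂ is uncorrelated with mean expression. Genes with
raw mean below 0.07 in *any* group are excluded everywhere (intersection
rule); groups come from cell types with at least 1,000 cells per individual.

On top of the estimator the package provides:

- **Differential dispersion (DD)** across cell types: quantile normalization
  of per-sample dispersion, per-gene fixed-effect models with all pairwise
  contrasts, and empirical p-values / FDR from permutation of sample-level
  cell-type labels.
- **Interspecies DD**: per-gene mixed models (species fixed, individual
  random) for diploid lines, and a paired cell-level bootstrap two-sample
  test for allele-resolved allotetraploid data.
- **Differential expression** analogues on pseudobulk log-CPM, plus a paired
  per-cell signed-rank test for allelic counts.
- **Rank machinery**: cell-type dispersion rankings (median across
  individuals), shared low/high-dispersion quintile sets with the analytic
  overlap null `n_genes × fraction^n_cell_types`, and rank-stability
  selection.
- **Enrichment**: sliding-window set proportions with resampled confidence
  bands, quintile Fisher tests with odds-ratio CIs, hypergeometric gene-set
  enrichment with BH FDR and q-values, Mann–Whitney / Kolmogorov–Smirnov /
  Spearman utilities.
- **Cis/trans partitioning**: for diploid effect *d* and allotetraploid
  (allelic) effect *t*, the cis proportion `|t| / (|t| + |d − t|)`, per-cell-
  type classification at 30%/70% thresholds, and gene-level aggregation
  (mixed / cis / trans / neither / not-DD).
- A **seeded synthetic-data generator** (negative-binomial counts on a
  configurable mean-variance trend, binomial capture, grouped metadata,
  allele-resolved allotetraploid cells with per-gene cis fractions, and
  annotation tables) with full ground truth for every parameter.

## Worked example

`examples/01_simulate_and_estimate.py` simulates 4,000 cells × 1,000 genes
at capture rate 0.4 and estimates dispersion:

```
simulated 4000 cells x 1000 genes (capture rate q = 0.4)
Spearman(dispersion, true offset) = 0.972  (close to 1: the estimator ranks genes by their generative offsets)
Spearman(dispersion, mean)        = -0.003  (close to 0: residualization removed the mean-variance trend)
```

The first number says the estimated dispersion recovers the per-gene
generative variance offsets almost perfectly at this depth; the second says
the estimate carries essentially no residual mean information — the defining
property of a mean-corrected dispersion measure.

`examples/04_cis_trans_partition.py` runs the comparative design end to end
(two diploid species plus an allotetraploid line) and classifies DD genes:

```
45 genes DD between diploid species (FDR < 0.05)
cis/trans classification (30%/70% rule):
not_dd     255
cis         16
neither     15
trans       14

correlation of estimated vs generative cis fraction among DD genes: 0.95
```

The other examples cover differential dispersion with permutation FDR
(`02`) and rank/enrichment analyses (`03`). A thin CLI wraps the same
functions (`scdisp simulate|moments|dd|dd-hybrid|rank|sets|enrich|cistrans|
run|report`); `scdisp run --out dir/ --seed 1` executes the whole pipeline
and writes stage-tagged TSVs plus a manifest.

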