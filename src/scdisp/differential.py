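"""Differential dispersion and expression tests with permutation-based FDR.

The cell-type analysis quantile-normalizes per-sample dispersion estimates,
fits a per-gene fixed-effect (cell-means) linear model with all pairwise
cell-type contrasts, and calibrates significance with an empirical null built
by permuting sample-level cell-type labels.  Interspecies tests use a
random-intercept model per individual; the allotetraploid comparison is a
two-sample difference of allele-wise dispersions with a cell-level bootstrap
standard error.  Mean-expression analogues run on pseudobulk log-CPM through
the same model machinery, plus a per-cell paired signed-rank test for
allele-resolved counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from scdisp.moments import (
    TrendFit,
    correct_capture,
    fit_trend,
    residual_variance,
    raw_group_moments,
)

__all__ = [
    "PermutationNull",
    "quantile_normalize",
    "dd_fixed_effect",
    "permutation_null",
    "empirical_fdr",
    "dd_mixed",
    "dd_two_sample",
    "pseudobulk",
    "de_pseudobulk",
    "de_allele_paired",
    "variance_partition",
]


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Map each sample (row) onto the mean of the across-sample order statistics.

    After normalization every complete sample carries the same multiset of
    values; within-sample ranks are preserved and ties receive the mean of the
    tied reference values.  Missing entries stay missing; samples with missing
    entries are mapped through interpolation at their own quantile positions.
    """
    X = values.to_numpy(dtype=float)
    n_s, n_g = X.shape
    if n_s == 0 or n_g == 0:
        raise ValueError("empty input")
    if np.any(np.all(np.isnan(X), axis=1)):
        raise ValueError("a sample with no observed values cannot be normalized")
    if n_s == 1:
        warnings.warn("single sample: quantile normalization is the identity")
        return values.copy()

    grid = (np.arange(n_g) + 0.5) / n_g
    ref = np.zeros(n_g)
    for row in X:
        obs = np.sort(row[~np.isnan(row)])
        k = obs.size
        ref += np.interp(grid, (np.arange(k) + 0.5) / k, obs)
    ref /= n_s

    out = np.full_like(X, np.nan)
    for i, row in enumerate(X):
        mask = ~np.isnan(row)
        k = mask.sum()
        ranks = st.rankdata(row[mask])  # average ranks for ties
        out[i, mask] = np.interp((ranks - 0.5) / k, grid, ref)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# fixed-effect pairwise cell-type model


def _bh(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-gene residual variances.

    Moment-matches a scaled inverse chi-square prior on the true variances
    from the distribution of ``log s2`` (Smyth-style), then returns posterior
    variances ``(d0*s0^2 + df*s2) / (d0 + df)`` and the total df.  Genes with
    zero variance are left untouched.
    """
    from scipy.special import digamma, polygamma

    ok = np.isfinite(s2) & (s2 > 0)
    z = np.log(s2[ok])
    e = z - digamma(df / 2) + np.log(df / 2)
    target = max(np.var(e, ddof=1) - polygamma(1, df / 2), 1e-8)

    from scipy.optimize import brentq

    def f(d0):
        return polygamma(1, d0 / 2) - target

    if polygamma(1, 1e-3 / 2) < target:
        d0 = 1e-3
    elif polygamma(1, 1e6 / 2) > target:
        d0 = np.inf
    else:
        d0 = brentq(f, 1e-3, 1e6)
    if np.isinf(d0):
        s0_sq = np.exp(np.mean(e))
        post = np.full_like(s2, s0_sq)
        post[~ok] = s2[~ok]
        return post, np.inf
    s0_sq = np.exp(np.mean(e) + digamma(d0 / 2) - np.log(d0 / 2))
    post = s2.copy()
    post[ok] = (d0 * s0_sq + df * s2[ok]) / (d0 + df)
    return post, df + d0


def dd_fixed_effect(norm_disp: pd.DataFrame, design: pd.Series,
                    moderate: bool = False) -> pd.DataFrame:
    """All pairwise cell-type contrasts from a per-gene one-way linear model.

    ``norm_disp`` is samples x genes (e.g. quantile-normalized dispersion or
    pseudobulk log-CPM); ``design`` gives the cell-type label of each sample.
    Genes with any missing value are dropped.  Returns a long effect table
    with one row per gene x contrast and BH FDR within each contrast.
    """
    design = design.reindex(norm_disp.index)
    if design.isna().any():
        raise ValueError("design labels missing for some samples")
    complete = norm_disp.columns[norm_disp.notna().all(axis=0)]
    if len(complete) < len(norm_disp.columns):
        warnings.warn(f"dropping {len(norm_disp.columns) - len(complete)} genes "
                      "with missing values")
    Y = norm_disp[complete].to_numpy(dtype=float)
    genes = np.asarray(complete)

    levels = sorted(lv for lv in pd.unique(design) if (design == lv).sum() >= 2)
    dropped = set(pd.unique(design)) - set(levels)
    if dropped:
        warnings.warn(f"cell types with a single sample dropped from contrasts: "
                      f"{sorted(map(str, dropped))}")
    if len(levels) < 2:
        raise ValueError("need at least two cell types with >= 2 samples")

    keep = design.isin(levels).to_numpy()
    Y = Y[keep]
    labels = design.to_numpy()[keep]
    n, g = Y.shape
    k = len(levels)

    means = np.vstack([Y[labels == lv].mean(axis=0) for lv in levels])
    counts = np.array([(labels == lv).sum() for lv in levels])
    rss = np.zeros(g)
    for i, lv in enumerate(levels):
        rss += ((Y[labels == lv] - means[i])**2).sum(axis=0)
    df = n - k
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = rss / df
    df_eff = float(df)
    if moderate:
        s2, df_eff = squeeze_variances(s2, df)

    rows = []
    for i, j in combinations(range(k), 2):
        eff = means[i] - means[j]
        se = np.sqrt(s2 * (1.0 / counts[i] + 1.0 / counts[j]))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, eff / se, 0.0)
        p = 2 * st.t.sf(np.abs(t), df_eff)
        rows.append(pd.DataFrame({
            "gene": genes,
            "contrast": f"{levels[i]}_vs_{levels[j]}",
            "effect": eff, "se": se, "statistic": t, "p": p,
            "fdr": _bh(p),
            "method": "fixed_effect" + ("_eb" if moderate else ""),
        }))
    out = pd.concat(rows, ignore_index=True)
    out.attrs["df"] = df_eff
    return out


# ---------------------------------------------------------------------------
# permutation null and empirical FDR


@dataclass
class PermutationNull:
    """Pooled null statistics from B permutations of cell-type labels."""

    statistics: np.ndarray
    n_permutations: int
    seed: int


def permutation_null(norm_disp: pd.DataFrame, design: pd.Series,
                     n_permutations: int = 100, seed: int = 0,
                     within: pd.Series | None = None) -> PermutationNull:
    """Null t statistics from permuting sample-level cell-type labels.

    Each permutation shuffles the labels across samples (within levels of
    ``within`` when given, e.g. within individuals), preserving group sizes;
    the t statistics of all pairwise contrasts of all genes are pooled.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    labels = design.reindex(norm_disp.index)
    pooled = []
    for _ in range(n_permutations):
        perm = labels.copy()
        if within is None:
            perm[:] = rng.permutation(labels.to_numpy())
        else:
            w = within.reindex(norm_disp.index)
            for lv in pd.unique(w):
                idx = np.where((w == lv).to_numpy())[0]
                perm.iloc[idx] = rng.permutation(labels.to_numpy()[idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = dd_fixed_effect(norm_disp, perm)
        pooled.append(res["statistic"].to_numpy())
    return PermutationNull(statistics=np.abs(np.concatenate(pooled)),
                           n_permutations=n_permutations, seed=seed)


def empirical_fdr(effects: pd.DataFrame, null: PermutationNull) -> pd.DataFrame:
    """Empirical p from the pooled permutation null, plus BH FDR.

    ``empirical_p = (1 + #{|null| >= |t|}) / (1 + N_null)`` with the null
    pooled across genes, contrasts and permutations.  Returns a copy of the
    effect table with ``empirical_p`` and ``fdr`` recomputed from it.
    """
    if null.statistics.size == 0:
        raise ValueError("empty permutation null")
    sorted_null = np.sort(null.statistics)
    t = np.abs(effects["statistic"].to_numpy(dtype=float))
    n_ge = sorted_null.size - np.searchsorted(sorted_null, t, side="left")
    emp_p = (1.0 + n_ge) / (1.0 + sorted_null.size)
    out = effects.copy()
    out["empirical_p"] = emp_p
    out["fdr"] = np.nan
    for c in pd.unique(out["contrast"]) if "contrast" in out else [None]:
        mask = slice(None) if c is None else (out["contrast"] == c).to_numpy()
        out.loc[mask, "fdr"] = _bh(out.loc[mask, "empirical_p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# interspecies mixed model


def dd_mixed(norm_disp: pd.DataFrame, species: pd.Series,
             individual: pd.Series) -> pd.DataFrame:
    """Per-gene species effect with a random intercept per individual.

    Fits, for every gene, ``value ~ species + (1 | individual)`` by REML and
    reports the species fixed effect, its SE and Wald p.  Singular or
    non-converged fits fall back to OLS with ``fallback=True`` recorded.
    """
    species = species.reindex(norm_disp.index)
    individual = individual.reindex(norm_disp.index)
    levels = pd.unique(species.dropna())
    if len(levels) != 2:
        raise ValueError(f"need exactly two species, got {list(levels)}")
    for lv in levels:
        if individual[species == lv].nunique() < 2:
            raise ValueError(f"need >= 2 individuals per species ({lv})")
    x = (species == levels[1]).to_numpy(dtype=float)
    exog = np.column_stack([np.ones_like(x), x])
    groups = individual.to_numpy()

    rows = []
    for gene in norm_disp.columns:
        y = norm_disp[gene].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 4 or np.unique(x[ok]).size < 2:
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, True))
            continue
        eff = se = np.nan
        fallback = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = MixedLM(y[ok], exog[ok], groups=groups[ok]).fit(reml=True)
            if (not fit.converged) or np.asarray(fit.cov_re)[0, 0] < 1e-10:
                fallback = True
            else:
                eff, se = fit.params[1], fit.bse[1]
        except (np.linalg.LinAlgError, ValueError):
            fallback = True
        if fallback:
            res = np.linalg.lstsq(exog[ok], y[ok], rcond=None)
            eff = res[0][1]
            resid = y[ok] - exog[ok] @ res[0]
            dof = ok.sum() - 2
            s2 = (resid**2).sum() / dof if dof > 0 else np.nan
            xtxi = np.linalg.inv(exog[ok].T @ exog[ok])
            se = np.sqrt(s2 * xtxi[1, 1])
        z = eff / se if se and se > 0 else np.nan
        p = 2 * st.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append((gene, eff, se, z, p, fallback))
    out = pd.DataFrame(rows, columns=["gene", "effect", "se", "statistic", "p",
                                      "fallback"])
    out["fdr"] = _bh(out["p"].to_numpy())
    out["contrast"] = f"{levels[1]}_vs_{levels[0]}"
    out["method"] = "mixed"
    return out


# ---------------------------------------------------------------------------
# allotetraploid two-sample test with cell bootstrap


def _paired_allele_matrices(adata: ad.AnnData):
    obs = adata.obs
    if "genome" not in obs.columns or "cell_id" not in obs.columns:
        raise ValueError("allotetraploid data needs 'genome' and 'cell_id' columns")
    a_rows = obs.index[obs["genome"] == "A"]
    b_rows = obs.index[obs["genome"] == "B"]
    ids_a = obs.loc[a_rows, "cell_id"]
    ids_b = obs.loc[b_rows, "cell_id"]
    if sorted(ids_a) != sorted(ids_b):
        raise ValueError("unpaired allotetraploid cells: allele rows do not match")
    order_a = a_rows[np.argsort(ids_a.to_numpy())]
    order_b = b_rows[np.argsort(ids_b.to_numpy())]
    Xa = adata[order_a].X
    Xb = adata[order_b].X
    return sp.csr_matrix(Xa), sp.csr_matrix(Xb)


def _weighted_moments(X: sp.csr_matrix, X2: sp.csr_matrix, w: np.ndarray):
    n = w.sum()
    mean = (w @ X) / n
    mean = np.asarray(mean).ravel()
    sq = np.asarray((w @ X2) / n).ravel()
    var = (sq - mean**2) * n / (n - 1)
    return mean, np.maximum(var, 0.0)


def _allele_dispersion(raw_mean, raw_var, q, trend_degree, gene_mask):
    m, v = correct_capture(raw_mean, raw_var, q)
    m = np.where(gene_mask, m, np.nan)
    v = np.where(gene_mask, v, np.nan)
    trend = fit_trend(m, v, degree=trend_degree)
    return residual_variance(m, v, trend)


def dd_two_sample(adata: ad.AnnData, q: float, n_bootstrap: int = 200,
                  seed: int = 0, min_raw_mean: float = 0.07,
                  trend_degree: int = 2) -> pd.DataFrame:
    """Allele-wise dispersion difference in allotetraploid cells.

    Effect per gene is ``dispersion(genome A) - dispersion(genome B)``.  The
    SE comes from a cell-level bootstrap: cells are resampled with
    replacement keeping each cell's two allele rows together, and the whole
    moment-correction-trend pipeline is recomputed per replicate.  Two-sided
    normal p from z = effect / SE, BH FDR.
    """
    if n_bootstrap < 100:
        raise ValueError("need n_bootstrap >= 100")
    Xa, Xb = _paired_allele_matrices(adata)
    n_cells = Xa.shape[0]
    genes = adata.var_names.to_numpy()
    Xa2, Xb2 = Xa.multiply(Xa).tocsr(), Xb.multiply(Xb).tocsr()

    ma_raw, va_raw = raw_group_moments(Xa)
    mb_raw, vb_raw = raw_group_moments(Xb)
    gene_mask = (ma_raw >= min_raw_mean) & (mb_raw >= min_raw_mean)
    da = _allele_dispersion(ma_raw, va_raw, q, trend_degree, gene_mask)
    db = _allele_dispersion(mb_raw, vb_raw, q, trend_degree, gene_mask)
    effect = da - db

    rng = np.random.default_rng(seed)
    boots = np.full((n_bootstrap, genes.size), np.nan)
    for b in range(n_bootstrap):
        w = rng.multinomial(n_cells, np.full(n_cells, 1.0 / n_cells)).astype(float)
        ma, va = _weighted_moments(Xa, Xa2, w)
        mb, vb = _weighted_moments(Xb, Xb2, w)
        try:
            da_b = _allele_dispersion(ma, va, q, trend_degree, gene_mask)
            db_b = _allele_dispersion(mb, vb, q, trend_degree, gene_mask)
        except ValueError:
            continue
        boots[b] = da_b - db_b
    se = np.nanstd(boots, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        # a degenerate bootstrap (zero spread) with zero effect is a clean null
        z = np.where(se > 0, effect / se,
                     np.where(effect == 0, 0.0, np.sign(effect) * np.inf))
    p = 2 * st.norm.sf(np.abs(z))
    out = pd.DataFrame({
        "gene": genes, "contrast": "A_vs_B",
        "effect": effect, "se": se, "statistic": z, "p": p,
        "fdr": _bh(p), "method": "two_sample_bootstrap",
    })
    return out


# ---------------------------------------------------------------------------
# pseudobulk differential expression


def pseudobulk(adata: ad.AnnData, group_keys: list[str]) -> pd.DataFrame:
    """Sum counts across cells per sample group; samples x genes."""
    groups = adata.obs.groupby(group_keys, observed=True, sort=True).indices
    rows, index = [], []
    X = sp.csr_matrix(adata.X)
    for key, idx in groups.items():
        rows.append(np.asarray(X[np.asarray(idx)].sum(axis=0)).ravel())
        index.append(key if isinstance(key, tuple) else (key,))
    out = pd.DataFrame(np.vstack(rows),
                       index=pd.MultiIndex.from_tuples(index, names=group_keys),
                       columns=adata.var_names)
    return out


def log_cpm(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a pseudocount on the CPM scale."""
    lib = counts.sum(axis=1)
    cpm = counts.div(lib, axis=0) * 1e6
    return np.log2(cpm + pseudocount)


def de_pseudobulk(adata: ad.AnnData, group_keys: list[str],
                  condition: str = "cell_type", method: str = "fixed",
                  individual_key: str | None = None,
                  moderate: bool = False) -> pd.DataFrame:
    """Pseudobulk differential mean expression through the DD model machinery."""
    pb = pseudobulk(adata, group_keys)
    y = log_cpm(pb)
    meta = pb.index.to_frame(index=False)
    meta.index = y.index
    if method == "fixed":
        return dd_fixed_effect(y, meta[condition], moderate=moderate)
    if method == "mixed":
        if individual_key is None:
            raise ValueError("mixed method needs individual_key")
        return dd_mixed(y, meta[condition], meta[individual_key])
    raise ValueError(f"unknown method {method!r}")


def de_allele_paired(adata: ad.AnnData, min_nonzero_pairs: int = 5) -> pd.DataFrame:
    """Per-gene paired signed-rank test of allele A vs allele B counts per cell.

    Zero differences are dropped (standard signed-rank convention); the exact
    null is used for up to 25 nonzero pairs, a normal approximation with
    continuity correction above.  Genes with fewer than ``min_nonzero_pairs``
    nonzero differences get a missing p.
    """
    Xa, Xb = _paired_allele_matrices(adata)
    D = np.asarray(Xa.todense(), dtype=float) - np.asarray(Xb.todense(), dtype=float)
    genes = adata.var_names.to_numpy()
    rows = []
    for j, gene in enumerate(genes):
        d = D[:, j]
        nz = d[d != 0]
        med = float(np.median(d))
        if nz.size < min_nonzero_pairs:
            rows.append((gene, med, np.nan, np.nan))
            continue
        method = "exact" if nz.size <= 25 else "approx"
        stat, p = st.wilcoxon(nz, zero_method="wilcox",
                              correction=(method == "approx"),
                              alternative="two-sided", method=method)
        rows.append((gene, med, stat, p))
    out = pd.DataFrame(rows, columns=["gene", "effect", "statistic", "p"])
    out["fdr"] = _bh(out["p"].to_numpy())
    out["method"] = "wilcoxon_paired"
    return out


# ---------------------------------------------------------------------------
# variance partition


def variance_partition(norm_disp: pd.DataFrame, cell_type: pd.Series,
                       covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-gene variance fractions for cell type, technical covariates, residual.

    Fits ``value ~ covariates + (1 | cell_type)`` per gene; the cell-type
    fraction is the random-intercept variance over the total, each covariate's
    fraction is the variance of its fitted component over the total, and the
    residual completes the sum to one.  Genes with singular fits get NaN
    fractions and ``failed=True``.
    """
    ct = cell_type.reindex(norm_disp.index)
    if ct.nunique() < 2:
        raise ValueError("need >= 2 cell-type levels")
    cov = covariates.reindex(norm_disp.index).astype(float)
    constant = cov.columns[cov.std(ddof=0) == 0]
    cov = cov.drop(columns=constant)  # a constant explains no variance
    covn = (cov - cov.mean()) / cov.std(ddof=0)
    exog = np.column_stack([np.ones(len(covn)), covn.to_numpy()])
    cov_names = list(covn.columns)
    groups = ct.to_numpy()

    rows = []
    for gene in norm_disp.columns:
        y = norm_disp[gene].to_numpy(dtype=float)
        ok = np.isfinite(y)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = MixedLM(y[ok], exog[ok], groups=groups[ok]).fit(reml=True)
            if not fit.converged:
                raise ValueError("no convergence")
            var_ct = float(np.asarray(fit.cov_re)[0, 0])
            var_res = float(fit.scale)
            parts = {}
            for i, name in enumerate(cov_names):
                comp = exog[ok][:, i + 1] * fit.params[i + 1]
                parts[name] = float(np.var(comp, ddof=0))
            total = var_ct + var_res + sum(parts.values())
            row = {"gene": gene, "cell_type": var_ct / total,
                   **{k: v / total for k, v in parts.items()},
                   **{k: 0.0 for k in constant},
                   "residual": var_res / total, "failed": False}
        except (np.linalg.LinAlgError, ValueError):
            row = {"gene": gene, "cell_type": np.nan,
                   **{k: np.nan for k in cov_names},
                   **{k: np.nan for k in constant},
                   "residual": np.nan, "failed": True}
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
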