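"""Capture-corrected moment estimation and mean-corrected dispersion.

UMI counts are modelled as a binomial subsample, at capture rate ``q``, of the
true per-cell transcript count.  Inverting the thinning gives moment-consistent
estimates of the true mean and variance from the raw UMI mean ``x`` and
variance ``s2``::

    mean      m = x / q
    variance  v = (s2 - (1 - q) * x) / q**2

Dispersion is the residual of ``log v`` against a polynomial trend of
``log v`` on ``log m`` fitted across genes within each sample group, removing
the systematic dependence of variance on mean expression.  ``v`` can be
non-positive for genes whose raw variance is at or below the thinning floor;
those entries are flagged undefined rather than floored, so no dispersion
value is fabricated for them.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "TrendFit",
    "correct_capture",
    "fit_trend",
    "residual_variance",
    "raw_group_moments",
    "estimate_moments",
]

DEFAULT_MIN_RAW_MEAN = 0.07
MIN_TREND_GENES = 50


@dataclass(eq=False)
class TrendFit:
    """Least-squares polynomial of log variance on log mean for one group."""

    coefficients: np.ndarray  # highest degree first, np.polyval convention
    degree: int
    n_genes: int
    residual_sd: float

    def predict(self, log_mean: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, log_mean)


def correct_capture(raw_mean, raw_var, q: float):
    """Invert binomial thinning at rate ``q`` on per-gene moments.

    Returns (corrected mean, corrected variance).  The corrected variance may
    be non-positive; callers must flag such genes rather than use them.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError(f"capture rate q must lie in (0, 1], got {q}")
    raw_mean = np.asarray(raw_mean, dtype=float)
    raw_var = np.asarray(raw_var, dtype=float)
    if np.any(raw_mean < 0) or np.any(raw_var < 0):
        raise ValueError("raw moments must be non-negative")
    m = raw_mean / q
    v = (raw_var - (1.0 - q) * raw_mean) / q**2
    return m, v


def fit_trend(corrected_mean, corrected_var, degree: int = 2) -> TrendFit:
    """Fit the mean-variance trend across genes of one sample group.

    Ordinary least squares of ``log v`` on a degree-``degree`` polynomial in
    ``log m``, using only genes with positive corrected variance.
    """
    m = np.asarray(corrected_mean, dtype=float)
    v = np.asarray(corrected_var, dtype=float)
    ok = np.isfinite(m) & np.isfinite(v) & (m > 0) & (v > 0)
    if ok.sum() < MIN_TREND_GENES:
        raise ValueError(
            f"need >= {MIN_TREND_GENES} genes with positive corrected variance "
            f"to fit the mean-variance trend, got {int(ok.sum())}"
        )
    x, y = np.log(m[ok]), np.log(v[ok])
    coef = np.polyfit(x, y, deg=degree)
    resid = y - np.polyval(coef, x)
    return TrendFit(coefficients=coef, degree=degree, n_genes=int(ok.sum()),
                    residual_sd=float(np.std(resid)))


def residual_variance(corrected_mean, corrected_var, trend: TrendFit) -> np.ndarray:
    """Dispersion: log corrected variance minus the fitted trend (NaN if v <= 0)."""
    m = np.asarray(corrected_mean, dtype=float)
    v = np.asarray(corrected_var, dtype=float)
    d = np.full(m.shape, np.nan)
    ok = np.isfinite(m) & np.isfinite(v) & (m > 0) & (v > 0)
    d[ok] = np.log(v[ok]) - trend.predict(np.log(m[ok]))
    return d


def raw_group_moments(X) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene raw mean and unbiased (n-1) variance of a cells x genes matrix."""
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to estimate a variance")
    if sp.issparse(X):
        mean = np.asarray(X.mean(axis=0)).ravel()
        sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    else:
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        sq = (X**2).mean(axis=0)
    var = (sq - mean**2) * n / (n - 1)
    return mean, np.maximum(var, 0.0)


def _group_indices(obs: pd.DataFrame, keys: list[str]) -> dict[tuple, np.ndarray]:
    grouped = obs.groupby(keys, observed=True, sort=True).indices
    return {k if isinstance(k, tuple) else (k,): np.asarray(v)
            for k, v in grouped.items()}


def estimate_moments(
    adata: ad.AnnData,
    group_keys: list[str] | str,
    q: float,
    min_raw_mean: float = DEFAULT_MIN_RAW_MEAN,
    min_cells_per_group: int | None = 1000,
    trend_degree: int = 2,
) -> pd.DataFrame:
    """Per gene x group corrected moments and dispersion.

    A gene passes the expression filter only if its raw UMI mean is at least
    ``min_raw_mean`` in EVERY group (intersection rule), so no gene is
    compared across groups in which it is too lowly expressed to measure.
    When ``min_cells_per_group`` is set and ``cell_type`` is among the group
    keys, cell types with fewer than that many cells in any sub-group are
    dropped before estimation; other groupings drop undersized groups
    directly.

    Returns a long table (one row per gene x group) with columns: the group
    keys, ``gene``, ``n_cells``, ``raw_mean``, ``mean``, ``variance``,
    ``dispersion`` (NaN where undefined) and ``pass_filter``.  The per-group
    :class:`TrendFit` objects are attached in ``result.attrs["trends"]``.
    """
    if isinstance(group_keys, str):
        group_keys = [k.strip() for k in group_keys.split(",")]
    for k in group_keys:
        if k not in adata.obs.columns:
            raise ValueError(f"group key {k!r} not in cell metadata")
    groups = _group_indices(adata.obs, group_keys)
    if not groups:
        raise ValueError("grouping produced no cell groups")
    for key, idx in groups.items():
        if idx.size == 0:
            raise ValueError(f"empty group {key}")

    if min_cells_per_group is not None:
        if "cell_type" in group_keys:
            ct_pos = group_keys.index("cell_type")
            bad_ct = {k[ct_pos] for k, idx in groups.items()
                      if idx.size < min_cells_per_group}
            groups = {k: v for k, v in groups.items() if k[ct_pos] not in bad_ct}
        else:
            groups = {k: v for k, v in groups.items()
                      if v.size >= min_cells_per_group}
        if not groups:
            raise ValueError(
                f"no group satisfies the {min_cells_per_group}-cell inclusion rule"
            )

    genes = adata.var_names.to_numpy()
    X = adata.X
    raw = {}
    for key, idx in groups.items():
        raw[key] = raw_group_moments(X[idx])

    # intersection filter: pass only if expressed above threshold everywhere
    pass_filter = np.ones(genes.size, dtype=bool)
    for key, (mean, _) in raw.items():
        pass_filter &= mean >= min_raw_mean
    if not pass_filter.any():
        raise ValueError("all genes fail the raw-mean expression filter")

    rows = []
    trends: dict[tuple, TrendFit] = {}
    for key, idx in groups.items():
        raw_mean, raw_var = raw[key]
        m, v = correct_capture(raw_mean, raw_var, q)
        m_f = np.where(pass_filter, m, np.nan)
        v_f = np.where(pass_filter, v, np.nan)
        trend = fit_trend(m_f, v_f, degree=trend_degree)
        d = residual_variance(m_f, v_f, trend)
        trends[key] = trend
        df = pd.DataFrame({k: val for k, val in zip(group_keys, key)}
                          | {"gene": genes, "n_cells": idx.size,
                             "raw_mean": raw_mean, "mean": m, "variance": v,
                             "dispersion": d, "pass_filter": pass_filter})
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    out.attrs["trends"] = trends
    out.attrs["group_keys"] = list(group_keys)
    out.attrs["q"] = q
    return out


def dispersion_matrix(moments: pd.DataFrame, group_keys: list[str] | None = None,
                      value: str = "dispersion") -> pd.DataFrame:
    """Pivot a long moment table to a samples x genes matrix of one column."""
    if group_keys is None:
        group_keys = moments.attrs.get("group_keys")
    if group_keys is None:
        raise ValueError("group_keys needed to pivot the moment table")
    sub = moments[moments["pass_filter"]]
    wide = sub.pivot_table(index=group_keys, columns="gene", values=value,
                           aggfunc="first", dropna=False)
    # pivot_table expands to the cartesian product of key levels; keep only
    # groups actually present in the table
    observed = pd.MultiIndex.from_frame(
        sub[group_keys].drop_duplicates()) if len(group_keys) > 1 else pd.Index(
        sub[group_keys[0]].unique())
    return wide.loc[wide.index.isin(observed)]
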