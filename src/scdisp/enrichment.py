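"""Enrichment statistics: sliding-window eGene profiles, Fisher and
hypergeometric tests, and the two-group / correlation tests used throughout
the analysis.

The sliding-window profile walks windows of width ``w`` with stride ``s``
along a dispersion ranking and reports the proportion of a target set (e.g.
eGenes) in each window, with a percentile confidence band built from sets of
the same size drawn uniformly from the ranked genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "sliding_window_proportion",
    "fisher_enrichment",
    "set_enrichment",
    "group_compare",
    "spearman",
]


def sliding_window_proportion(ranking: pd.Series, members: set[str],
                              window: int, step: int, n_resamples: int = 50,
                              seed: int = 0) -> pd.DataFrame:
    """Set proportion per rank window, with a resampled 2.5/97.5% band.

    ``ranking`` maps genes to ranks (1 = lowest dispersion).  For each window
    the observed proportion is |set ∩ window| / window.  The band per window
    comes from ``n_resamples`` uniformly drawn gene sets of the same size.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    genes = ranking.sort_values().index.to_numpy()
    g = genes.size
    if window > g:
        raise ValueError("window larger than the number of ranked genes")
    members = set(members)
    if not members <= set(genes):
        raise ValueError("target set must be a subset of the ranked genes")
    is_member = np.isin(genes, list(members))
    starts = np.arange(0, g - window + 1, step)

    def window_props(ind: np.ndarray) -> np.ndarray:
        cum = np.concatenate([[0], np.cumsum(ind)])
        return (cum[starts + window] - cum[starts]) / window

    observed = window_props(is_member)
    rng = np.random.default_rng(seed)
    k = int(is_member.sum())
    res = np.empty((n_resamples, starts.size))
    for r in range(n_resamples):
        ind = np.zeros(g, dtype=bool)
        ind[rng.choice(g, size=k, replace=False)] = True
        res[r] = window_props(ind)
    lo, hi = np.percentile(res, [2.5, 97.5], axis=0)
    return pd.DataFrame({
        "start_rank": starts + 1, "end_rank": starts + window,
        "proportion": observed, "band_low": lo, "band_high": hi,
    })


@dataclass
class EnrichmentResult:
    """2x2 enrichment with sample odds ratio, Woolf 95% CI and exact p."""

    table: np.ndarray  # [[a, b], [c, d]]
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


def _woolf_ci(a, b, c, d, alpha=0.05):
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells == 0):  # Haldane-Anscombe
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = st.norm.ppf(1 - alpha / 2)
    return np.exp(log_or - z * se), np.exp(log_or + z * se)


def fisher_enrichment(bin_set: set[str], target_set: set[str],
                      universe: set[str]) -> EnrichmentResult:
    """Fisher's exact test of bin x target membership over a gene universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    bin_set = set(bin_set) & universe
    target_set = set(target_set) & universe
    a = len(bin_set & target_set)
    b = len(bin_set - target_set)
    c = len(target_set - bin_set)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    _, p = st.fisher_exact(table, alternative="two-sided")
    with np.errstate(divide="ignore", invalid="ignore"):
        sample_or = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    lo, hi = _woolf_ci(a, b, c, d)
    return EnrichmentResult(table=table, odds_ratio=float(sample_or),
                            ci_low=float(lo), ci_high=float(hi), p=float(p))


def _qvalues(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a fixed lambda pFDR estimate of pi0."""
    m = p.size
    pi0 = min(1.0, (p > lam).sum() / ((1 - lam) * m)) if m else 1.0
    order = np.argsort(p)
    ranked = p[order]
    q = pi0 * ranked * m / (np.arange(m) + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def set_enrichment(query: set[str], collection: dict[str, list[str] | set[str]],
                   background: set[str], fdr_cutoff: float = 0.05,
                   q_cutoff: float = 0.2) -> pd.DataFrame:
    """Hypergeometric (upper-tail) enrichment of a query set in a collection.

    Each collection set is intersected with the background; p is
    ``P[X >= overlap]`` for X hypergeometric with the background as the urn.
    BH-adjusted p and Storey q-values are reported; sets passing both cutoffs
    are flagged significant.
    """
    background = set(background)
    query = set(query)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    if not query:
        return pd.DataFrame(columns=["set", "overlap", "set_size", "query_size",
                                     "background_size", "p", "fdr", "qvalue",
                                     "significant"]).set_index("set")
    n_bg = len(background)
    n_q = len(query)
    rows = []
    for name, genes in collection.items():
        s = set(genes) & background
        k = len(query & s)
        p = float(st.hypergeom.sf(k - 1, n_bg, len(s), n_q)) if s else 1.0
        rows.append((name, k, len(s), n_q, n_bg, p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "query_size",
                                      "background_size", "p"]).set_index("set")
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["qvalue"] = _qvalues(out["p"].to_numpy())
    out["significant"] = (out["fdr"] <= fdr_cutoff) & (out["qvalue"] <= q_cutoff)
    return out.sort_values("p")


def group_compare(values: pd.Series, group_a: set[str], group_b: set[str],
                  test: str = "mann_whitney") -> tuple[float, float]:
    """Two-sided Mann-Whitney U or Kolmogorov-Smirnov test between gene groups."""
    a = values.reindex(sorted(group_a)).dropna().to_numpy(dtype=float)
    b = values.reindex(sorted(group_b)).dropna().to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty with observed values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return (float(a.size * b.size / 2) if test == "mann_whitney" else 0.0, 1.0)
    if test == "mann_whitney":
        stat, p = st.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "ks":
        stat, p = st.ks_2samp(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(stat), float(p)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties; (nan, nan) if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.unique(x[ok]).size < 2 or np.unique(y[ok]).size < 2:
        return float("nan"), float("nan")
    rho, p = st.spearmanr(x[ok], y[ok])
    return float(rho), float(p)
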