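"""Dispersion-based gene rankings, quintile sets and rank-stability selection.

Genes are ranked within each cell type by their median dispersion across
individuals (rank 1 = lowest dispersion, ties averaged).  Shared low/high
dispersion sets are the genes in the first (respectively fifth) quintile of
that ranking in every cell type; the analytic null for the overlap of such
sets under independent rankings is ``n_genes * fraction ** n_cell_types``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st

__all__ = [
    "rank_by_dispersion",
    "quintile_bins",
    "shared_quintile_sets",
    "expected_overlap",
    "stable_ranking",
    "mean_quintile_distribution",
    "extreme_fraction_sets",
]


def rank_by_dispersion(moments: pd.DataFrame, value: str = "dispersion",
                       by: str = "cell_type",
                       within: str = "individual") -> pd.DataFrame:
    """Genes x cell-types table of dispersion ranks (1 = lowest, ties averaged).

    The ranking basis is the median of ``value`` across ``within`` (the
    individuals) for each gene in each cell type.  Genes missing a value in
    any group are excluded before ranking, so all cell types rank the same
    gene universe.
    """
    if moments.empty:
        raise ValueError("empty moment table")
    sub = moments[moments["pass_filter"]] if "pass_filter" in moments else moments
    med = sub.pivot_table(index="gene", columns=by, values=value,
                          aggfunc="median", dropna=False)
    med = med.dropna(axis=0, how="any")
    if med.empty:
        raise ValueError("no gene has a defined dispersion in every cell type")
    ranks = med.apply(lambda col: st.rankdata(col), axis=0)
    ranks = pd.DataFrame(ranks, index=med.index, columns=med.columns)
    ranks.attrs["medians"] = med
    return ranks


def quintile_bins(ranks: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Quintile (1..5) per rank; boundary ties fall to the lower bin."""
    g = len(ranks)
    q = 1 + np.floor(5 * (np.asarray(ranks, dtype=float) - 1) / g).astype(int)
    q = np.clip(q, 1, 5)
    if isinstance(ranks, pd.Series):
        return pd.Series(q, index=ranks.index)
    return pd.DataFrame(q, index=ranks.index, columns=ranks.columns)


def shared_quintile_sets(ranks: pd.DataFrame) -> dict[str, set[str]]:
    """Genes in the first (shared_low) / fifth (shared_high) quintile everywhere."""
    if ranks.isna().any().any():
        raise ValueError("rankings must share a common gene universe")
    q = quintile_bins(ranks)
    low = set(q.index[(q == 1).all(axis=1)])
    high = set(q.index[(q == 5).all(axis=1)])
    return {"shared_low": low, "shared_high": high}


def expected_overlap(n_genes: int, n_cell_types: int, fraction: float) -> float:
    """Expected shared-set size under independent rankings: n * f**k."""
    if n_genes < 1 or n_cell_types < 1:
        raise ValueError("n_genes and n_cell_types must be positive")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    return n_genes * fraction**n_cell_types


def stable_ranking(ranks: pd.DataFrame,
                   deviation_fraction: float = 0.15) -> pd.DataFrame:
    """Genes whose rank never strays far from their cross-cell-type median.

    A gene is kept if, in every cell type, its rank deviates from its median
    rank across cell types by at most ``deviation_fraction`` of the number of
    ranked genes.  Returns the kept genes with their median ranks.
    """
    if not 0.0 < deviation_fraction <= 1.0:
        raise ValueError("deviation_fraction must lie in (0, 1]")
    g = len(ranks)
    med = ranks.median(axis=1)
    dev = ranks.sub(med, axis=0).abs().max(axis=1)
    keep = dev <= deviation_fraction * g
    out = pd.DataFrame({"median_rank": med[keep]})
    out.index.name = "gene"
    return out.sort_values("median_rank")


def mean_quintile_distribution(members: set[str],
                               mean_ranking: pd.Series) -> pd.Series:
    """Counts of set members per quintile of a mean-expression ranking.

    ``mean_ranking`` holds ranks of the median mean expression across cell
    types (1 = lowest mean).  The five counts sum to the number of members
    present in the ranking.
    """
    q = quintile_bins(mean_ranking)
    counts = pd.Series(0, index=pd.RangeIndex(1, 6, name="quintile"))
    in_set = q[q.index.isin(members)]
    vc = in_set.value_counts()
    counts.loc[vc.index] = vc.values
    return counts


def extreme_fraction_sets(rank_column: pd.Series,
                          fraction: float = 0.3) -> dict[str, set[str]]:
    """Within-cell-type low/high dispersion sets at a rank-fraction cutoff."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    g = len(rank_column)
    cut = fraction * g
    low = set(rank_column.index[rank_column <= cut])
    high = set(rank_column.index[rank_column > g - cut])
    return {"low": low, "high": high}
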