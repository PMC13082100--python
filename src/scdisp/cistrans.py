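"""Cis/trans partitioning of interspecies dispersion divergence.

In an allotetraploid line both parental genomes share one nucleus, so an
interspecies difference that persists between the alleles must be encoded in
cis.  Given the diploid interspecies effect ``d`` and the allelic
(allotetraploid) effect ``t`` for a gene, the cis proportion is

    |t| / (|t| + |d - t|)

A gene is called cis within a cell type when the proportion exceeds the high
threshold (default 0.70), trans when it is below the low threshold (default
0.30), neither otherwise, with strict inequalities at the boundaries; genes
not differentially dispersed are not classified.  Per-gene aggregate calls
follow the precedence mixed > cis/trans > neither > not_dd.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "cis_proportion",
    "classify_cell_type",
    "classify_table",
    "aggregate_gene",
    "recapitulation_fraction",
    "specificity_count",
]

CLASSES = ("cis", "trans", "neither", "not_dd")


def cis_proportion(diploid_lfc, tetra_lfc):
    """|t| / (|t| + |d - t|); NaN where both terms vanish.

    Scale-invariant: multiplying both effects by any nonzero constant leaves
    the proportion unchanged.
    """
    d = np.asarray(diploid_lfc, dtype=float)
    t = np.asarray(tetra_lfc, dtype=float)
    denom = np.abs(t) + np.abs(d - t)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, np.abs(t) / denom, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def classify_cell_type(cis_prop: float, dd_flag: bool,
                       hi: float = 0.70, lo: float = 0.30) -> str:
    """cis / trans / neither call for one gene in one cell type."""
    if not 0.0 < lo < hi < 1.0:
        raise ValueError(f"need 0 < lo < hi < 1, got lo={lo}, hi={hi}")
    if not dd_flag:
        return "not_dd"
    if np.isnan(cis_prop):
        return "neither"
    if cis_prop > hi:
        return "cis"
    if cis_prop < lo:
        return "trans"
    return "neither"


def classify_table(diploid: pd.DataFrame, tetra: pd.DataFrame,
                   hi: float = 0.70, lo: float = 0.30,
                   dd_column: str = "significant") -> pd.DataFrame:
    """Per gene x cell type cis/trans calls from two effect tables.

    Both tables need columns ``gene``, ``effect`` and a boolean ``dd_column``
    marking significant diploid DD genes, plus ``cell_type`` when calls are
    per cell type.  Effects must be on the same dispersion scale in both
    tables.  Returns a table with cis proportion and class per row.
    """
    keys = ["gene"] + (["cell_type"] if "cell_type" in diploid.columns else [])
    merged = diploid.merge(tetra, on=keys, suffixes=("_diploid", "_tetra"))
    prop = cis_proportion(merged["effect_diploid"].to_numpy(),
                          merged["effect_tetra"].to_numpy())
    dd = merged[f"{dd_column}_diploid"].to_numpy(dtype=bool) \
        if f"{dd_column}_diploid" in merged else merged[dd_column].to_numpy(dtype=bool)
    calls = [classify_cell_type(p, f, hi=hi, lo=lo) for p, f in zip(prop, dd)]
    out = merged[keys].copy()
    out["diploid_effect"] = merged["effect_diploid"].to_numpy()
    out["tetra_effect"] = merged["effect_tetra"].to_numpy()
    out["cis_proportion"] = prop
    out["class"] = calls
    return out


def aggregate_gene(calls: Iterable[str]) -> str:
    """Aggregate per-cell-type calls into one gene-level class.

    mixed when cis and trans co-occur; cis (or trans) when present in at
    least one cell type with all remaining calls neither or not_dd; neither
    when present at least once with all others not_dd; not_dd otherwise.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("need at least one cell-type call")
    bad = set(calls) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    has = {c: c in calls for c in CLASSES}
    if has["cis"] and has["trans"]:
        return "mixed"
    if has["cis"]:
        return "cis"
    if has["trans"]:
        return "trans"
    if has["neither"]:
        return "neither"
    return "not_dd"


def aggregate_table(calls: pd.DataFrame) -> pd.Series:
    """Gene-level aggregate class from a classify_table output."""
    return calls.groupby("gene")["class"].apply(aggregate_gene)


def recapitulation_fraction(diploid: pd.DataFrame, tetra: pd.DataFrame,
                            significance_column: str = "significant",
                            require_sign_concordance: bool = True) -> float:
    """Fraction of diploid DD genes recapitulated in the allotetraploid line.

    A diploid DD gene counts as recapitulated when it is significant in the
    allotetraploid table and (optionally) its effect has the same sign in
    both.  Tables are matched on ``gene``; NaN when no diploid DD genes.
    """
    dip = diploid.set_index("gene")
    tet = tetra.set_index("gene")
    dd_genes = dip.index[dip[significance_column].astype(bool)]
    if len(dd_genes) == 0:
        return float("nan")
    tet = tet.reindex(dd_genes)
    sig = tet[significance_column].fillna(False).astype(bool).to_numpy()
    if require_sign_concordance:
        sign_ok = (np.sign(dip.loc[dd_genes, "effect"].to_numpy())
                   * np.sign(tet["effect"].to_numpy())) > 0
        sig = sig & sign_ok
    return float(sig.sum() / len(dd_genes))


def specificity_count(dd_flags: pd.DataFrame) -> pd.Series:
    """Per-gene number of cell types in which the gene is DD."""
    return dd_flags.astype(bool).sum(axis=1)
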