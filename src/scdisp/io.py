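"""Readers and writers for the pipeline's interchange formats.

Counts travel as Matrix Market triplets with sidecar ``genes.tsv`` /
``cells.tsv`` tables; every tabular stage output is TSV with an explicit
header, ``NA`` as the missing marker, and optional leading ``#`` comment
lines naming the producing stage; gene sets use the GMT convention
(name, description, members, tab-separated).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "write_counts",
    "read_counts",
    "write_table",
    "read_table",
    "write_gmt",
    "read_gmt",
]

NA = "NA"


def write_counts(adata: ad.AnnData, outdir: str | Path) -> Path:
    """Write cells x genes counts as matrix.mtx + genes.tsv + cells.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X)
    mmwrite(str(outdir / "matrix.mtx"), X, field="integer")
    genes = adata.var.reset_index()
    genes.columns = ["gene"] + list(genes.columns[1:])
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False, na_rep=NA)
    cells = adata.obs.reset_index(names="row_id")
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False, na_rep=NA)
    return outdir


def read_counts(indir: str | Path) -> ad.AnnData:
    """Read counts written by :func:`write_counts`.

    Explicit zero entries in the Matrix Market file are canonicalized away so
    a round trip is independent of how zeros were stored.
    """
    indir = Path(indir)
    try:
        X = mmread(str(indir / "matrix.mtx"))
    except Exception as exc:  # pragma: no cover - scipy raises various types
        raise ValueError(f"malformed Matrix Market file in {indir}: {exc}") from exc
    X = sp.csr_matrix(X)
    X.eliminate_zeros()
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", keep_default_na=False,
                        na_values=[NA])
    cells = pd.read_csv(indir / "cells.tsv", sep="\t", keep_default_na=False,
                        na_values=[NA])
    var = genes.set_index("gene")
    obs = cells.set_index("row_id")
    obs.index.name = None
    var.index.name = "gene"
    return ad.AnnData(X=X, obs=obs, var=var)


def write_table(df: pd.DataFrame, path: str | Path, stage: str | None = None,
                config_hash: str | None = None, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if stage is not None:
            tag = f"# stage={stage}"
            if config_hash is not None:
                tag += f" config={config_hash}"
            fh.write(tag + "\n")
        df.to_csv(fh, sep="\t", index=index, na_rep=NA)
    return path


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", keep_default_na=False,
                           na_values=[NA], index_col=index_col)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed TSV {path}: {exc}") from exc


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              description: str = "na") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
    return path


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT collection; duplicate members are dropped with a warning."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"malformed GMT line {lineno} in {path}: expected at least "
                    "3 tab-separated fields (name, description, members)"
                )
            name, _desc, *genes = fields
            seen, unique = set(), []
            for g in genes:
                if g in seen:
                    continue
                seen.add(g)
                unique.append(g)
            if len(unique) < len(genes):
                warnings.warn(f"GMT set {name!r}: duplicate members removed")
            sets[name] = unique
    return sets
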