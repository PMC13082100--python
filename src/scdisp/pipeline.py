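"""End-to-end orchestration: simulate -> moments -> differential -> ranks ->
enrichment (-> hybrid cis/trans), with a manifest and reproducible seeding.

Each stage reads its inputs from the run directory and writes TSV outputs
tagged with the producing stage and a config hash, so a run is resumable:
in incremental mode a stage whose outputs already exist is skipped, and
deleting an intermediate regenerates only the downstream stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from scdisp import io as sio
from scdisp.cistrans import aggregate_table, classify_table
from scdisp.differential import (
    dd_fixed_effect,
    dd_mixed,
    dd_two_sample,
    de_pseudobulk,
    empirical_fdr,
    permutation_null,
    quantile_normalize,
    variance_partition,
)
from scdisp.enrichment import fisher_enrichment, set_enrichment, sliding_window_proportion
from scdisp.moments import dispersion_matrix, estimate_moments
from scdisp.ranksets import (
    quintile_bins,
    rank_by_dispersion,
    shared_quintile_sets,
    stable_ranking,
)
from scdisp.simulate import SimConfig, simulate_annotations, simulate_counts, simulate_hybrid

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("scdisp")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Numeric defaults follow the study design: capture rate 0.4 (0.2 for the
    comparative design), raw-mean filter 0.07, the 1,000-cell inclusion rule,
    FDR 0.05, 50 sliding-window resamples, 15% rank-stability threshold and
    the 30%/70% cis classification thresholds.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    q: float = 0.4
    min_raw_mean: float = 0.07
    min_cells_per_group: int | None = 1000
    trend_degree: int = 2
    n_permutations: int = 100
    n_bootstrap: int = 200
    window: int = 500
    step: int = 50
    n_resamples: int = 50
    stability_fraction: float = 0.15
    cis_hi: float = 0.70
    cis_lo: float = 0.30
    fdr_cutoff: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        sim = SimConfig(**sim_raw)
        cfg = cls(sim=sim, **raw)
        if "seed" not in sim_raw:
            cfg.sim.seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["mean_range"] = list(d["sim"]["mean_range"])
        return d

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:10]


def _done(paths: list[Path]) -> bool:
    return all(p.exists() for p in paths)


def _sample_covariates(cells: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    grp = cells.groupby(keys, observed=True)
    out = pd.DataFrame({
        "n_cells": grp.size(),
        "n_features": grp["n_features"].mean(),
        "mito_frac": grp["mito_frac"].mean(),
    })
    return out


def run_pipeline(config: RunConfig, outdir: str | Path,
                 incremental: bool = False) -> Path:
    """Execute all stages in dependency order; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.hash
    manifest: dict = {"config": config.to_dict(), "config_hash": h, "stages": {}}
    hybrid = config.sim.n_species == 2

    def table(df, name, stage, index=False):
        path = sio.write_table(df, outdir / name, stage=stage, config_hash=h,
                               index=index)
        manifest["stages"].setdefault(stage, []).append(name)
        return path

    # ---- stage: simulate -------------------------------------------------
    counts_dir = outdir / "counts"
    sim_outputs = [counts_dir / "matrix.mtx", outdir / "truth_genes.tsv",
                   outdir / "features.tsv", outdir / "egenes.tsv",
                   outdir / "gene_sets.gmt"]
    if not (incremental and _done(sim_outputs)):
        log.info("stage simulate: %d genes, %d cell types", config.sim.n_genes,
                 config.sim.n_cell_types)
        adata, truth = (simulate_hybrid if hybrid else simulate_counts)(config.sim)
        features, egenes, gene_sets = simulate_annotations(truth, config.sim)
        sio.write_counts(adata, counts_dir)
        table(truth.genes.reset_index(), "truth_genes.tsv", "simulate")
        table(truth.groups, "truth_groups.tsv", "simulate")
        table(features.reset_index(), "features.tsv", "simulate")
        table(egenes, "egenes.tsv", "simulate")
        sio.write_gmt(gene_sets, outdir / "gene_sets.gmt")
        manifest["stages"].setdefault("simulate", []).append("counts/")
    else:
        log.info("stage simulate: outputs present, skipped")

    # ---- stage: moments --------------------------------------------------
    moments_path = outdir / "moments.tsv"
    group_keys = ["cell_type", "individual"]
    if hybrid:
        group_keys = ["species", "cell_type", "individual", "replicate"]
    if not (incremental and moments_path.exists()):
        adata = sio.read_counts(counts_dir)
        dip = adata[adata.obs["ploidy"] == "diploid"] if hybrid else adata
        moments = estimate_moments(
            dip, group_keys, q=config.q, min_raw_mean=config.min_raw_mean,
            min_cells_per_group=config.min_cells_per_group,
            trend_degree=config.trend_degree)
        n_pass = int(moments.groupby("gene")["pass_filter"].first().sum())
        log.info("stage moments: %d genes pass the %.2f raw-mean filter in all "
                 "groups", n_pass, config.min_raw_mean)
        table(moments, "moments.tsv", "moments")
    else:
        log.info("stage moments: outputs present, skipped")

    # ---- stage: differential --------------------------------------------
    dd_path = outdir / "dd_effects.tsv"
    de_path = outdir / "de_effects.tsv"
    vp_path = outdir / "variance_partition.tsv"
    if not (incremental and _done([dd_path, de_path, vp_path])):
        moments = sio.read_table(moments_path)
        moments.attrs["group_keys"] = group_keys
        disp = dispersion_matrix(moments, group_keys)
        disp = disp.dropna(axis=1, how="any")
        norm = quantile_normalize(disp)
        meta = norm.index.to_frame(index=False)
        meta.index = norm.index
        if hybrid:
            per_ct = []
            for ct, sub in norm.groupby(level="cell_type"):
                eff = dd_mixed(sub, meta.loc[sub.index, "species"],
                               meta.loc[sub.index, "individual"])
                eff["cell_type"] = ct
                per_ct.append(eff)
            dd_eff = pd.concat(per_ct, ignore_index=True)
        else:
            dd_eff = dd_fixed_effect(norm, meta["cell_type"])
            null = permutation_null(norm, meta["cell_type"],
                                    n_permutations=config.n_permutations,
                                    seed=config.seed % 2**31)
            dd_eff = empirical_fdr(dd_eff, null)
        dd_eff["significant"] = dd_eff["fdr"] < config.fdr_cutoff
        table(dd_eff, "dd_effects.tsv", "differential")

        adata = sio.read_counts(counts_dir)
        dip = adata[adata.obs["ploidy"] == "diploid"] if hybrid else adata
        if hybrid:
            de_eff = de_pseudobulk(dip, group_keys, condition="species",
                                   method="mixed", individual_key="individual")
        else:
            de_eff = de_pseudobulk(dip, group_keys, condition="cell_type")
        de_eff["significant"] = de_eff["fdr"] < config.fdr_cutoff
        table(de_eff, "de_effects.tsv", "differential")

        cells = sio.read_table(counts_dir / "cells.tsv")
        cov = _sample_covariates(cells[cells["ploidy"] == "diploid"]
                                 if hybrid else cells, group_keys)
        cov = cov.reindex(norm.index)
        vp = variance_partition(norm, meta["cell_type"], cov)
        log.info("stage differential: median cell-type variance fraction %.3f",
                 float(vp["cell_type"].median()))
        table(vp.reset_index(), "variance_partition.tsv", "differential")
    else:
        log.info("stage differential: outputs present, skipped")

    # ---- stage: ranks ----------------------------------------------------
    ranks_path = outdir / "ranks.tsv"
    if not (incremental and ranks_path.exists()):
        moments = sio.read_table(moments_path)
        ranks = rank_by_dispersion(moments)
        table(ranks.reset_index(), "ranks.tsv", "ranksets")
        sets = shared_quintile_sets(ranks)
        set_df = pd.DataFrame(
            [(label, g) for label, genes in sets.items() for g in sorted(genes)],
            columns=["set", "gene"])
        log.info("stage ranksets: %d shared-low, %d shared-high genes",
                 len(sets["shared_low"]), len(sets["shared_high"]))
        table(set_df, "shared_sets.tsv", "ranksets")
        stable = stable_ranking(ranks, config.stability_fraction)
        table(stable.reset_index(), "stable_ranking.tsv", "ranksets")
    else:
        log.info("stage ranksets: outputs present, skipped")

    # ---- stage: enrichment ----------------------------------------------
    enr_path = outdir / "egene_quintile_fisher.tsv"
    if not (incremental and enr_path.exists()):
        ranks = sio.read_table(ranks_path, index_col="gene")
        egenes = set(sio.read_table(outdir / "egenes.tsv")["gene"])
        stable = sio.read_table(outdir / "stable_ranking.tsv", index_col="gene")
        global_rank = stable["median_rank"].rank(method="average")
        eg = egenes & set(global_rank.index)
        w = min(config.window, max(len(global_rank) // 4, 1))
        profile = sliding_window_proportion(global_rank, eg, window=w,
                                            step=config.step,
                                            n_resamples=config.n_resamples,
                                            seed=config.seed % 2**31)
        table(profile, "egene_window.tsv", "enrichment")
        quint = quintile_bins(global_rank)
        universe = set(global_rank.index)
        rows = []
        for qb in range(1, 6):
            res = fisher_enrichment(set(quint.index[quint == qb]), eg, universe)
            rows.append((qb, *res.table.ravel(), res.odds_ratio, res.ci_low,
                         res.ci_high, res.p))
        fisher_df = pd.DataFrame(rows, columns=["quintile", "a", "b", "c", "d",
                                                "odds_ratio", "ci_low", "ci_high",
                                                "p"])
        table(fisher_df, "egene_quintile_fisher.tsv", "enrichment")

        sets_df = sio.read_table(outdir / "shared_sets.tsv")
        shared_low = set(sets_df.loc[sets_df["set"] == "shared_low", "gene"])
        collection = sio.read_gmt(outdir / "gene_sets.gmt")
        go = set_enrichment(shared_low & set(ranks.index), collection,
                            set(ranks.index))
        table(go.reset_index(), "set_enrichment.tsv", "enrichment")
    else:
        log.info("stage enrichment: outputs present, skipped")

    # ---- stage: cistrans (hybrid designs only) ---------------------------
    if hybrid:
        ct_path = outdir / "cistrans.tsv"
        if not (incremental and ct_path.exists()):
            adata = sio.read_counts(counts_dir)
            moments = sio.read_table(moments_path)
            moments.attrs["group_keys"] = group_keys
            disp = dispersion_matrix(moments, group_keys).dropna(axis=1, how="any")
            meta = disp.index.to_frame(index=False)
            meta.index = disp.index
            dip_parts, tet_parts = [], []
            for ct in sorted(meta["cell_type"].unique()):
                sub = disp.xs(ct, level="cell_type", drop_level=False)
                eff = dd_mixed(sub, meta.loc[sub.index, "species"],
                               meta.loc[sub.index, "individual"])
                eff["cell_type"] = ct
                dip_parts.append(eff)
                tet_mask = ((adata.obs["ploidy"] == "allotetraploid")
                            & (adata.obs["cell_type"] == ct)).to_numpy()
                tet = dd_two_sample(adata[tet_mask], q=config.q,
                                    n_bootstrap=config.n_bootstrap,
                                    seed=config.seed % 2**31,
                                    min_raw_mean=config.min_raw_mean,
                                    trend_degree=config.trend_degree)
                tet["effect"] = -tet["effect"]  # orient as B-vs-A to match diploid
                tet["cell_type"] = ct
                tet_parts.append(tet)
            dip = pd.concat(dip_parts, ignore_index=True)
            tet = pd.concat(tet_parts, ignore_index=True)
            dip["significant"] = dip["fdr"] < config.fdr_cutoff
            tet["significant"] = tet["fdr"] < config.fdr_cutoff
            calls = classify_table(dip, tet, hi=config.cis_hi, lo=config.cis_lo)
            agg = aggregate_table(calls).rename("aggregate_class")
            table(calls, "cistrans.tsv", "cistrans")
            table(agg.reset_index(), "cistrans_aggregate.tsv", "cistrans")
        else:
            log.info("stage cistrans: outputs present, skipped")

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
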