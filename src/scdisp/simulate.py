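"""Seeded synthetic single-cell datasets with known dispersion structure.

The generator emulates the data-generating process the dispersion estimator
assumes: per-gene true transcript counts are negative binomial with a
gene-specific variance offset relative to a global mean-variance trend, and
the measured UMI counts are a binomial subsample of the true counts at a
capture rate ``q``.  Cells are organised into groups defined by cell type x
individual (x species x replicate), and an allotetraploid mode emits paired
allele-resolved rows per cell whose allelic dispersion difference is a
configurable cis fraction of the diploid interspecies difference.

Every draw flows from a single master seed through named substreams, so the
count matrix and the annotation tables can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_counts",
    "simulate_hybrid",
    "simulate_annotations",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic data generator.

    The mean-variance trend is on the natural-log scale:
    ``log Var = trend_intercept + trend_slope * log mean + delta`` with
    per-gene offsets ``delta ~ N(0, dispersion_offset_sd^2)`` truncated at
    three standard deviations.  Defaults guarantee overdispersion
    (variance > mean) for every gene given the default mean range.
    """

    n_genes: int = 3000
    n_cell_types: int = 6
    n_individuals_per_species: int = 3
    n_species: int = 1
    n_replicates: int = 1
    cells_per_group: int = 2000
    capture_rate: float = 0.4
    trend_slope: float = 1.5
    trend_intercept: float = 0.5
    dispersion_offset_sd: float = 0.3
    mean_range: tuple[float, float] = (3.0, 100.0)
    dd_fraction: float = 0.1
    dd_effect: float = 1.0
    de_fraction: float = 0.0
    de_effect: float = 0.69314718056  # natural-log fold change (2-fold)
    cis_fraction_distribution: float | str | Sequence[float] = "uniform"
    egene_logodds_per_rank: float = 2.0
    egene_base_rate: float = 0.2
    feature_assoc: float = 1.0
    store_true_counts: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_cell_types", "n_individuals_per_species",
                     "n_replicates", "cells_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_species not in (1, 2):
            raise ValueError(f"n_species must be 1 or 2, got {self.n_species}")
        if not 0.0 < self.capture_rate <= 1.0:
            raise ValueError(f"capture_rate must lie in (0, 1], got {self.capture_rate}")
        if not 0.0 <= self.dd_fraction <= 1.0:
            raise ValueError(f"dd_fraction must lie in [0, 1], got {self.dd_fraction}")
        if self.dispersion_offset_sd < 0:
            raise ValueError("dispersion_offset_sd must be >= 0")
        if not (0 < self.mean_range[0] <= self.mean_range[1]):
            raise ValueError(f"invalid mean_range {self.mean_range}")


@dataclass
class SimTruth:
    """Ground-truth generative parameters for a simulated dataset.

    ``genes`` is indexed by gene id and carries the baseline dispersion
    offset, DD/DE flags, the per-gene cis fraction and the eGene flag (the
    latter filled in by :func:`simulate_annotations`).  ``groups`` is a long
    table with one row per gene x group holding the realised mean and
    dispersion offset actually used to draw counts.
    """

    genes: pd.DataFrame
    groups: pd.DataFrame
    config: SimConfig

    def group_params(self, **labels: str) -> pd.DataFrame:
        sub = self.groups
        for key, val in labels.items():
            sub = sub[sub[key] == val]
        return sub.set_index("gene")


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(4)
    names = ("counts", "hybrid", "annotations", "covariates")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _gene_params(config: SimConfig, rng: np.random.Generator):
    """Baseline per-gene means and truncated-normal dispersion offsets."""
    lo, hi = config.mean_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))
    sd = config.dispersion_offset_sd
    if sd == 0:
        delta = np.zeros(config.n_genes)
    else:
        delta = rng.normal(0.0, sd, size=config.n_genes)
        delta = np.clip(delta, -3 * sd, 3 * sd)
    return mu, delta


def _nb_variance(config: SimConfig, mu: np.ndarray, delta: np.ndarray) -> np.ndarray:
    var = np.exp(config.trend_intercept + config.trend_slope * np.log(mu) + delta)
    bad = var < mu
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValueError(
            "config implies underdispersion (variance < mean) for "
            f"{int(bad.sum())} genes; first offender: mean={mu[i]:.4g}, "
            f"variance={var[i]:.4g}. Raise trend_intercept/trend_slope, narrow "
            "dispersion_offset_sd, or raise the lower end of mean_range."
        )
    return var


def _draw_group_counts(rng: np.random.Generator, mu: np.ndarray, var: np.ndarray,
                       n_cells: int) -> np.ndarray:
    """NB counts for one group: shape (n_cells, n_genes)."""
    out = np.empty((n_cells, mu.size), dtype=np.int64)
    poisson = var <= mu * (1 + 1e-12)
    if np.any(poisson):
        out[:, poisson] = rng.poisson(mu[poisson], size=(n_cells, int(poisson.sum())))
    nb = ~poisson
    if np.any(nb):
        m, v = mu[nb], var[nb]
        r = m**2 / (v - m)
        p = r / (r + m)
        out[:, nb] = rng.negative_binomial(r, p, size=(n_cells, int(nb.sum())))
    return out


def _thin(rng: np.random.Generator, true_counts: np.ndarray, q: float) -> np.ndarray:
    if q >= 1.0:
        return true_counts
    return rng.binomial(true_counts, q)


def _diploid_groups(config: SimConfig) -> pd.DataFrame:
    species = [chr(ord("A") + i) for i in range(config.n_species)]
    rows = []
    for sp in species:
        for ind in range(config.n_individuals_per_species):
            for ct in range(config.n_cell_types):
                for rep in range(config.n_replicates):
                    rows.append({
                        "species": sp,
                        "individual": f"{sp}{ind + 1}",
                        "cell_type": f"ct{ct + 1}",
                        "replicate": f"r{rep + 1}",
                    })
    return pd.DataFrame(rows)


def _assign_effects(config: SimConfig, rng: np.random.Generator):
    """Pick DD/DE genes and the condition carrying their effect.

    With one species the effect is placed in one randomly chosen cell type;
    with two species it is placed in every group of species B, so the DD/DE
    contrast of interest is the interspecies one.
    """
    g = config.n_genes
    n_dd = int(round(config.dd_fraction * g))
    n_de = int(round(config.de_fraction * g))
    dd = np.zeros(g, dtype=bool)
    de = np.zeros(g, dtype=bool)
    dd[rng.choice(g, size=n_dd, replace=False)] = True
    de[rng.choice(g, size=n_de, replace=False)] = True
    dd_ct = rng.integers(1, config.n_cell_types + 1, size=g)  # used when n_species == 1
    de_ct = rng.integers(1, config.n_cell_types + 1, size=g)
    return dd, de, dd_ct, de_ct


def _cis_fractions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    dist = config.cis_fraction_distribution
    if isinstance(dist, str):
        if dist != "uniform":
            raise ValueError(f"unknown cis_fraction_distribution {dist!r}")
        c = rng.uniform(0.0, 1.0, size=config.n_genes)
    elif np.isscalar(dist):
        c = np.full(config.n_genes, float(dist))
    else:
        c = np.asarray(dist, dtype=float)
        if c.shape != (config.n_genes,):
            raise ValueError("cis fraction array must have length n_genes")
    if np.any((c < 0) | (c > 1)):
        raise ValueError("cis fractions must lie in [0, 1]")
    return c


def _group_effects(config: SimConfig, group: pd.Series, gene_idx: np.ndarray,
                   dd: np.ndarray, de: np.ndarray,
                   dd_ct: np.ndarray, de_ct: np.ndarray):
    """Per-gene (log-mean shift, dispersion shift) for one sample group."""
    dmu = np.zeros(config.n_genes)
    ddisp = np.zeros(config.n_genes)
    if config.n_species == 1:
        ct = int(group["cell_type"][2:])
        ddisp[dd & (dd_ct == ct)] = config.dd_effect
        dmu[de & (de_ct == ct)] = config.de_effect
    else:
        if group["species"] == "B":
            ddisp[dd] = config.dd_effect
            dmu[de] = config.de_effect
    return dmu, ddisp


def _sparse_block(dense: np.ndarray) -> sp.csr_matrix:
    return sp.csr_matrix(dense.astype(np.int32))


def _build_adata(blocks, obs_rows, gene_ids, config, rng_cov, layers_true=None):
    X = sp.vstack(blocks, format="csr")
    obs = pd.DataFrame(obs_rows)
    obs.index = obs["cell_id"].values
    obs.index.name = None
    var = pd.DataFrame(index=pd.Index(gene_ids, name="gene"))
    adata = ad.AnnData(X=X, obs=obs, var=var)
    if layers_true is not None:
        adata.layers["true"] = sp.vstack(layers_true, format="csr")
    # technical covariates: feature count from the matrix, mito fraction
    # independent of everything (makes the variance-partition null testable)
    adata.obs["n_features"] = np.asarray((X > 0).sum(axis=1)).ravel()
    adata.obs["mito_frac"] = rng_cov.beta(2.0, 20.0, size=adata.n_obs)
    return adata


def simulate_counts(config: SimConfig) -> tuple[ad.AnnData, SimTruth]:
    """Draw a grouped UMI count matrix and its generative ground truth.

    True counts per gene/group are negative binomial with mean ``mu_gs`` and
    variance ``exp(trend(log mu_gs) + delta_gs)``; observed counts are a
    binomial thinning at ``config.capture_rate``.  Identical config and seed
    give bit-identical output.
    """
    config.validate()
    rngs = _substreams(config.seed)
    rng = rngs["counts"]
    mu0, delta0 = _gene_params(config, rng)
    dd, de, dd_ct, de_ct = _assign_effects(config, rng)
    cis = _cis_fractions(config, rng)
    gene_ids = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    groups = _diploid_groups(config)

    blocks, true_blocks, obs_rows, group_rows = [], [], [], []
    cell_counter = 0
    for _, grp in groups.iterrows():
        dmu, ddisp = _group_effects(config, grp, np.arange(config.n_genes),
                                    dd, de, dd_ct, de_ct)
        mu = mu0 * np.exp(dmu)
        delta = delta0 + ddisp
        var = _nb_variance(config, mu, delta)
        true = _draw_group_counts(rng, mu, var, config.cells_per_group)
        obs = _thin(rng, true, config.capture_rate)
        blocks.append(_sparse_block(obs))
        if config.store_true_counts:
            true_blocks.append(_sparse_block(true))
        for _ in range(config.cells_per_group):
            cell_counter += 1
            obs_rows.append({"cell_id": f"c{cell_counter:07d}", "ploidy": "diploid",
                             "genome": grp["species"], **grp.to_dict()})
        gr = pd.DataFrame({
            "gene": gene_ids, **{k: grp[k] for k in grp.index},
            "mu": mu, "delta": delta, "variance": var,
        })
        group_rows.append(gr)

    adata = _build_adata(blocks, obs_rows, gene_ids, config, rngs["covariates"],
                         true_blocks if config.store_true_counts else None)
    genes = pd.DataFrame({
        "gene": gene_ids, "mu0": mu0, "delta0": delta0,
        "dd": dd, "de": de, "dd_cell_type": [f"ct{c}" for c in dd_ct],
        "de_cell_type": [f"ct{c}" for c in de_ct],
        "cis_fraction": cis, "egene": pd.NA,
    }).set_index("gene")
    truth = SimTruth(genes=genes, groups=pd.concat(group_rows, ignore_index=True),
                     config=config)
    return adata, truth


def simulate_hybrid(config: SimConfig) -> tuple[ad.AnnData, SimTruth]:
    """Diploid groups for two species plus paired allele-resolved tetraploid cells.

    Allotetraploid cells are represented as two rows per cell (genome A and
    genome B sharing a cell identifier).  For DD genes the allelic dispersion
    difference equals ``cis_fraction * dd_effect``, i.e. the cis share of the
    diploid interspecies difference, on the same log-variance scale.
    """
    config.validate()
    if config.n_species != 2:
        raise ValueError("simulate_hybrid requires n_species = 2")
    adata_dip, truth = simulate_counts(config)
    rngs = _substreams(config.seed)
    rng = rngs["hybrid"]

    mu0 = truth.genes["mu0"].to_numpy()
    delta0 = truth.genes["delta0"].to_numpy()
    dd = truth.genes["dd"].to_numpy()
    de = truth.genes["de"].to_numpy()
    cis = truth.genes["cis_fraction"].to_numpy()
    gene_ids = truth.genes.index.tolist()

    blocks, obs_rows, group_rows = [], [], []
    cell_counter = 0
    for ct in range(config.n_cell_types):
        for rep in range(config.n_replicates):
            base = {"cell_type": f"ct{ct + 1}", "replicate": f"r{rep + 1}",
                    "individual": "tetra", "ploidy": "allotetraploid"}
            # allele B carries the cis share of the species-B effect
            for genome in ("A", "B"):
                dmu = np.zeros(config.n_genes)
                ddisp = np.zeros(config.n_genes)
                if genome == "B":
                    ddisp[dd] = cis[dd] * config.dd_effect
                    dmu[de] = cis[de] * config.de_effect
                mu = mu0 * np.exp(dmu)
                delta = delta0 + ddisp
                var = _nb_variance(config, mu, delta)
                true = _draw_group_counts(rng, mu, var, config.cells_per_group)
                obs = _thin(rng, true, config.capture_rate)
                blocks.append(_sparse_block(obs))
                for i in range(config.cells_per_group):
                    obs_rows.append({
                        "cell_id": f"t{cell_counter + i + 1:07d}",
                        "genome": genome, "species": genome, **base,
                    })
                gr = pd.DataFrame({
                    "gene": gene_ids, "species": genome, "individual": "tetra",
                    "cell_type": base["cell_type"], "replicate": base["replicate"],
                    "mu": mu, "delta": delta, "variance": var,
                })
                group_rows.append(gr)
            cell_counter += config.cells_per_group

    X_tet = sp.vstack(blocks, format="csr")
    obs_tet = pd.DataFrame(obs_rows)
    counts_per_id = obs_tet["cell_id"].value_counts()
    if not (counts_per_id == 2).all():
        raise ValueError("allotetraploid pairing broken: each cell id needs exactly two rows")
    obs_tet.index = (obs_tet["cell_id"] + "_" + obs_tet["genome"]).values

    X = sp.vstack([adata_dip.X, X_tet], format="csr")
    obs = pd.concat([adata_dip.obs.drop(columns=["n_features", "mito_frac"]), obs_tet])
    adata = ad.AnnData(X=X, obs=obs, var=adata_dip.var.copy())
    adata.obs["n_features"] = np.asarray((X > 0).sum(axis=1)).ravel()
    adata.obs["mito_frac"] = rngs["covariates"].beta(2.0, 20.0, size=adata.n_obs)

    truth.groups = pd.concat([truth.groups.assign(ploidy="diploid"),
                              pd.concat(group_rows, ignore_index=True).assign(
                                  ploidy="allotetraploid")],
                             ignore_index=True)
    return adata, truth


def simulate_annotations(truth: SimTruth, config: SimConfig | None = None,
                         n_gene_sets: int = 20,
                         set_size_range: tuple[int, int] = (30, 200),
                         ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Per-gene feature table, eGene list and a GMT-style gene-set collection.

    eGene status is Bernoulli with log-odds linear in the normalised true
    dispersion rank (0 = lowest dispersion), with slope
    ``egene_logodds_per_rank`` over the full rank range.  Feature columns are
    drawn with associations to dispersion scaled by ``feature_assoc`` in the
    directions the biology suggests (TATA promoters, TSS count, introns and
    enhancer length increase with dispersion; constraint tightens, i.e. LOEUF
    falls, as dispersion falls).
    """
    if config is None:
        config = truth.config
    rng = _substreams(config.seed)["annotations"]
    genes = truth.genes.index.to_numpy()
    g = genes.size
    # normalised dispersion rank in [0, 1], 0 = lowest true dispersion
    order = np.argsort(np.argsort(truth.genes["delta0"].to_numpy(), kind="stable"))
    r = order / max(g - 1, 1)

    logit0 = np.log(config.egene_base_rate / (1 - config.egene_base_rate))
    eta = logit0 + config.egene_logodds_per_rank * (r - 0.5)
    p_egene = 1.0 / (1.0 + np.exp(-eta))
    egene = rng.uniform(size=g) < p_egene
    truth.genes["egene"] = egene

    a = config.feature_assoc
    features = pd.DataFrame({
        "gene": genes,
        "tata": (rng.uniform(size=g)
                 < 1.0 / (1.0 + np.exp(-(-1.5 + 2.0 * a * (r - 0.5))))).astype(int),
        "tss_count": 1 + rng.poisson(np.exp(0.5 + a * (r - 0.5))),
        "intron_count": rng.poisson(np.exp(1.8 + a * (r - 0.5))),
        "enhancer_length": np.exp(rng.normal(9.0 + a * (r - 0.5), 1.0)),
        "loeuf": np.clip(rng.normal(1.0 + 0.4 * a * (r - 0.5), 0.25), 0.01, None),
        "pct_identity": np.clip(rng.normal(99.2 - 0.3 * a * (r - 0.5), 0.3), None, 100.0),
    }).set_index("gene")

    egene_list = pd.DataFrame({"gene": genes[egene]})

    lo, hi = set_size_range
    gene_sets: dict[str, list[str]] = {}
    for k in range(n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=min(size, g), replace=False)
        gene_sets[f"SET_{k + 1:03d}"] = sorted(members.tolist())
    return features, egene_list, gene_sets
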