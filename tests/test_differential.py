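"""Differential dispersion/expression machinery and its calibration."""

import math

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats as st

from scdisp.differential import (
    PermutationNull,
    dd_fixed_effect,
    dd_mixed,
    dd_two_sample,
    de_allele_paired,
    de_pseudobulk,
    empirical_fdr,
    log_cpm,
    permutation_null,
    pseudobulk,
    quantile_normalize,
    variance_partition,
)

# ---------------------------------------------------------------------------
# quantile normalization


def test_qn_hand_computed_example():
    df = pd.DataFrame([[1.0, 2.0, 3.0], [4.0, 6.0, 8.0]],
                      index=["s1", "s2"], columns=list("abc"))
    out = quantile_normalize(df)
    expected = np.array([[2.5, 4.0, 5.5], [2.5, 4.0, 5.5]])
    assert np.allclose(out.to_numpy(), expected)


def test_qn_identical_sorted_values_is_identity():
    df = pd.DataFrame([[3.0, 1.0, 2.0], [1.0, 2.0, 3.0]])
    out = quantile_normalize(df)
    assert np.allclose(out.to_numpy(), df.to_numpy())


def test_qn_equalizes_multisets(rng):
    df = pd.DataFrame(rng.normal(size=(5, 40)))
    out = quantile_normalize(df).to_numpy()
    ref = np.sort(out[0])
    for row in out[1:]:
        assert np.allclose(np.sort(row), ref)
    # ranks preserved within each sample
    for orig, normed in zip(df.to_numpy(), out):
        assert np.array_equal(np.argsort(orig), np.argsort(normed))


def test_qn_single_sample_warns():
    with pytest.warns(UserWarning, match="single sample"):
        out = quantile_normalize(pd.DataFrame([[1.0, 2.0]]))
    assert np.allclose(out.to_numpy(), [[1.0, 2.0]])


# ---------------------------------------------------------------------------
# fixed-effect model + permutation FDR


def _null_matrix(rng, n_samples=18, n_genes=300):
    idx = pd.Index([f"s{i}" for i in range(n_samples)])
    design = pd.Series([f"ct{i % 6 + 1}" for i in range(n_samples)], index=idx)
    y = pd.DataFrame(rng.normal(size=(n_samples, n_genes)), index=idx,
                     columns=[f"g{j}" for j in range(n_genes)])
    return y, design


def test_fixed_effect_zero_for_constant_gene(rng):
    y, design = _null_matrix(rng)
    y["g0"] = 1.7
    res = dd_fixed_effect(y, design)
    assert (res.loc[res["gene"] == "g0", "effect"] == 0).all()


def test_fixed_effect_row_permutation_invariance(rng):
    y, design = _null_matrix(rng)
    perm = rng.permutation(len(y))
    res1 = dd_fixed_effect(y, design).sort_values(["gene", "contrast"])
    res2 = dd_fixed_effect(y.iloc[perm], design.iloc[perm]).sort_values(
        ["gene", "contrast"])
    assert np.allclose(res1["statistic"].to_numpy(), res2["statistic"].to_numpy())


def test_fixed_effect_null_pvalues_uniform(rng):
    y, design = _null_matrix(rng, n_genes=3000)
    res = dd_fixed_effect(y, design)
    p = res[res["contrast"] == res["contrast"].iloc[0]]["p"].to_numpy()
    assert st.kstest(p, "uniform").pvalue > 0.01


def test_fixed_effect_single_sample_level_dropped(rng):
    y, design = _null_matrix(rng, n_samples=13)
    design.iloc[-1] = "lonely"
    with pytest.warns(UserWarning, match="single sample"):
        res = dd_fixed_effect(y, design)
    assert not any("lonely" in c for c in res["contrast"].unique())


def test_empirical_p_add_one_formula():
    obs = pd.DataFrame({"gene": ["g1"], "contrast": ["a_vs_b"],
                        "statistic": [10.0], "p": [0.001]})
    null = PermutationNull(statistics=np.arange(10, dtype=float) / 10,
                           n_permutations=10, seed=0)
    out = empirical_fdr(obs, null)
    assert out["empirical_p"].iloc[0] == pytest.approx(1 / 11)
    obs_low = obs.assign(statistic=[0.0])  # at or below every pooled null
    out_low = empirical_fdr(obs_low, null)
    assert out_low["empirical_p"].iloc[0] == pytest.approx(1.0)


def test_empirical_fdr_bh_monotone(rng):
    y, design = _null_matrix(rng, n_genes=500)
    res = dd_fixed_effect(y, design)
    null = permutation_null(y, design, n_permutations=5, seed=3)
    out = empirical_fdr(res, null)
    for _, sub in out.groupby("contrast"):
        sub = sub.sort_values("empirical_p")
        assert (np.diff(sub["fdr"].to_numpy()) >= -1e-12).all()


def test_permutation_preserves_group_sizes(rng):
    y, design = _null_matrix(rng, n_genes=20)
    null = permutation_null(y, design, n_permutations=3, seed=1)
    n_contrasts = 15  # 6 cell types -> C(6,2) pairwise contrasts
    assert null.statistics.size == 3 * n_contrasts * 20


# ---------------------------------------------------------------------------
# mixed model


def _species_design(n_ind=3, n_rep=2):
    rows = [(sp_, f"{sp_}{i+1}", f"r{r+1}") for sp_ in "AB"
            for i in range(n_ind) for r in range(n_rep)]
    meta = pd.DataFrame(rows, columns=["species", "individual", "replicate"])
    meta.index = [f"s{i}" for i in range(len(meta))]
    return meta


def test_mixed_null_effect_near_zero(rng):
    meta = _species_design()
    y = pd.DataFrame(rng.normal(size=(len(meta), 40)), index=meta.index)
    res = dd_mixed(y, meta["species"], meta["individual"])
    assert abs(res["effect"].mean()) < 0.2
    assert (res["p"] > 0.01).mean() > 0.8


def test_mixed_recovers_species_shift_sign(rng):
    meta = _species_design()
    shift = (meta["species"] == "B").to_numpy(dtype=float)[:, None] * 2.0
    y = pd.DataFrame(rng.normal(size=(len(meta), 60)) + shift, index=meta.index)
    res = dd_mixed(y, meta["species"], meta["individual"])
    assert (res["effect"] > 0).mean() > 0.95


def test_mixed_duplication_invariance(rng):
    meta = _species_design()
    y = pd.DataFrame(rng.normal(size=(len(meta), 10)), index=meta.index)
    res1 = dd_mixed(y, meta["species"], meta["individual"])
    y2 = pd.concat([y, y.set_axis([f"{i}_dup" for i in y.index])])
    meta2 = pd.concat([meta, meta.set_axis([f"{i}_dup" for i in meta.index])])
    res2 = dd_mixed(y2, meta2["species"], meta2["individual"])
    assert np.allclose(res1["effect"].to_numpy(), res2["effect"].to_numpy(),
                       atol=1e-6)


def test_mixed_requires_two_species(rng):
    meta = _species_design()
    meta["species"] = "A"
    y = pd.DataFrame(rng.normal(size=(len(meta), 5)), index=meta.index)
    with pytest.raises(ValueError, match="two species"):
        dd_mixed(y, meta["species"], meta["individual"])


# ---------------------------------------------------------------------------
# allotetraploid two-sample test


def _tetra_adata(Xa, Xb):
    n, g = Xa.shape
    obs = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)] * 2,
        "genome": ["A"] * n + ["B"] * n,
        "ploidy": "allotetraploid",
    })
    obs.index = obs["cell_id"] + "_" + obs["genome"]
    var = pd.DataFrame(index=[f"g{j}" for j in range(g)])
    X = sp.csr_matrix(np.vstack([Xa, Xb]))
    return ad.AnnData(X=X, obs=obs, var=var)


def test_two_sample_identical_alleles_zero_effect(rng):
    X = rng.poisson(8.0, size=(400, 80))
    adata = _tetra_adata(X, X)
    res = dd_two_sample(adata, q=0.5, n_bootstrap=100, seed=0, min_raw_mean=0.0)
    assert np.allclose(res["effect"].to_numpy(), 0.0, atol=1e-12)
    assert (res["p"] > 0.9).all()


def test_two_sample_bootstrap_se_positive_when_alleles_differ(rng):
    Xa = rng.poisson(8.0, size=(400, 80))
    Xb = rng.poisson(8.0, size=(400, 80))
    adata = _tetra_adata(Xa, Xb)
    res = dd_two_sample(adata, q=0.5, n_bootstrap=100, seed=0, min_raw_mean=0.0)
    assert (res["se"] > 0).all()


def test_two_sample_rejects_unpaired(rng):
    X = rng.poisson(8.0, size=(50, 20))
    adata = _tetra_adata(X, X)
    adata.obs.loc[adata.obs.index[0], "cell_id"] = "mismatch"
    with pytest.raises(ValueError, match="unpaired"):
        dd_two_sample(adata, q=0.5, n_bootstrap=100)


def test_two_sample_requires_enough_bootstraps(rng):
    X = rng.poisson(8.0, size=(50, 20))
    with pytest.raises(ValueError, match="bootstrap"):
        dd_two_sample(_tetra_adata(X, X), q=0.5, n_bootstrap=10)


# ---------------------------------------------------------------------------
# pseudobulk DE


def test_pseudobulk_exact_column_sums(small_sim):
    adata, _, _ = small_sim
    pb = pseudobulk(adata, ["cell_type", "individual"])
    key = ("ct1", "A1")
    mask = ((adata.obs["cell_type"] == "ct1")
            & (adata.obs["individual"] == "A1")).to_numpy()
    expected = np.asarray(adata.X[mask].sum(axis=0)).ravel()
    assert np.array_equal(pb.loc[key].to_numpy(), expected)


def test_logcpm_scale_invariance(rng):
    counts = pd.DataFrame(rng.poisson(20.0, size=(6, 30)))
    assert np.allclose(log_cpm(counts).to_numpy(), log_cpm(2 * counts).to_numpy())


def test_de_pseudobulk_detects_mean_shift():
    from scdisp import SimConfig, simulate_counts

    cfg = SimConfig(n_genes=200, n_cell_types=2, n_individuals_per_species=3,
                    cells_per_group=300, dd_fraction=0.0, de_fraction=0.3,
                    de_effect=np.log(2), seed=5)
    adata, truth = simulate_counts(cfg)
    res = de_pseudobulk(adata, ["cell_type", "individual"], condition="cell_type")
    de_genes = truth.genes[truth.genes["de"]]
    merged = res.merge(de_genes.reset_index()[["gene", "de_cell_type"]], on="gene")
    # orient each contrast so positive effect means higher in the affected type
    eff = merged["effect"].to_numpy().copy()
    flip = merged.apply(lambda r: r["contrast"].startswith(r["de_cell_type"]),
                        axis=1).to_numpy()
    eff = np.where(flip, eff, -eff)
    assert (eff > 0).mean() > 0.95


def test_allele_paired_all_positive_exact_p(rng):
    n = 20
    Xa = rng.poisson(5.0, size=(n, 3)) + 5
    Xb = np.maximum(Xa - rng.integers(1, 4, size=Xa.shape), 0)
    adata = _tetra_adata(Xa, Xb)
    res = de_allele_paired(adata)
    # every pair strictly positive -> two-sided exact p = 2 * 2^-20
    assert np.allclose(res["p"].to_numpy(), 2 * 2.0**-n, rtol=1e-10)


def test_allele_paired_identical_missing_and_swap_symmetry(rng):
    n = 30
    Xa = rng.poisson(5.0, size=(n, 4))
    Xb = Xa.copy()
    Xb[:, 1:] = rng.poisson(5.0, size=(n, 3))
    res_ab = de_allele_paired(_tetra_adata(Xa, Xb))
    assert np.isnan(res_ab.loc[res_ab["gene"] == "g0", "p"].iloc[0])
    res_ba = de_allele_paired(_tetra_adata(Xb, Xa))
    assert np.allclose(res_ab["p"].to_numpy()[1:], res_ba["p"].to_numpy()[1:])
    assert np.allclose(res_ab["effect"].to_numpy()[1:],
                       -res_ba["effect"].to_numpy()[1:])


# ---------------------------------------------------------------------------
# variance partition


def _vp_inputs(rng, n_genes=30, effect=None):
    meta = pd.DataFrame({
        "cell_type": [f"ct{i % 6 + 1}" for i in range(18)],
        "n_features": rng.normal(2000, 100, size=18),
        "mito_frac": rng.beta(2, 20, size=18),
    }, index=[f"s{i}" for i in range(18)])
    y = pd.DataFrame(rng.normal(size=(18, n_genes)), index=meta.index)
    if effect is not None:
        ct_vals = {f"ct{i + 1}": v for i, v in enumerate(effect)}
        y = y * 0.01 + np.array([ct_vals[c] for c in meta["cell_type"]])[:, None]
    return y, meta


def test_variance_partition_pure_cell_type_signal(rng):
    y, meta = _vp_inputs(rng, n_genes=10, effect=[0, 2, 4, 6, 8, 10])
    vp = variance_partition(y, meta["cell_type"],
                            meta[["n_features", "mito_frac"]])
    ok = vp[~vp["failed"]]
    assert (ok["cell_type"] > 0.9).all()
    assert (ok["residual"] < 0.05).all()


def test_variance_partition_fractions_sum_to_one(rng):
    y, meta = _vp_inputs(rng, n_genes=40)
    vp = variance_partition(y, meta["cell_type"],
                            meta[["n_features", "mito_frac"]])
    ok = vp[~vp["failed"]]
    total = ok[["cell_type", "n_features", "mito_frac", "residual"]].sum(axis=1)
    assert np.allclose(total, 1.0)
    assert ((ok[["cell_type", "n_features", "mito_frac", "residual"]] >= -1e-9)
            .all().all())


def test_variance_partition_null_cell_type_fraction_small(rng):
    y, meta = _vp_inputs(rng, n_genes=200)
    vp = variance_partition(y, meta["cell_type"],
                            meta[["n_features", "mito_frac"]])
    assert vp.loc[~vp["failed"], "cell_type"].median() < 0.1
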