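"""Simulate grouped UMI counts and estimate capture-corrected dispersion.

Generates a small dataset (negative-binomial true counts, binomial capture),
estimates per-group moments, and shows that the dispersion estimate recovers
the generative offsets while staying uncorrelated with mean expression.
"""

from scdisp import SimConfig, estimate_moments, simulate_counts, spearman

cfg = SimConfig(n_genes=1000, n_cell_types=2, n_individuals_per_species=2,
                cells_per_group=1000, dd_fraction=0.0, seed=0)
adata, truth = simulate_counts(cfg)
print(f"simulated {adata.n_obs} cells x {adata.n_vars} genes "
      f"(capture rate q = {cfg.capture_rate})")

moments = estimate_moments(adata, ["cell_type", "individual"],
                           q=cfg.capture_rate, min_cells_per_group=None)
sub = moments[(moments["cell_type"] == "ct1")
              & (moments["individual"] == "A1")].set_index("gene")
sub = sub[sub["dispersion"].notna()]
truth_params = truth.group_params(cell_type="ct1", individual="A1").loc[sub.index]

rho_truth, _ = spearman(sub["dispersion"], truth_params["delta"])
rho_mean, _ = spearman(sub["dispersion"], sub["mean"])
print(f"Spearman(dispersion, true offset) = {rho_truth:.3f}  "
      "(close to 1: the estimator ranks genes by their generative offsets)")
print(f"Spearman(dispersion, mean)        = {rho_mean:+.3f}  "
      "(close to 0: residualization removed the mean-variance trend)")
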