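import numpy as np
import pytest

from scdisp import SimConfig, simulate_counts, simulate_hybrid


@pytest.fixture(scope="session")
def small_sim():
    """Small single-species dataset: 3 cell types x 2 individuals, 400 cells/group."""
    cfg = SimConfig(n_genes=300, n_cell_types=3, n_individuals_per_species=2,
                    cells_per_group=400, dd_fraction=0.2, dd_effect=1.2, seed=42)
    adata, truth = simulate_counts(cfg)
    return adata, truth, cfg


@pytest.fixture(scope="session")
def hybrid_sim():
    """Two-species + allotetraploid dataset with intermediate cis fractions."""
    cfg = SimConfig(n_genes=200, n_cell_types=1, n_individuals_per_species=3,
                    n_species=2, n_replicates=2, cells_per_group=400,
                    capture_rate=0.2, dd_fraction=0.4, dd_effect=1.5,
                    cis_fraction_distribution="uniform", seed=21)
    adata, truth = simulate_hybrid(cfg)
    return adata, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
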