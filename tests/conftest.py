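import numpy as np
import pytest

from pdac_clonevo import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort shared across test modules: 800 genes, 19 samples,
    60 cells/sample, planted 4-program structure and clone CNVs."""
    cfg = SimulationConfig(
        seed=7,
        n_genes=800,
        n_cells_per_sample=60,
        samples_per_origin={"Pn": 3, "Pm0": 4, "Pm1": 8, "Lm": 4},
        n_signature_genes_per_program=30,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cnv(small_cohort):
    """CNV matrix of the shared cohort's ductal cells, Pn reference."""
    from pdac_clonevo import infer_cnv

    adata = small_cohort.counts
    obs = adata.obs
    ductal = obs["compartment"] == "ductal"
    ref = adata.obs_names[(obs["origin"] == "Pn") & ductal]
    sub = adata[ductal]
    cnv = infer_cnv(sub, small_cohort.annotation, ref, window=51, clip=3.0)
    return cnv, sub.obs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
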