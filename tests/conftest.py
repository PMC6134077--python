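import numpy as np
import pytest

from zwscan.simdata import SimConfig, simulate_population, simulate_ztw_cohort


@pytest.fixture(scope="session")
def small_population():
    """A small 9-family population with family LD (scaled marker panel)."""
    cfg = SimConfig(marker_scale=0.02, n_offspring_per_family=24, seed=11)
    geno, pheno, truth = simulate_population(cfg)
    return cfg, geno, pheno, truth


@pytest.fixture(scope="session")
def ztw_cohort_171():
    """The study-sized scan cohort: 171 Z^T W genetic females, ~1/10 panel."""
    cfg = SimConfig(marker_scale=0.1, seed=1)
    geno, pheno, truth = simulate_ztw_cohort(171, cfg)
    return cfg, geno, pheno, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
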