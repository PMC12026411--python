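import numpy as np
import pytest

from scetr.synthetic_data import (
    SimulationConfig,
    default_effect_table,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    cfg = SimulationConfig(
        seed=7,
        n_samples_per_cohort=150,
        n_cohorts=2,
        n_cell_types=3,
        n_tr_loci=6,
        n_snv_loci=18,
        n_genes=6,
        n_cpg_sites=4,
    )
    cfg.effect_table.extend(default_effect_table(cfg, beta=0.5))
    return cfg


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
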