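import numpy as np
import pytest

from tribescan.synthetic_data import SimConfig, simulate_panel_and_cohort


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_snps=300, n_samples_study=15, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_panel_and_cohort(small_cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
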