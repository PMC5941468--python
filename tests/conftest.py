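import numpy as np
import pytest

from pubmeth.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_female=10,
        n_male=8,
        n_probes=400,
        n_genes=120,
        n_dmp_female=30,
        n_dmp_male=10,
        n_dmp_shared=8,
        effect_low=0.04,
        effect_median=0.07,
        effect_high=0.15,
        noise_sd=0.08,
        expr_modules=[(30, 0.8)],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    # paper-regime defaults: 30 F / 25 M pairs, 347/50/48 planted effects
    return simulate_cohort(SimConfig(seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
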