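import numpy as np
import pytest

from pgsx.synthetic_data import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Additive-only cohort shared by read-only tests."""
    params = SimulationParams(
        n_samples=2000, n_snps=100, n_causal=30, beta_sd=0.3, seed=11
    )
    return simulate_cohort(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
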