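import numpy as np
import pytest

from prscreen.config import ScenarioConfig
from prscreen.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest trait->disorder cohort reused across read-only tests."""
    cfg = ScenarioConfig(
        scenario="trait_to_disorder", n_individuals=2000, n_snps=300,
        ld_block_size=5, ld_rho=0.5, n_causal=30, seed=42,
    )
    return simulate_cohort(cfg, with_locations=True)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
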