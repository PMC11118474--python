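import numpy as np
import pytest

from nascentmech.sim import SimConfig, simulate_chip, simulate_genome, simulate_proseq


@pytest.fixture(scope="session")
def sim_data():
    """One standard simulated experiment shared across tests (seed 5)."""
    cfg = SimConfig(seed=5)
    return simulate_chip(simulate_proseq(simulate_genome(cfg)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
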