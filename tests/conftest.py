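import pytest
from hypothesis import settings

from gcdecay.simulate import SimConfig, simulate_all

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_small():
    """One small, fully populated synthetic dataset shared across tests."""
    return simulate_all(SimConfig(n_genes=150, seed=42))


@pytest.fixture(scope="session")
def annotation_small(sim_small):
    return sim_small.annotation


@pytest.fixture(scope="session")
def truth_small(sim_small):
    return sim_small.truth
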