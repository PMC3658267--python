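import numpy as np
import pytest

from phosmap.simulate import SimConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_sim():
    """One shared default-benchmark realization (seed 0)."""
    return simulate(SimConfig(rng_seed=0))


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast benchmark for pipeline-level tests."""
    return simulate(SimConfig(n_kinases=3, n_proteins=120, n_blacklist=5,
                              substrates_per_kinase=6, rng_seed=0))
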