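import numpy as np
import pytest

from asrt import GenomeSpec, SimParams
from asrt.genome import default_genome
from asrt.simulate import simulate_counts, simulate_rt_landscape


@pytest.fixture(scope="session")
def small_genome() -> GenomeSpec:
    """Two 50-Mb autosomes on the 100-kb grid (1,000 windows)."""
    return default_genome(n_chromosomes=2, n_windows=500)


@pytest.fixture(scope="session")
def default_params() -> SimParams:
    return SimParams(seed=11)


@pytest.fixture(scope="session")
def truth(small_genome, default_params):
    return simulate_rt_landscape(small_genome, default_params)


@pytest.fixture(scope="session")
def clone_counts(truth):
    return simulate_counts(truth)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
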