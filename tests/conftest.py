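import numpy as np
import pytest

from sdhap.fixtures import load_grch38_model
from sdhap.simulate import (SimulationConfig, build_catalog,
                            default_haplotypes, simulate_locus)


@pytest.fixture(scope="session")
def sim_locus():
    """Default synthetic locus, seed 1 (shared across the suite)."""
    return simulate_locus(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def sim_haplotypes(sim_locus):
    return default_haplotypes(sim_locus)


@pytest.fixture(scope="session")
def sim_catalog(sim_locus, sim_haplotypes):
    return build_catalog(sim_locus, sim_haplotypes)


@pytest.fixture(scope="session")
def grch38_model():
    return load_grch38_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
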