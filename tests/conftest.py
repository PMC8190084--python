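import numpy as np
import pytest

from penexome import SimulationConfig, simulate_cohort, simulate_variant_annotations


@pytest.fixture(scope="session")
def small_sim():
    """Small default-structure cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(n_individuals=5_000, seed=11))


@pytest.fixture(scope="session")
def fixtures():
    return simulate_variant_annotations()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
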