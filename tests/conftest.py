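import numpy as np
import pytest

from ernakit.config import PipelineConfig
from ernakit.simulate import CohortSpec, SimulationDesign, simulate_all


@pytest.fixture(scope="session")
def config():
    return PipelineConfig(seed=0)


@pytest.fixture(scope="session")
def bundle():
    """Default 3-cohort synthetic bundle with every planted effect."""
    return simulate_all(SimulationDesign(seed=7))


def null_design(seed: int) -> SimulationDesign:
    """Design with no planted effects of any kind."""
    return SimulationDesign(
        seed=seed, master_tf=False, n_planted_links=0, n_planted_de=0,
        n_planted_drug=0, n_planted_hazard=0, n_planted_subtype=0,
    )


@pytest.fixture(scope="session")
def null_bundle():
    return simulate_all(null_design(11))


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
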