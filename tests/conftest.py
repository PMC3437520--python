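import numpy as np
import pytest
from hypothesis import settings

from shallowseq import SimulationConfig

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Shrunken synthetic world for fast tests (structure preserved)."""
    return SimulationConfig(
        n_genes=2000,
        n_modules=100,
        ct_times=tuple(float(t) for t in range(0, 45, 4)),
        seed=1,
    )


@pytest.fixture(scope="session")
def full_config() -> SimulationConfig:
    """Defaults at study scale (22,746 genes)."""
    return SimulationConfig(seed=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
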