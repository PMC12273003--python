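import numpy as np
import pytest
from hypothesis import settings

import psiquant as pq
from psiquant import synthdata as sd

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> pq.SimConfig:
    """A reduced study (8 genes, 4 tissues) for fast structural checks."""
    return pq.SimConfig(
        n_genes=8, n_tissues=4, n_replicates=2, depth_mean=300.0, seed=11
    )


@pytest.fixture(scope="session")
def small_bundle(small_config) -> sd.SimBundle:
    return sd.simulate_all(small_config)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
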