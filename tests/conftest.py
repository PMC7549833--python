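import numpy as np
import pytest

from spikemotifs import TopologyConfig, build_clustered_network


@pytest.fixture(scope="session")
def small_clustered_network():
    """A reduced clustered network for structural tests (fast to build)."""
    cfg = TopologyConfig(n_excitatory=400, n_inhibitory=100, n_clusters=10,
                         seed=11)
    return build_clustered_network(cfg)


@pytest.fixture(scope="session")
def full_clustered_network():
    """One full-size clustered network (4000 E + 1000 I)."""
    return build_clustered_network(TopologyConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
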