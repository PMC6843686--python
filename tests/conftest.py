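import numpy as np
import pytest

from channelgate.synthetic import build_pseudo_receptor
from channelgate.topology import default_topology


@pytest.fixture(scope="session")
def topology():
    return default_topology()


@pytest.fixture(scope="session")
def base(topology):
    return build_pseudo_receptor(topology, seed=0)


@pytest.fixture(scope="session")
def compact_base(topology):
    return build_pseudo_receptor(topology, seed=0, resolution="compact")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
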