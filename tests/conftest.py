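import numpy as np
import pytest

from hepcg.params import CGParameters
from hepcg.topology import rebuild_cartesian


@pytest.fixture(scope="session")
def params():
    return CGParameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_chain_factory(rng):
    """Random non-degenerate chains with realistic bond lengths."""

    def make(n_sites=6, params=None):
        d = rng.uniform(4.2, 5.8, n_sites)
        th = rng.uniform(90.0, 170.0, n_sites - 1)
        ga = rng.uniform(-170.0, 170.0, max(n_sites - 2, 0))
        return rebuild_cartesian(d, th, ga, params or CGParameters())

    return make
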