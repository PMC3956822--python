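import numpy as np
import pytest

import phylofid as pf


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def yule24():
    """Small ultrametric Yule tree shared by unit tests."""
    return pf.simulate_tree(24, seed=3)


@pytest.fixture(scope="session")
def yule24_cov(yule24):
    return yule24.vcv()


@pytest.fixture(scope="session")
def fixture_dataset():
    """One study-shaped dataset: 41-species trait table + five trees."""
    table, trees, latents = pf.paper_shaped_fixture(7)
    return table, trees, latents
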