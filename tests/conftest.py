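import numpy as np
import pytest

from retinatune.templates import make_grid


@pytest.fixture(scope="session")
def grid_5nm():
    return make_grid(300.0, 700.0, 5.0)


@pytest.fixture(scope="session")
def grid_1nm():
    return make_grid(300.0, 700.0, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
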