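import numpy as np
import pytest

from curtainkit.synthetic import make_default_substrate


@pytest.fixture(scope="session")
def substrate_4x():
    return make_default_substrate("4x")


@pytest.fixture(scope="session")
def substrate_1x():
    return make_default_substrate("1x")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
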