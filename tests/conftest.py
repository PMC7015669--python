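import numpy as np
import pytest

from axonmap import preset


@pytest.fixture(scope="session")
def connectom():
    return preset("connectom")


@pytest.fixture(scope="session")
def aeon():
    return preset("aeon")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
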