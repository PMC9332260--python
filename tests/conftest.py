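import numpy as np
import pytest

from luxtherm.synthgen import toy_chain


@pytest.fixture(scope="session")
def chain30():
    return toy_chain(30)


@pytest.fixture(scope="session")
def chain10():
    return toy_chain(10)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
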