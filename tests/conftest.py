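import numpy as np
import pytest

from mcaspol.models import (
    make_indirect_model,
    make_mechanistic_model,
    make_minimal_model,
)
from mcaspol.solver import Grid


@pytest.fixture(scope="session")
def minimal_model():
    return make_minimal_model()


@pytest.fixture(scope="session")
def indirect_model():
    return make_indirect_model()


@pytest.fixture(scope="session")
def mechanistic_model():
    return make_mechanistic_model()


@pytest.fixture(scope="session")
def nfb_model():
    return make_mechanistic_model(negative_feedback=True)


@pytest.fixture(scope="session")
def all_models(minimal_model, indirect_model, mechanistic_model, nfb_model):
    return [minimal_model, indirect_model, mechanistic_model, nfb_model]


@pytest.fixture
def grid_1d():
    return Grid((200,), (5.0,), bc="periodic")


@pytest.fixture
def grid_1d_noflux():
    return Grid((200,), (5.0,), bc="noflux")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
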