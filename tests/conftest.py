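import numpy as np
import pytest

from langshift import CompetitionModel, PopulationState, get_fixture


@pytest.fixture(scope="session")
def singapore():
    return get_fixture("singapore")


@pytest.fixture(scope="session")
def singapore_model(singapore):
    return singapore.model()


@pytest.fixture(scope="session")
def singapore_x0(singapore):
    return singapore.initial_state()


@pytest.fixture
def symmetric_model():
    return CompetitionModel(["A", "B", "C"], np.full(3, 1 / 3), alpha=1.2, beta=0.8)


@pytest.fixture
def symmetric_state():
    return PopulationState(np.full(3, 1 / 3))
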