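import numpy as np
import pytest
from hypothesis import settings

from mcpopgen import ModelParams, StateSpace, build_transition_matrix, make_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def space5():
    return StateSpace(5)


@pytest.fixture(scope="session")
def model_n5():
    """Dense model matrix for N=5, mu=1e-6, c=0 (21 states)."""
    return build_transition_matrix(ModelParams(N=5, mu=1e-6, c=0.0))


@pytest.fixture(scope="session")
def model_n20():
    """Dense model matrix for N=20, mu=1e-6, c=0 (231 states)."""
    return build_transition_matrix(ModelParams(N=20, mu=1e-6, c=0.0))


@pytest.fixture
def toy3():
    return make_fixture("toy3")


@pytest.fixture
def toy5():
    return make_fixture("toy5")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
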