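import numpy as np
import pytest

from copolar import CellParams, PeriodicDomain, init_state


@pytest.fixture(scope="session")
def domain():
    return PeriodicDomain()


@pytest.fixture(scope="session")
def params():
    return CellParams()


@pytest.fixture(scope="session")
def fast_params():
    """Default kinetics but a short horizon, for structural checks."""
    return CellParams(t_end=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def cell_state(params, domain):
    return init_state(params, domain, rng=7)
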