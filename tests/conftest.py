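import numpy as np
import pytest
from hypothesis import settings

from ndcrate import ThermoState, table2_case
from ndcrate.correlations import TimeGrid, corr_closed_form

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def theta1():
    return ThermoState.from_theta(1.0)


@pytest.fixture(scope="session")
def grid10():
    """Reduced-unit grid spanning t·ω_c in [0, 10]."""
    return TimeGrid(10.0, 0.01)


@pytest.fixture(scope="session")
def grid40():
    """Longer reduced-unit grid for converged rate integrals (θ = 1 baths)."""
    return TimeGrid(40.0, 0.004)


@pytest.fixture(scope="session")
def case_corrs(grid40):
    """Closed-form correlation sets for all six named model cases."""
    out = {}
    for cid in ("I-A", "I-B", "I-C", "II-A", "II-B", "II-C"):
        nc = table2_case(cid)
        out[cid] = corr_closed_form(nc.params, nc.thermo, grid40)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
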