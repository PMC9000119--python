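import numpy as np
import pytest

from pacesim import get_preset, simulate_cell


@pytest.fixture(scope="session")
def pap_trace():
    """Settled pAP 0D trace (b = 0.03), shared across tests."""
    trace, _ = simulate_cell(get_preset("pAP-0D"), 40_000.0, dt=0.01,
                             scheme="fe", record_dt=0.1)
    return trace


@pytest.fixture(scope="session")
def pcn_trace():
    """Settled pCN 0D trace (b = 0.3), shared across tests."""
    trace, _ = simulate_cell(get_preset("pCN-0D"), 40_000.0, dt=0.01,
                             scheme="fe", record_dt=0.1)
    return trace


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
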