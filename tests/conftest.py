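import numpy as np
import pytest

from atriagp.cell_models import PacingProtocol, ParameterAssignment, simulate
from atriagp.design import latin_hypercube
from atriagp.emulator import train


@pytest.fixture(scope="session")
def toy_defaults():
    return ParameterAssignment.defaults("toy")


@pytest.fixture(scope="session")
def crn_defaults():
    return ParameterAssignment.defaults("courtemanche")


@pytest.fixture(scope="session")
def mal_defaults():
    return ParameterAssignment.defaults("maleckar")


@pytest.fixture(scope="session")
def crn_short_trace(crn_defaults):
    """Three Courtemanche beats at CL 1000 ms (shared across tests)."""
    return simulate(crn_defaults, PacingProtocol(n_beats=3))


@pytest.fixture(scope="session")
def triangle_trace():
    """Instant rise to +20 mV at t=0, linear fall to -80 mV at t=500 ms.

    Closed forms: amplitude 100 mV, APD_90 = 450 ms, APD_50 = 250 ms,
    V(t) = 20 - 0.2 t so V_20 = V(90) = +2 mV.
    """
    from atriagp.cell_models import Trace

    t = np.arange(-200.0, 700.0, 0.5)
    v = np.where(t < 0, -80.0, np.where(t <= 500, 20.0 - 0.2 * t, -80.0))
    ca = 1e-4 + 5e-4 * np.exp(-((t - 30.0) / 80.0) ** 2) * (t >= 0)
    return Trace(t, v, ca, np.array([0.0]), np.array([0.0]))


@pytest.fixture(scope="session")
def linear_emulator():
    """Emulator of y = 2 x1 + 1 on a 2-input design."""
    X = latin_hypercube(20, 2, seed=1).X
    return train(X, 2 * X[:, 0] + 1, seed=0, restarts=4)


@pytest.fixture(scope="session")
def two_input_design():
    return latin_hypercube(30, 2, seed=3).X


@pytest.fixture(scope="session")
def interaction_emulator(two_input_design):
    """Emulator of the pure-interaction surface (x1-0.5)(x2-0.5)."""
    X = two_input_design
    y = (X[:, 0] - 0.5) * (X[:, 1] - 0.5)
    return train(X, y, seed=0, restarts=6)
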