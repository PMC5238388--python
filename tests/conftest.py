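import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tdca import model, tdcf
from tdca.trajio import AngleSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def coupled_system():
    """One asymmetric, clearly correlated two-variable system."""
    return model.OscillatorSystem.from_relaxation_times(
        5.0, 8.0, coupling_ij=0.03, coupling_ji=0.12)


@pytest.fixture(scope="session")
def simulated_pair(coupled_system):
    """Long stationary realization of the coupled system as fluctuation series."""
    t, x = model.simulate(coupled_system, 2 ** 18, 0.05, seed=7)
    fi = tdcf.fluctuations(AngleSeries(1, "phi", t, x[:, 0]))
    fj = tdcf.fluctuations(AngleSeries(2, "phi", t, x[:, 1]))
    return fi, fj
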