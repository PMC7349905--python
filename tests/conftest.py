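import numpy as np
import pytest

from polarflow import ReactionParams, SystemParams, homogeneous_state, make_initial


@pytest.fixture(scope="session")
def params():
    """Default attachment-detachment kinetics."""
    return ReactionParams()


@pytest.fixture(scope="session")
def sys0():
    """Canonical operating point: periodic L=10, n_bar=5, Dm=0.01, Dc=10."""
    return SystemParams()


@pytest.fixture(scope="session")
def state0(sys0):
    """Homogeneous steady state at the canonical operating point."""
    return homogeneous_state(sys0.n_bar, sys0.reaction)


@pytest.fixture(scope="session")
def relaxed_peak(sys0):
    """Stationary single-peak pattern at the canonical operating point
    (shared across tests; treated as read-only)."""
    return make_initial("single-peak", sys0, N=256, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
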