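import numpy as np
import pytest

from nrf2dyn.model import Condition, StimulusSpec, simulate_condition
from nrf2dyn.steady_state import solve_steady_state
from nrf2dyn.synthetic import reference_parameters


@pytest.fixture(scope="session")
def theta():
    """Reference (ground-truth) parameter set."""
    return reference_parameters()


@pytest.fixture(scope="session")
def steady_hl(theta):
    ss = solve_steady_state("hinge_latch", theta)
    assert ss.converged
    return ss


@pytest.fixture(scope="session")
def dem316_trajectories(theta, steady_hl):
    """Half-hourly hinge-latch trajectories for DEM 316 over 48 h."""
    times = tuple(np.arange(0.0, 48.5, 0.5))
    cond = Condition(stimulus=StimulusSpec(compound="DEM", dose=316.0),
                     horizon=48.0, observation_times=times)
    return simulate_condition("hinge_latch", theta, cond, x0=steady_hl.state0)


def perturbed_parameters(theta, rng, spread=0.3):
    """Random positive parameter set: reference rates scaled log-uniformly."""
    updates = {}
    for name, value in theta.values.items():
        if name.startswith(("f_", "h_")):
            continue
        updates[name] = value * 10.0 ** rng.uniform(-spread, spread)
    return theta.replace(**updates)
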