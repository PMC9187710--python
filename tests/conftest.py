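import numpy as np
import pytest

from dynclicks.accumulation import ModelParams
from dynclicks.synth import TaskParams, Trial, generate_dataset


@pytest.fixture(scope="session")
def task():
    return TaskParams()


@pytest.fixture(scope="session")
def theta():
    """A leaky-regime parameter set used throughout the tests."""
    return ModelParams(sigma_i2=0.3, sigma_a2=1.0, sigma_s2=1.5, lam=-2.0,
                       phi=0.6, tau_phi=0.15, B=0.1, lapse=0.05)


@pytest.fixture(scope="session")
def small_dataset(theta):
    """120 trials x 6 units (4 tuned, 2 untuned), deterministic."""
    return generate_dataset(120, 6, theta=theta, seed=42)


def make_trial(duration=1.0, left=(), right=(), changes=(), initial_state=1,
               trial_id=0, choice=None, hit=None, movement=None):
    changes = np.asarray(changes, dtype=float)
    final = initial_state if changes.size % 2 == 0 else 3 - initial_state
    return Trial(trial_id=trial_id, duration=duration,
                 left_clicks=np.asarray(left, dtype=float),
                 right_clicks=np.asarray(right, dtype=float),
                 state_changes=changes, initial_state=initial_state,
                 final_state=final, choice=choice, hit=hit, movement=movement)


@pytest.fixture
def trial_factory():
    return make_trial
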