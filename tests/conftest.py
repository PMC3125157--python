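import numpy as np
import pytest

import cfbandit as cb
from cfbandit.learner import GridSpec, run_learner


@pytest.fixture(scope="session")
def schedule():
    return cb.generate_true_probability_walk(180, seed=7)


@pytest.fixture(scope="session")
def skeleton(schedule):
    return cb.generate_session(schedule, seed=8)


@pytest.fixture(scope="session")
def agent_session(skeleton, schedule):
    """One optimal-learner softmax agent at moderate weights."""
    return cb.simulate_agent(skeleton, schedule, cb.ChoiceParams(6, 3, 4),
                             "optimal", seed=9)


@pytest.fixture(scope="session")
def estimates(agent_session):
    return run_learner(agent_session, variant="optimal")


@pytest.fixture(scope="session")
def small_grid():
    """Coarse grid for tests where quadrature accuracy is not the point."""
    return GridSpec(r_points=20, v_points=5, k_points=3)


def make_full_feedback_session(outcomes):
    """Condition-1 session frame with given (n, 3) outcome array."""
    import pandas as pd

    outcomes = np.asarray(outcomes, dtype=int)
    n = outcomes.shape[0]
    return pd.DataFrame({
        "condition": np.ones(n, dtype=int),
        "first_choice": np.ones(n, dtype=int),
        "outcome_1": outcomes[:, 0],
        "outcome_2": outcomes[:, 1],
        "outcome_3": outcomes[:, 2],
    })
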