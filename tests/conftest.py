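import pandas as pd
import pytest

from transinf import task_env


@pytest.fixture(scope="session")
def exp2_trials():
    return task_env.build_trial_sequence("exp2", 123)


@pytest.fixture
def tiny_dataset():
    """Hand-built 3-item, 2-trial session with recorded choices.

    Trial 1: pair (1,2), feedback, truthful winner 1, agent chose 1.
    Trial 2: pair (2,3), feedback, truthful winner 2, agent chose 2.
    """
    df = pd.DataFrame(
        {
            "trial": [1, 2],
            "block": [1, 1],
            "item_hi": [1, 2],
            "item_lo": [2, 3],
            "first_position": ["hi", "lo"],
            "feedback_scheduled": [True, True],
            "outcome_winner": pd.array([1, 2], dtype="Int64"),
            "truthful": pd.array([True, True], dtype="boolean"),
            "choice": [1, 2],
            "correct": [True, True],
        }
    )
    return df


def make_dataset(design, model, params, seed):
    """Simulated session as a fit-ready trial table."""
    from transinf.simulate import simulate_agent

    return simulate_agent(design, model, params, seed).trials
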