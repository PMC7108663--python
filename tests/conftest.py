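import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from grouplearn import DesignConfig, LearnerParams, build_agents, simulate_cohort


@pytest.fixture(scope="session")
def default_design() -> DesignConfig:
    return DesignConfig()


@pytest.fixture(scope="session")
def default_agents(default_design):
    return build_agents(default_design)


@pytest.fixture(scope="session")
def small_cohort():
    """Four participants (all counterbalance variants), reduced schedule."""
    cfg = DesignConfig(
        n_block1_trials_per_agent=12,
        n_block2_new_agent_trials=6,
        n_block2_old_agent_trials_total=8,
    )
    params = LearnerParams(miss_rate=0.02)
    return simulate_cohort(4, params, cfg, seed=123), cfg


def make_records(pred_counts, participant_id=0, block=1, condition_of=None):
    """Build a trial table directly from per-agent prediction count vectors.

    ``pred_counts``: dict agent_id -> length-4 counts of predicted vases.
    Actual choices are irrelevant for prediction-distribution analyses and
    set to 0.
    """
    rows = []
    t = 0
    for aid, counts in pred_counts.items():
        pres = 0
        for vase, c in enumerate(counts):
            for _ in range(int(c)):
                t += 1
                pres += 1
                rows.append(
                    {
                        "participant_id": participant_id,
                        "block": block,
                        "global_trial_index": t,
                        "agent_id": aid,
                        "condition": condition_of[aid] if condition_of else "Logo",
                        "presentation_index": pres,
                        "predicted_vase": vase,
                        "actual_choice": 0,
                        "missed": False,
                    }
                )
    df = pd.DataFrame(rows)
    df["predicted_vase"] = df["predicted_vase"].astype("Int64")
    return df
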