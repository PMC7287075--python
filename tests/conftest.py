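import numpy as np
import pytest

import serialorder as so


@pytest.fixture(scope="session")
def stim7() -> so.StimulusList:
    return so.StimulusList(7)


@pytest.fixture(scope="session")
def small_session(stim7):
    """70 single-stimulus + 2 all-pairs blocks (84 choice trials)."""
    schedule = so.build_session_schedule(stim7, 2, rng_seed=11)
    return so.simulate_session(schedule, rng_seed=12)


@pytest.fixture(scope="session")
def mid_session(stim7):
    """70 single-stimulus + 10 all-pairs blocks (420 choice trials)."""
    schedule = so.build_session_schedule(stim7, 10, rng_seed=21)
    return so.simulate_session(schedule, rng_seed=22)


@pytest.fixture(scope="session")
def default_unit_spikes(small_session):
    unit = so.NeuronParams()
    return so.simulate_unit(unit, small_session, rng_seed=5), unit


def make_trials_df(event_times, latency_ms=232.0):
    """Minimal hand-built trial table for window arithmetic tests."""
    import pandas as pd

    rows = []
    for i, t_stim in enumerate(event_times):
        t_sacc = t_stim + latency_ms / 1000.0
        rows.append({
            "trial_index": i, "phase": 2, "block": 0, "choice_trial_index": i + 1,
            "rank_low": 1, "rank_high": 2, "sd": 1, "jr": 3, "single_rank": np.nan,
            "in_rf_item": 1, "chosen_location": 0, "chosen_item": 1,
            "correct": True, "rewarded": True,
            "t_fix_on": t_stim - 0.5, "t_stimulus_on": t_stim,
            "t_saccade": t_sacc, "t_feedback": t_sacc + 0.5,
            "t_reward": t_sacc + 1.0, "t_trial_end": t_sacc + 1.2,
            "latency_ms": latency_ms, "prev_rewarded": i > 0,
        })
    df = pd.DataFrame(rows)
    df.attrs["n_items"] = 7
    return df
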