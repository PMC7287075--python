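"""Behavioral analyses: learning curves, SD effects, reward-history biases."""

import numpy as np
import pytest

import serialorder as so

from conftest import make_trials_df


def _sessions(n, blocks=10, seed0=500):
    out = []
    stim = so.StimulusList(7)
    for s in range(n):
        sched = so.build_session_schedule(stim, blocks, rng_seed=seed0 + s)
        out.append(so.simulate_session(sched, rng_seed=seed0 + 1000 + s))
    return out


def test_moving_accuracy_all_correct():
    trials = make_trials_df(np.arange(30) * 5.0)
    curve = so.moving_accuracy(trials, window=25)
    assert np.allclose(curve["value"], 1.0)


def test_moving_accuracy_alternating():
    trials = make_trials_df(np.arange(50) * 5.0)
    trials["correct"] = (np.arange(50) % 2 == 0)
    curve = so.moving_accuracy(trials, window=25)
    full = curve["value"].to_numpy()[12:-12]  # full windows only
    assert np.all(np.isin(np.round(full * 25), [12, 13]))


def test_moving_accuracy_matches_brute_force():
    rng = np.random.default_rng(1)
    trials = make_trials_df(np.arange(120) * 5.0)
    trials["correct"] = rng.uniform(size=120) < 0.7
    curve = so.moving_accuracy(trials, window=25)
    c = trials["correct"].to_numpy().astype(float)
    i = 60
    brute = c[i - 12:i + 13].mean()
    assert curve["value"].iloc[i] == pytest.approx(brute)


def test_moving_accuracy_by_sd_and_item(mid_session):
    # at 10 choice blocks SD 6 has only 20 trials, fewer than the default
    # 25-trial window, and is omitted by rule
    by_sd = so.moving_accuracy(mid_session, group_by="sd")
    assert set(by_sd["group"]) == set(range(1, 6))
    by_sd20 = so.moving_accuracy(mid_session, window=20, group_by="sd")
    assert set(by_sd20["group"]) == set(range(1, 7))
    by_item = so.moving_accuracy(mid_session, group_by="item")
    assert set(by_item["group"]) == set(range(1, 8))
    assert by_item["value"].between(0, 1).all()


def test_accuracy_at_trial_stationary_bernoulli():
    rng = np.random.default_rng(2)
    sessions = _sessions(1, blocks=15)
    trials = sessions[0]
    trials = trials.copy()
    ct_mask = trials["phase"] == 2
    trials.loc[ct_mask, "correct"] = rng.uniform(size=ct_mask.sum()) < 0.7
    for method in ("window", "gpr"):
        surf = so.accuracy_at_trial(trials, 250, method=method, window=200)
        assert len(surf) == 21
        assert surf["accuracy"].mean() == pytest.approx(0.7, abs=0.08)


def test_accuracy_at_trial_learning_monotone():
    """For the learning agent every SD level improves from early (trial 100)
    to late (trial 500) estimates (mean over sessions), and window and GPR
    estimates agree on smooth learning curves."""
    sessions = _sessions(12, blocks=15, seed0=600)
    deltas = {sd: [] for sd in range(1, 7)}
    gaps = []
    for trials in sessions[:4]:
        g100 = so.accuracy_at_trial(trials, 100, method="gpr")
        w100 = so.accuracy_at_trial(trials, 100, method="window", window=150)
        gaps.append((w100["accuracy"] - g100["accuracy"]).abs().mean())
    for trials in sessions:
        s100 = so.accuracy_at_trial(trials, 100, method="window", window=150)
        s500 = so.accuracy_at_trial(trials, 500, method="window", window=150)
        for sd in range(1, 7):
            deltas[sd].append(s500[s500.sd == sd].accuracy.mean()
                              - s100[s100.sd == sd].accuracy.mean())
    for sd in range(1, 7):
        assert np.mean(deltas[sd]) > -0.01
    assert np.mean([np.mean(d) for d in deltas.values()]) > 0.0
    assert np.mean(gaps) < 0.12


def test_sd_correlation_perfect_ordering():
    sessions = _sessions(1)
    trials = sessions[0].copy()
    ct = trials["phase"] == 2
    # per-level accuracy exactly linear in SD: correct on a fixed fraction
    rng = np.random.default_rng(8)
    for sd in range(1, 7):
        m = ct & (trials["sd"] == sd)
        n = int(m.sum())
        k = round(n * (0.35 + 0.1 * sd))
        vals = np.zeros(n, bool)
        vals[:k] = True
        trials.loc[m, "correct"] = vals
    out = so.sd_performance_correlation([trials])
    assert out["r"] > 0.99


def test_sd_correlation_constant_errors():
    trials = make_trials_df(np.arange(80) * 5.0)
    with pytest.raises(ValueError):
        so.sd_performance_correlation([trials, trials, trials])


def test_sd_correlation_closed_loop():
    out = so.sd_performance_correlation(_sessions(10))
    assert out["r"] > 0.5
    assert out["p"] < 1e-4
    assert out["n"] == 60


def test_rt_by_sd_planted_offsets():
    rng = np.random.default_rng(3)
    trials = make_trials_df(np.arange(600) * 5.0)
    sd = rng.integers(1, 7, 600)
    trials["sd"] = sd
    trials["latency_ms"] = 200.0 - 3.0 * sd + rng.normal(0, 0.01, 600)
    out = so.rt_by_sd(trials)
    assert out["range_ms"] == pytest.approx(15.0, abs=0.05)
    assert out["p"] < 1e-10


def test_rt_by_sd_recovers_generator_slope():
    out = so.rt_by_sd(_sessions(15))
    assert out["range_ms"] == pytest.approx(7.0, abs=2.0)
    assert out["p"] < 0.001


def test_winstay_deterministic_alternation():
    trials = make_trials_df(np.arange(40) * 5.0)
    trials["chosen_location"] = np.arange(40) % 2
    trials["rewarded"] = np.arange(40) % 3 == 0
    out = so.winstay_loseshift(trials)
    assert out["after_reward"]["mean"] == 0.0
    assert out["after_noreward"]["mean"] == 0.0


def test_winstay_fair_coin():
    rng = np.random.default_rng(4)
    vals = []
    for s in range(30):
        trials = make_trials_df(np.arange(200) * 5.0)
        trials["chosen_location"] = rng.integers(0, 2, 200)
        trials["rewarded"] = rng.uniform(size=200) < 0.6
        vals.append(trials)
    out = so.winstay_loseshift(vals)
    assert out["after_reward"]["mean"] == pytest.approx(0.5, abs=0.03)
    assert out["after_noreward"]["mean"] == pytest.approx(0.5, abs=0.03)
    assert out["after_reward"]["p"] > 0.01


def test_item_reward_history_null_agent():
    """The default agent's bias is spatial only: item-level choice
    probability does not depend on the item's previous outcome."""
    out = so.item_reward_history(_sessions(25, seed0=700))
    diff = out["mean_after_reward"] - out["mean_after_noreward"]
    assert abs(diff) < 0.05
    assert abs(out["latency_diff_ms"]) < 2.0


def test_item_reward_history_recovers_planted_stickiness():
    params = so.AgentParams(item_stay_bias=0.3)
    stim = so.StimulusList(7)
    sessions = []
    for s in range(15):
        sched = so.build_session_schedule(stim, 10, rng_seed=800 + s)
        sessions.append(so.simulate_session(sched, params, rng_seed=900 + s))
    out = so.item_reward_history(sessions)
    diff = out["mean_after_reward"] - out["mean_after_noreward"]
    # the conditional-probability contrast recovers the bias direction; its
    # magnitude is attenuated because the override fires only when the two
    # presented items' last outcomes differ
    assert diff > 0.05
    assert out["choice_p"] < 1e-4


def test_item_reward_history_empty_errors():
    trials = make_trials_df(np.arange(5) * 5.0)  # only pair (1,2): no cells
    with pytest.raises(ValueError):
        so.item_reward_history(trials)
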