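"""Generative behavioral agent for transitive-inference sessions.

The agent is a minimal statistical stand-in for a learning macaque: choice
accuracy follows a logistic model whose symbolic-distance slope ramps up with
experience, with a bonus for pairs containing a terminal (first/last) item, a
spatial win-stay/lose-shift bias applied as an independent post-hoc override,
and saccade latencies drawn from a truncated normal whose mean decreases
slightly with symbolic distance.

Calibrated defaults: accuracy rises from chance (0.5) to a plateau around
0.75 within ~250 choice trials; the rewarded spatial location is repeated 56%
of the time (48% after non-reward); latencies are ~232 ± 31 ms with a ~7 ms
spread of means across symbolic distances 1..6.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .task import SessionSchedule, TrialTiming

__all__ = ["AgentParams", "choice_accuracy_model", "simulate_session", "TRIAL_COLUMNS"]


@dataclass(frozen=True)
class AgentParams:
    """Parameters of the generative behavioral agent.

    b0, b_sd_max, b_term are log-odds terms of the accuracy model;
    tau_learn is the learning time constant in choice trials; p_winstay /
    p_loseshift_stay are the marginal probabilities of repeating the previous
    trial's location after reward / non-reward; rt_* set the latency model
    (ms).
    """

    b0: float = 0.0
    b_sd_max: float = 0.4
    tau_learn: float = 100.0
    b_term: float = 0.35
    p_winstay: float = 0.56
    p_loseshift_stay: float = 0.48
    rt_mu: float = 232.0
    rt_sigma: float = 31.0
    rt_sd_slope: float = 1.4
    # probability of overriding the choice toward a presented item whose most
    # recent choice was rewarded (away from one whose last choice was not);
    # the default agent's reward-history bias is spatial only
    item_stay_bias: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_winstay", "p_loseshift_stay"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.rt_sigma <= 0:
            raise ValueError("rt_sigma must be positive")
        if self.tau_learn <= 0:
            raise ValueError("tau_learn must be positive")


def choice_accuracy_model(pair, t: int, params: AgentParams, n_items: int = 7) -> float:
    """P(correct) on choice trial ``t`` (1-based) for the given pair.

    logistic(b0 + b_sd(t)·SD + b_term(t)·[terminal pair]) where both slopes
    ramp with learning, b(t) = b_max · (1 − exp(−(t−1) / tau_learn)), so the
    first trial is exactly at chance (for b0 = 0) and the model is monotone
    nondecreasing in both t and symbolic distance.  The terminal-item bonus
    ramps too: before learning nothing distinguishes the end items.
    """
    if t < 1:
        raise ValueError("trial index is 1-based")
    ramp = 1.0 - np.exp(-(t - 1.0) / params.tau_learn)
    x = params.b0 + params.b_sd_max * ramp * pair.symbolic_distance
    if pair.contains_terminal(n_items):
        x += params.b_term * ramp
    return float(expit(x))


TRIAL_COLUMNS = [
    "trial_index", "phase", "block", "choice_trial_index",
    "rank_low", "rank_high", "sd", "jr", "single_rank", "in_rf_item",
    "chosen_location", "chosen_item", "correct", "rewarded",
    "t_fix_on", "t_stimulus_on", "t_saccade", "t_feedback", "t_reward",
    "t_trial_end", "latency_ms", "prev_rewarded",
]


def _truncnorm_sample(rng: np.random.Generator, mu: float, sigma: float,
                      lo: float, hi: float) -> float:
    # rejection sampling; acceptance region covers nearly all mass here
    for _ in range(1000):
        x = rng.normal(mu, sigma)
        if lo < x <= hi:
            return x
    return float(np.clip(mu, lo + 1e-9, hi))


def simulate_session(
    schedule: SessionSchedule,
    params: AgentParams | None = None,
    rng_seed: int = 0,
    timing: TrialTiming | None = None,
    iti: float = 1.0,
) -> pd.DataFrame:
    """Simulate one session of behavior on a schedule; returns the trial table.

    Phase-1 (single stimulus) trials are always completed and rewarded.  On
    choice trials the item is drawn from :func:`choice_accuracy_model`, then
    with probability 2·(p_winstay − 0.5) after a rewarded trial the choice is
    overridden toward the previous trial's location (2·(0.5 −
    p_loseshift_stay) toward the opposite location after non-reward), so the
    marginal location-repeat probabilities equal the configured p_winstay /
    p_loseshift_stay while rank learning stays intact on non-override trials.
    Deterministic given the seed.
    """
    params = params or AgentParams()
    timing = timing or TrialTiming()
    rng = np.random.default_rng(rng_seed)
    n = schedule.stim_list.n_items

    w_stay = max(0.0, 2.0 * params.p_winstay - 1.0)
    w_stay_shift = max(0.0, 1.0 - 2.0 * params.p_winstay)  # if p_winstay < 0.5
    w_shift = max(0.0, 1.0 - 2.0 * params.p_loseshift_stay)
    w_shift_stay = max(0.0, 2.0 * params.p_loseshift_stay - 1.0)

    rows = []
    t_clock = 0.5  # pre-roll so peri-trial windows stay on the session clock
    choice_idx = 0
    prev_location: int | None = None
    prev_rewarded: bool | None = None
    item_outcome: dict[int, bool] = {}  # last outcome of each item's choice

    for i, st in enumerate(schedule.trials):
        fix_delay = float(timing.sample_fix_delay(rng))
        hold = float(timing.sample_hold(rng))
        reward_int = float(timing.sample_reward_interval(rng))
        t_fix_on = t_clock
        t_stim = t_fix_on + fix_delay

        if st.phase == 1:
            # single stimulus: location 0 = inside RF, 1 = opposite
            location = 0 if st.in_rf else 1
            chosen_item = st.single_rank
            correct = True
            latency = _truncnorm_sample(rng, params.rt_mu, params.rt_sigma, 0.0, 1500.0)
            sd = jr = np.nan
            rank_low = rank_high = in_rf_item = np.nan
            single_rank = st.single_rank
            this_choice_idx = np.nan
        else:
            pair = st.pair
            choice_idx += 1
            p_correct = choice_accuracy_model(pair, choice_idx, params, n)
            chosen_item = pair.rank_low if rng.uniform() < p_correct else pair.rank_high
            # optional item-level reward stickiness
            if params.item_stay_bias > 0 and rng.uniform() < params.item_stay_bias:
                o_lo = item_outcome.get(pair.rank_low)
                o_hi = item_outcome.get(pair.rank_high)
                if o_lo != o_hi:
                    if True in (o_lo, o_hi):       # approach last-rewarded item
                        chosen_item = pair.rank_low if o_lo is True else pair.rank_high
                    else:                          # avoid last-unrewarded item
                        chosen_item = pair.rank_high if o_lo is False else pair.rank_low
            location = 0 if chosen_item == st.in_rf_item else 1
            # independent spatial win-stay / lose-shift override
            if prev_location is not None and prev_rewarded is not None:
                u = rng.uniform()
                if prev_rewarded:
                    if u < w_stay:
                        location = prev_location
                    elif u < w_stay + w_stay_shift:
                        location = 1 - prev_location
                else:
                    if u < w_shift:
                        location = 1 - prev_location
                    elif u < w_shift + w_shift_stay:
                        location = prev_location
                chosen_item = st.in_rf_item if location == 0 else (
                    pair.rank_low if st.in_rf_item == pair.rank_high else pair.rank_high
                )
            correct = chosen_item == pair.rank_low
            sd_val = pair.symbolic_distance
            latency = _truncnorm_sample(
                rng, params.rt_mu - params.rt_sd_slope * sd_val, params.rt_sigma,
                0.0, 1500.0,
            )
            sd, jr = sd_val, pair.joint_rank
            rank_low, rank_high, in_rf_item = pair.rank_low, pair.rank_high, st.in_rf_item
            single_rank = np.nan
            this_choice_idx = choice_idx

        rewarded = bool(correct)  # all correctly completed trials are rewarded
        t_saccade = t_stim + latency / 1000.0
        t_feedback = t_saccade + hold
        t_reward = t_feedback + reward_int if rewarded else np.nan
        t_end = t_feedback + reward_int + 0.2

        rows.append((
            i, st.phase, st.block, this_choice_idx,
            rank_low, rank_high, sd, jr, single_rank, in_rf_item,
            location, chosen_item, bool(correct), rewarded,
            t_fix_on, t_stim, t_saccade, t_feedback, t_reward,
            t_end, latency, bool(prev_rewarded),
        ))
        if st.phase == 2:
            item_outcome[chosen_item] = rewarded
        prev_location, prev_rewarded = location, rewarded
        t_clock = t_end + iti

    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df.attrs["n_items"] = n
    df.attrs["agent_params"] = asdict(params)
    df.attrs["rng_seed"] = rng_seed
    return df
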