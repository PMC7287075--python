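"""Behavioral analyses: learning curves, symbolic-distance effects, reaction
times, and reward-history biases.

Accuracy curves are centred 25-trial moving proportions (truncated at the
session edges), optionally per symbolic distance or per item.  Pair-level
accuracy at fixed trial points (250, 500) is estimated either by windowed
averaging or by Gaussian-process regression of the binary outcomes over
(trial, SD, JR).  The symbolic distance effect is quantified as the Pearson
correlation of per-session, per-SD accuracy with symbolic distance.  Spatial
win-stay/lose-shift and item-level reward-history biases follow the lag-1
conditional-probability definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .task import StimulusList, enumerate_pairs

__all__ = [
    "moving_accuracy",
    "accuracy_at_trial",
    "sd_performance_correlation",
    "rt_by_sd",
    "winstay_loseshift",
    "item_reward_history",
]


def _choice_trials(trials: pd.DataFrame) -> pd.DataFrame:
    ct = trials[trials["phase"] == 2].sort_values("choice_trial_index")
    return ct.reset_index(drop=True)


def moving_accuracy(
    trials: pd.DataFrame, window: int = 25, group_by: str | None = None
) -> pd.DataFrame:
    """Centred moving proportion correct over choice trials.

    ``group_by`` may be None (overall accuracy), 'sd' (per symbolic
    distance), or 'item' (probability of choosing each item when presented,
    among the trials where it appears).  Windows are truncated at the edges.
    Groups with fewer than ``window`` trials are omitted.  Returns a tidy
    frame [group, choice_trial_index, value].
    """
    ct = _choice_trials(trials)
    if len(ct) == 0:
        raise ValueError("no choice trials")

    def smooth(x: np.ndarray) -> np.ndarray:
        return (
            pd.Series(x.astype(float))
            .rolling(window, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )

    rows = []
    if group_by is None:
        if len(ct) < window:
            raise ValueError("fewer trials than the smoothing window")
        vals = smooth(ct["correct"].to_numpy())
        rows += list(zip(["all"] * len(ct), ct["choice_trial_index"], vals))
    elif group_by == "sd":
        for sd, sub in ct.groupby("sd"):
            if len(sub) < window:
                continue
            vals = smooth(sub["correct"].to_numpy())
            rows += list(zip([sd] * len(sub), sub["choice_trial_index"], vals))
    elif group_by == "item":
        n = trials.attrs.get("n_items", int(ct["rank_high"].max()))
        for item in range(1, n + 1):
            sub = ct[(ct["rank_low"] == item) | (ct["rank_high"] == item)]
            if len(sub) < window:
                continue
            chose = (sub["chosen_item"] == item).to_numpy()
            vals = smooth(chose)
            rows += list(zip([item] * len(sub), sub["choice_trial_index"], vals))
    else:
        raise ValueError(f"unknown group_by {group_by!r}")
    return pd.DataFrame(rows, columns=["group", "choice_trial_index", "value"])


def accuracy_at_trial(
    trials: pd.DataFrame,
    t: int,
    method: str = "window",
    window: int = 100,
    gpr_seed: int = 0,
) -> pd.DataFrame:
    """Per-pair accuracy estimate at choice trial ``t`` (e.g. 250 or 500).

    'window' averages each pair's outcomes within ±window/2 trials of t;
    'gpr' regresses the binary outcomes on (trial, SD, JR) with a
    squared-exponential prior and reports the posterior mean at t for each
    pair.  Returns [rank_low, rank_high, sd, jr, accuracy].
    """
    ct = _choice_trials(trials)
    if t > ct["choice_trial_index"].max():
        raise ValueError(f"trial point {t} beyond the session")
    n = trials.attrs.get("n_items", int(ct["rank_high"].max()))
    pairs = enumerate_pairs(StimulusList(n))

    if method == "window":
        lo, hi = t - window / 2, t + window / 2
        sub = ct[(ct["choice_trial_index"] >= lo) & (ct["choice_trial_index"] <= hi)]
        rows = []
        for p in pairs:
            m = (sub["rank_low"] == p.rank_low) & (sub["rank_high"] == p.rank_high)
            acc = float(sub.loc[m, "correct"].mean()) if m.any() else np.nan
            rows.append((p.rank_low, p.rank_high, p.symbolic_distance, p.joint_rank, acc))
        return pd.DataFrame(rows, columns=["rank_low", "rank_high", "sd", "jr", "accuracy"])

    if method == "gpr":
        X = ct[["choice_trial_index", "sd", "jr"]].to_numpy(float)
        y = ct["correct"].to_numpy(float)
        mu, sig = X.mean(0), X.std(0)
        sig[sig == 0] = 1.0
        kernel = ConstantKernel(0.25) * RBF([1.0, 1.0, 1.0]) + WhiteKernel(0.2)
        gp = GaussianProcessRegressor(kernel=kernel, optimizer=None, alpha=1e-6)
        rng = np.random.default_rng(gpr_seed)
        idx = (rng.choice(len(y), 1500, replace=False)
               if len(y) > 1500 else np.arange(len(y)))
        gp.fit((X[idx] - mu) / sig, y[idx] - y.mean())
        rows = []
        for p in pairs:
            xq = (np.array([[t, p.symbolic_distance, p.joint_rank]]) - mu) / sig
            acc = float(np.clip(gp.predict(xq)[0] + y.mean(), 0.0, 1.0))
            rows.append((p.rank_low, p.rank_high, p.symbolic_distance, p.joint_rank, acc))
        return pd.DataFrame(rows, columns=["rank_low", "rank_high", "sd", "jr", "accuracy"])

    raise ValueError(f"unknown method {method!r}")


def sd_performance_correlation(sessions: list[pd.DataFrame]) -> dict:
    """Pearson correlation of session-average accuracy with symbolic distance.

    The observation unit is (session, SD level): each session contributes its
    mean accuracy at each symbolic distance.  Returns r, two-sided p, r², N.
    """
    obs_sd, obs_acc = [], []
    for trials in sessions:
        ct = _choice_trials(trials)
        for sd, sub in ct.groupby("sd"):
            obs_sd.append(float(sd))
            obs_acc.append(float(sub["correct"].mean()))
    if len(obs_sd) < 3:
        raise ValueError("need at least 3 (session, SD) observations")
    if np.ptp(obs_acc) == 0:
        raise ValueError("accuracy is constant; correlation undefined")
    r, p = stats.pearsonr(obs_sd, obs_acc)
    return {"r": float(r), "p": float(p), "r2": float(r ** 2), "n": len(obs_sd)}


def rt_by_sd(sessions: list[pd.DataFrame] | pd.DataFrame) -> dict:
    """Saccade-latency means per symbolic distance with a one-way ANOVA.

    Returns per-SD mean latencies, the overall F and p, and the range
    (max − min) of the level means in ms.
    """
    if isinstance(sessions, pd.DataFrame):
        sessions = [sessions]
    ct = pd.concat([_choice_trials(s) for s in sessions], ignore_index=True)
    groups = {sd: sub["latency_ms"].to_numpy() for sd, sub in ct.groupby("sd")}
    if len(groups) < 2:
        raise ValueError("need at least two SD levels")
    f, p = stats.f_oneway(*groups.values())
    means = {float(sd): float(v.mean()) for sd, v in groups.items()}
    return {
        "means": means,
        "f": float(f),
        "p": float(p),
        "range_ms": float(max(means.values()) - min(means.values())),
        "n": int(len(ct)),
    }


def winstay_loseshift(sessions: list[pd.DataFrame] | pd.DataFrame) -> dict:
    """Spatial win-stay/lose-shift: lag-1 location-repeat probabilities.

    Per session, the probability of repeating the previous choice trial's
    location after a rewarded vs an unrewarded trial; across sessions,
    one-sample t-tests against 0.5 and Cohen's d = (mean − 0.5)/sd.
    """
    if isinstance(sessions, pd.DataFrame):
        sessions = [sessions]
    p_win, p_lose = [], []
    for trials in sessions:
        ct = _choice_trials(trials)
        if len(ct) < 2:
            raise ValueError("need at least 2 choice trials per session")
        loc = ct["chosen_location"].to_numpy()
        rew = ct["rewarded"].to_numpy(bool)
        repeat = loc[1:] == loc[:-1]
        prev_rew = rew[:-1]
        if prev_rew.any():
            p_win.append(float(repeat[prev_rew].mean()))
        if (~prev_rew).any():
            p_lose.append(float(repeat[~prev_rew].mean()))

    out: dict = {}
    for name, vals in (("after_reward", p_win), ("after_noreward", p_lose)):
        arr = np.asarray(vals)
        res: dict = {"mean": float(arr.mean()), "n": int(arr.size)}
        if arr.size > 1:
            t, p = stats.ttest_1samp(arr, 0.5)
            sd = arr.std(ddof=1)
            res.update(t=float(t), p=float(p),
                       cohens_d=float((arr.mean() - 0.5) / sd) if sd > 0 else np.inf,
                       sem=float(sd / np.sqrt(arr.size)))
        out[name] = res
    return out


def item_reward_history(sessions: list[pd.DataFrame] | pd.DataFrame) -> dict:
    """Item-level reward-history bias for non-terminal list items.

    For each (session, item) with item ranks 2..n−1: the probability of
    choosing the item when presented, conditioned on whether its most recent
    previous choice was rewarded or not; cells with an empty denominator are
    dropped and counted.  Reports the paired t-test across (session, item)
    cells and the same contrast applied to saccade latency.
    """
    if isinstance(sessions, pd.DataFrame):
        sessions = [sessions]
    rows = []
    n_dropped = 0
    for s_id, trials in enumerate(sessions):
        ct = _choice_trials(trials)
        n = trials.attrs.get("n_items", int(ct["rank_high"].max()))
        for item in range(2, n):
            avail = ct[(ct["rank_low"] == item) | (ct["rank_high"] == item)]
            chose = (avail["chosen_item"] == item).to_numpy()
            rew = avail["rewarded"].to_numpy(bool)
            lat = avail["latency_ms"].to_numpy()
            # outcome of the most recent previous choice of this item
            prev_outcome = np.full(len(avail), -1)  # -1: none yet
            last = -1
            for i in range(len(avail)):
                prev_outcome[i] = last
                if chose[i]:
                    last = int(rew[i])
            sel_r, sel_u = prev_outcome == 1, prev_outcome == 0
            if not sel_r.any() or not sel_u.any():
                n_dropped += 1
                continue
            rows.append((
                s_id, item,
                float(chose[sel_r].mean()), float(chose[sel_u].mean()),
                float(lat[sel_r].mean()), float(lat[sel_u].mean()),
            ))
    if not rows:
        raise ValueError("no (session, item) cells with both conditions defined")
    df = pd.DataFrame(rows, columns=[
        "session", "item", "p_choose_after_reward", "p_choose_after_noreward",
        "latency_after_reward", "latency_after_noreward",
    ])
    t_p, p_p = stats.ttest_rel(df["p_choose_after_reward"], df["p_choose_after_noreward"])
    t_l, p_l = stats.ttest_rel(df["latency_after_reward"], df["latency_after_noreward"])
    return {
        "table": df,
        "n_cells": int(len(df)),
        "n_dropped": int(n_dropped),
        "mean_after_reward": float(df["p_choose_after_reward"].mean()),
        "mean_after_noreward": float(df["p_choose_after_noreward"].mean()),
        "choice_t": float(t_p), "choice_p": float(p_p),
        "latency_diff_ms": float(
            (df["latency_after_reward"] - df["latency_after_noreward"]).mean()
        ),
        "latency_t": float(t_l), "latency_p": float(p_l),
    }
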