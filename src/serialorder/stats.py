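"""Resampling machinery and unit-level hypothesis tests.

Bootstrap distributions resample N observations with replacement; shuffle
(permutation) tests permute explanatory-variable labels among trials,
preserving the label multiset, with p = (1 + #{null ≥ observed}) / (1 +
n_perm).  On top of these sit the study's unit-level tests: the best/worst
stimulus-identity shuffle control, correct-vs-incorrect outcome tests
(rank-sum with η² effect sizes), a Kruskal–Wallis panel over explanatory
factors, and the previous-trial-reward firing-rate contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .task import EpochWindow, IDENTITY_WINDOW, OUTCOME_EPOCHS, EpochScheme
from .spikes import DegenerateUnitError, epoch_spike_rate, zscore_rates

__all__ = [
    "ShuffleResult",
    "bootstrap_distribution",
    "shuffle_test",
    "best_worst_identity_test",
    "outcome_effect_tests",
    "kruskal_effect_panel",
    "prior_reward_neural_test",
]


@dataclass
class ShuffleResult:
    observed: float
    null_distribution: np.ndarray
    p_value: float
    n_permutations: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0
        assert self.null_distribution.size == self.n_permutations


def bootstrap_distribution(
    observations: np.ndarray,
    statistic=np.mean,
    n: int = 10_000,
    rng_seed: int = 0,
    ci: float = 95.0,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Bootstrap distribution of a statistic with a percentile CI.

    Draws N-with-replacement resamples of the N observations ``n`` times.
    Returns (distribution, (ci_lo, ci_hi)); deterministic given the seed.
    """
    obs = np.asarray(observations)
    if obs.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(0, obs.shape[0], size=(n, obs.shape[0]))
    dist = np.array([statistic(obs[row]) for row in idx])
    half = (100.0 - ci) / 2.0
    lo, hi = np.percentile(dist, [half, 100.0 - half])
    return dist, (float(lo), float(hi))


def shuffle_test(
    labels: np.ndarray,
    responses: np.ndarray,
    statistic,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> ShuffleResult:
    """Permutation test of statistic(labels, responses).

    Labels are permuted among trials (multiset preserved); the one-sided
    p-value uses the add-one convention, never exactly zero.
    """
    labels = np.asarray(labels)
    responses = np.asarray(responses)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two label levels")
    rng = np.random.default_rng(rng_seed)
    observed = float(statistic(labels, responses))
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = statistic(rng.permutation(labels), responses)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return ShuffleResult(observed, null, float(p), n_perm)


# ---------------------------------------------------------------------------
# Best/worst stimulus identity test
# ---------------------------------------------------------------------------

def _best_worst(z: np.ndarray, items: np.ndarray) -> tuple[float, float] | None:
    """Mean z of the best (argmax) and worst (argmin) stimulus.

    Ties break toward the lower stimulus rank (np.unique returns sorted
    levels and argmax/argmin take the first maximum/minimum).
    """
    levels = np.unique(items)
    means = np.array([z[items == lv].mean() for lv in levels])
    return float(means.max()), float(means.min())


def best_worst_identity_test(
    units: list[tuple[np.ndarray, pd.DataFrame]],
    phase: str = "single",
    window: EpochWindow = IDENTITY_WINDOW,
    learning_trials: int = 250,
    rng_seed: int = 0,
) -> dict:
    """Observed vs label-shuffled best/worst stimulus responses across units.

    ``units`` is a list of (spike times, full trial table).  ``phase``
    selects the trials: 'single' (phase-1 presentations, stimulus = the
    presented item), 'early-choice' (first ``learning_trials`` choice trials,
    stimulus = the in-RF item) or 'late-choice' (the rest).  Per unit, z
    rates in the visual identity window give the best (argmax) and worst
    (argmin) stimulus means, observed and with stimulus labels shuffled among
    trials; across units a paired t-test compares the observed and shuffled
    best−worst differences.  Units missing a stimulus in the phase are
    excluded.
    """
    rng = np.random.default_rng(rng_seed)
    obs_diff, shuf_diff = [], []
    obs_best, obs_worst, shuf_best, shuf_worst = [], [], [], []
    n_excluded = 0
    for spikes, trials in units:
        if phase == "single":
            # in-RF presentations only: mixing in- and out-of-field trials
            # would let the label shuffle break the spatial balance and bias
            # the shuffled best-worst difference upward
            sub = trials[(trials["phase"] == 1) & (trials["chosen_location"] == 0)]
            items = sub["single_rank"].to_numpy()
        else:
            ct = trials[trials["phase"] == 2]
            early = ct["choice_trial_index"] <= learning_trials
            sub = ct[early] if phase == "early-choice" else ct[~early]
            items = sub["in_rf_item"].to_numpy()
        n_items = trials.attrs.get("n_items", 7)
        if np.unique(items).size < n_items:
            n_excluded += 1
            continue
        rates = epoch_spike_rate(spikes, sub, window)
        try:
            z, _ = zscore_rates(rates)
        except DegenerateUnitError:
            n_excluded += 1  # silent in the window
            continue
        b, w = _best_worst(z, items)
        sb, sw = _best_worst(z, rng.permutation(items))
        obs_best.append(b)
        obs_worst.append(w)
        shuf_best.append(sb)
        shuf_worst.append(sw)
        obs_diff.append(b - w)
        shuf_diff.append(sb - sw)
    if len(obs_diff) < 2:
        raise ValueError("need at least two units with all stimuli sampled")
    t, p = sps.ttest_rel(obs_diff, shuf_diff)
    return {
        "phase": phase,
        "n_units": len(obs_diff),
        "n_excluded": n_excluded,
        "observed_best": float(np.mean(obs_best)),
        "observed_worst": float(np.mean(obs_worst)),
        "shuffled_best": float(np.mean(shuf_best)),
        "shuffled_worst": float(np.mean(shuf_worst)),
        "mean_diff_obs": float(np.mean(obs_diff)),
        "mean_diff_shuf": float(np.mean(shuf_diff)),
        "t": float(t),
        "p": float(p),
    }


# ---------------------------------------------------------------------------
# Outcome and explanatory-variable tests
# ---------------------------------------------------------------------------

def _rank_eta2(u_stat: float, n1: int, n2: int) -> float:
    """η² for a rank-sum test via the normal approximation, z²/N."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    sigma = np.sqrt(n1 * n2 * (n + 1) / 12.0)
    if sigma == 0:
        return 0.0
    z = (u_stat - mu) / sigma
    return float(z ** 2 / n)


def outcome_effect_tests(
    units: list[tuple[np.ndarray, pd.DataFrame]],
    scheme: EpochScheme = OUTCOME_EPOCHS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correct-vs-incorrect rank-sum test per unit and epoch.

    Spike rates on choice trials are compared between correct and incorrect
    outcomes (two-sided Wilcoxon rank-sum / Mann-Whitney); effect size is η².
    Units with a single outcome present are skipped.  Returns a tidy frame
    with one row per unit × epoch plus 'significant' at the given alpha.
    """
    rows = []
    for uid, (spikes, trials) in enumerate(units):
        ct = trials[trials["phase"] == 2]
        outcome = ct["correct"].to_numpy(bool)
        if outcome.all() or not outcome.any():
            continue
        for name, window in scheme.items():
            rates = epoch_spike_rate(spikes, ct, window)
            ok = np.isfinite(rates)
            a, b = rates[ok & outcome], rates[ok & ~outcome]
            if a.size < 2 or b.size < 2 or np.ptp(rates[ok]) == 0:
                continue
            u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            rows.append((uid, name, float(u), float(p),
                         _rank_eta2(u, a.size, b.size), bool(p < alpha)))
    df = pd.DataFrame(rows, columns=["unit_id", "epoch", "u", "p", "eta2", "significant"])
    return df


def kruskal_effect_panel(
    units: list[tuple[np.ndarray, pd.DataFrame]],
    window: EpochWindow = IDENTITY_WINDOW,
    factors: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kruskal–Wallis test per unit and explanatory factor.

    Default factors map onto trial-table columns: target location (in-RF item
    position on single trials → 'chosen_location'), saccade direction
    ('chosen_location' on choice trials), and outcome ('correct').  Effect
    size is the generalized η²_H = (H − k + 1)/(n − k).  Single-level factors
    are skipped.
    """
    if factors is None:
        factors = {
            "target_location": "chosen_location",
            "saccade_direction": "chosen_location",
            "outcome": "correct",
        }
    rows = []
    for uid, (spikes, trials) in enumerate(units):
        for fname, col in factors.items():
            sub = trials[trials["phase"] == 1] if fname == "target_location" \
                else trials[trials["phase"] == 2]
            rates = epoch_spike_rate(spikes, sub, window)
            ok = np.isfinite(rates)
            labels = sub[col].to_numpy()[ok]
            vals = rates[ok]
            levels = np.unique(labels)
            if levels.size < 2:
                continue
            groups = [vals[labels == lv] for lv in levels]
            if any(len(g) < 2 for g in groups) or np.ptp(vals) == 0:
                continue
            h, p = sps.kruskal(*groups)
            k, n = levels.size, vals.size
            eta2 = max(0.0, (h - k + 1) / (n - k))
            rows.append((uid, fname, float(h), float(p), float(eta2), bool(p < alpha)))
    return pd.DataFrame(rows, columns=["unit_id", "factor", "h", "p", "eta2", "significant"])


def prior_reward_neural_test(
    units: list[tuple[np.ndarray, pd.DataFrame]],
) -> dict:
    """Previous-trial-reward effect on stimulus→saccade firing rate.

    Per unit and per saccade direction (toward the RF, location 0, vs away),
    the mean rate between stimulus onset and the choice saccade is contrasted
    between trials following a rewarded vs an unrewarded trial (the first
    choice trial, lacking a predecessor, is excluded).  Across units, a
    one-sample t-test of the per-unit differences.
    """
    window = EpochWindow("stimulus", 0.0, end_ms=0.0, end_align="saccade")
    diffs = {"toward": [], "away": []}
    for spikes, trials in units:
        ct = trials[trials["phase"] == 2].reset_index(drop=True)
        rates = epoch_spike_rate(spikes, ct, window)
        prev_rew = ct["rewarded"].to_numpy(bool)[:-1]
        rates = rates[1:]
        loc = ct["chosen_location"].to_numpy()[1:]
        for name, sel in (("toward", loc == 0), ("away", loc == 1)):
            a = rates[sel & prev_rew]
            b = rates[sel & ~prev_rew]
            if a.size >= 2 and b.size >= 2:
                diffs[name].append(float(np.nanmean(a) - np.nanmean(b)))
    out = {}
    for name, vals in diffs.items():
        arr = np.asarray(vals)
        res = {"mean_diff_hz": float(arr.mean()), "n": int(arr.size)}
        if arr.size > 1:
            t, p = sps.ttest_1samp(arr, 0.0)
            res.update(t=float(t), p=float(p))
        out[name] = res
    return out
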