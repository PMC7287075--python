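"""Variance accounted for (VAC) by joint rank and symbolic distance.

Per unit and epoch, spike trains are binned into 10-ms counts, smoothed with
Gaussian-process regression over (trial, time, joint rank, symbolic
distance) — a squared-exponential kernel with per-dimension length-scales on
variance-stabilised (square-root) counts, which keeps the GP exact — and
averaged within each epoch.  After subtracting the baseline epoch per trial,
the degree of tuning to each variable is quantified as partial eta-squared,
η²p = F·df1 / (F·df1 + df2), with F and degrees of freedom from Welch's
one-way ANOVA for groups with unequal variances.  η²p measures how much
variance a variable accounts for without assuming any functional form of the
tuning; JR and SD enter the kernel as continuous inputs so that trials at
similar times with similar JR/SD share statistical strength.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .task import EpochScheme, EpochWindow, VAC_EPOCHS
from .spikes import _window_bounds

__all__ = [
    "GprSpec",
    "VacResult",
    "bin_counts",
    "gpr_smooth",
    "welch_anova_oneway",
    "welch_partial_eta2",
    "vac_for_unit",
    "vac_scatter",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GprSpec:
    """Gaussian-process smoothing configuration.

    Inputs are standardised per dimension; length-scales start at the median
    heuristic (1.0 on standardised inputs).  ``optimize`` turns on marginal-
    likelihood hyperparameter fitting; ``max_points`` caps the number of
    training points (seeded subsample) to bound the exact-GP cost.
    """

    bin_ms: float = 10.0
    length_scales: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    optimize: bool = False
    max_points: int = 1500
    # sqrt-transformed Poisson counts have variance ≈ 1/4, the default
    # observation-noise level of the Gaussian GP
    noise_level: float = 0.25
    signal_variance: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(ls <= 0 for ls in self.length_scales):
            raise ValueError("length-scales must be positive")


@dataclass(frozen=True)
class VacResult:
    """Welch F, degrees of freedom, and partial eta-squared for one
    unit × epoch × variable."""

    unit_id: int
    epoch: str
    variable: str
    f_stat: float
    df1: float
    df2: float
    eta_p2: float


def bin_counts(
    spike_times: np.ndarray,
    trials: pd.DataFrame,
    window: EpochWindow,
    bin_ms: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike-count tensor over (trial, 10-ms bin) for a peri-event window.

    Returns (counts, bin centre times in ms relative to the aligning event).
    The bin count sum equals the total number of in-window spikes.
    """
    spike_times = np.asarray(spike_times, float)
    n_bins = int(round((window.end_ms - window.start_ms) / bin_ms))
    edges_ms = window.start_ms + bin_ms * np.arange(n_bins + 1)
    centers = 0.5 * (edges_ms[:-1] + edges_ms[1:])
    anchor = {"stimulus": "t_stimulus_on", "saccade": "t_saccade"}[window.align]
    events = trials[anchor].to_numpy(float)
    counts = np.zeros((len(trials), n_bins), dtype=int)
    for i, t_event in enumerate(events):
        if not np.isfinite(t_event):
            continue
        edges_s = t_event + edges_ms / 1000.0
        counts[i] = np.diff(np.searchsorted(spike_times, edges_s))
    return counts, centers


def gpr_smooth(
    counts: np.ndarray,
    bin_centers_ms: np.ndarray,
    trial_index: np.ndarray,
    jr: np.ndarray,
    sd: np.ndarray,
    spec: GprSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """GP-smoothed firing rate over (trial, time, JR, SD).

    ``counts`` is (n_trials, n_bins); ``trial_index``, ``jr``, ``sd`` are per
    trial.  The GP is fit to sqrt(counts) (variance stabilised, Gaussian
    observation model) and evaluated at every training point.  Returns
    (posterior mean rate in sp/s, posterior SD on the sqrt-count scale), both
    shaped like ``counts``.  Falls back to fixed median-heuristic
    length-scales if hyperparameter optimisation fails.
    """
    spec = spec or GprSpec()
    counts = np.asarray(counts, float)
    n_trials, n_bins = counts.shape
    for name, v in (("jr", jr), ("sd", sd)):
        if np.unique(v).size < 2:
            raise ValueError(f"need at least 2 levels of {name}")

    tt, bb = np.meshgrid(np.arange(n_trials), np.arange(n_bins), indexing="ij")
    X = np.column_stack([
        np.asarray(trial_index, float)[tt.ravel()],
        np.asarray(bin_centers_ms, float)[bb.ravel()],
        np.asarray(jr, float)[tt.ravel()],
        np.asarray(sd, float)[tt.ravel()],
    ])
    y = np.sqrt(counts).ravel()

    mu = X.mean(axis=0)
    sig = X.std(axis=0)
    sig[sig == 0] = 1.0
    Xs = (X - mu) / sig
    y_mean = y.mean()

    rng = np.random.default_rng(spec.rng_seed)
    if Xs.shape[0] > spec.max_points:
        train = rng.choice(Xs.shape[0], spec.max_points, replace=False)
    else:
        train = np.arange(Xs.shape[0])

    kernel = (
        ConstantKernel(spec.signal_variance)
        * RBF(length_scale=np.asarray(spec.length_scales))
        + WhiteKernel(noise_level=spec.noise_level)
    )
    gp = GaussianProcessRegressor(
        kernel=kernel,
        optimizer="fmin_l_bfgs_b" if spec.optimize else None,
        normalize_y=False,
        alpha=1e-8,
    )
    try:
        gp.fit(Xs[train], y[train] - y_mean)
    except Exception:  # pragma: no cover - optimiser failure path
        log.warning("gpr_smooth: hyperparameter fit failed; median-heuristic fallback")
        gp = GaussianProcessRegressor(kernel=kernel, optimizer=None, alpha=1e-8)
        gp.fit(Xs[train], y[train] - y_mean)
    post_mean, post_sd = gp.predict(Xs, return_std=True)
    post_mean = post_mean + y_mean
    rate_hz = np.clip(post_mean, 0.0, None) ** 2 / (
        np.mean(np.diff(bin_centers_ms)) / 1000.0 if n_bins > 1 else spec.bin_ms / 1000.0
    )
    return rate_hz.reshape(counts.shape), post_sd.reshape(counts.shape)


# ---------------------------------------------------------------------------
# Welch ANOVA and partial eta-squared
# ---------------------------------------------------------------------------

def welch_anova_oneway(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """Welch's one-way ANOVA for unequal variances: returns (F, df1, df2)."""
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    n = np.array([len(g) for g in groups], float)
    if np.any(n < 2):
        bad = [i for i, g in enumerate(groups) if len(g) < 2]
        raise ValueError(f"groups {bad} have fewer than 2 observations")
    m = np.array([np.mean(g) for g in groups])
    v = np.array([np.var(g, ddof=1) for g in groups])
    if np.any(v == 0):
        bad = [i for i, var in enumerate(v) if var == 0]
        raise ValueError(f"groups {bad} have zero variance")
    w = n / v
    w_sum = w.sum()
    m_bar = (w * m).sum() / w_sum
    a = (w * (m - m_bar) ** 2).sum() / (k - 1)
    r = ((1 - w / w_sum) ** 2 / (n - 1)).sum()
    b = 1 + 2.0 * (k - 2) / (k ** 2 - 1) * r
    f = a / b
    df1 = k - 1.0
    df2 = (k ** 2 - 1.0) / (3.0 * r)
    return float(f), float(df1), float(df2)


def partial_eta_squared(f: float, df1: float, df2: float) -> float:
    """η²p = F·df1 / (F·df1 + df2); lies in [0, 1] for F ≥ 0."""
    return float(f * df1 / (f * df1 + df2))


def welch_partial_eta2(
    values: np.ndarray,
    labels: np.ndarray,
    baseline: np.ndarray | None = None,
    unit_id: int = 0,
    epoch: str = "",
    variable: str = "",
) -> VacResult:
    """VAC for one variable: Welch F across levels of baseline-subtracted
    per-trial epoch rates, expressed as partial eta-squared."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    if baseline is not None:
        values = values - np.asarray(baseline, float)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    groups = [values[labels == lv] for lv in np.unique(labels)]
    f, df1, df2 = welch_anova_oneway(groups)
    return VacResult(unit_id, epoch, variable, f, df1, df2,
                     partial_eta_squared(f, df1, df2))


def vac_for_unit(
    spike_times: np.ndarray,
    choice_trials: pd.DataFrame,
    scheme: EpochScheme = VAC_EPOCHS,
    spec: GprSpec | None = None,
    unit_id: int = 0,
    baseline_epoch: str = "baseline",
    variables: tuple[str, ...] = ("jr", "sd"),
) -> list[VacResult]:
    """Full VAC pipeline for one unit.

    For every epoch in ``scheme``: 10-ms bin counts → GP smoothing over
    (trial, time, JR, SD) → epoch-averaged per-trial rate.  The baseline
    epoch mean is subtracted per trial from every other epoch, and Welch
    partial eta-squared is computed per variable and epoch.
    """
    spec = spec or GprSpec()
    jr = choice_trials["jr"].to_numpy(float)
    sd = choice_trials["sd"].to_numpy(float)
    tr = choice_trials["choice_trial_index"].to_numpy(float)

    epoch_rates: dict[str, np.ndarray] = {}
    for name, window in scheme.items():
        counts, centers = bin_counts(spike_times, choice_trials, window, spec.bin_ms)
        rate, _ = gpr_smooth(counts, centers, tr, jr, sd, spec)
        epoch_rates[name] = rate.mean(axis=1)

    baseline = epoch_rates.get(baseline_epoch)
    results: list[VacResult] = []
    for name in scheme:
        if name == baseline_epoch:
            continue
        for var, levels in (("jr", jr), ("sd", sd)):
            if var not in variables:
                continue
            results.append(welch_partial_eta2(
                epoch_rates[name], levels, baseline,
                unit_id=unit_id, epoch=name, variable=var,
            ))
    return results


def vac_scatter(
    results: list[VacResult] | pd.DataFrame,
    epoch: str,
    preferred_jr: dict[int, float] | None = None,
    exclude_extreme_jr: bool = False,
) -> dict:
    """Paired per-unit VAC(JR) vs VAC(SD) summary for one epoch.

    Returns the paired table, Spearman rank correlation, and counts of units
    with JR > SD and SD > JR.  With ``exclude_extreme_jr`` units whose
    preferred joint rank (from ``preferred_jr``) is 3 or 13 are dropped
    before the comparison.
    """
    if isinstance(results, list):
        df = pd.DataFrame([vars(r) for r in results])
    else:
        df = results.copy()
    df = df[df["epoch"] == epoch]
    wide = df.pivot(index="unit_id", columns="variable", values="eta_p2")
    if not {"jr", "sd"} <= set(wide.columns):
        raise ValueError("both jr and sd VAC required per unit")
    wide = wide.dropna()
    if exclude_extreme_jr:
        if preferred_jr is None:
            raise ValueError("exclude_extreme_jr requires preferred_jr")
        keep = [u for u in wide.index if preferred_jr.get(u) not in (3, 13)]
        wide = wide.loc[keep]
    r_s, p = spearmanr(wide["jr"], wide["sd"])
    return {
        "table": wide.reset_index(),
        "spearman_r": float(r_s),
        "p_value": float(p),
        "n_jr_gt_sd": int((wide["jr"] > wide["sd"]).sum()),
        "n_sd_gt_jr": int((wide["sd"] > wide["jr"]).sum()),
    }
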