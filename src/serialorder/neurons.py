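"""Synthetic parietal units: tuned inhomogeneous-Poisson spike generators.

Each unit belongs to one of six temporal-profile families (visual transient,
visual sustained, presaccadic ramp, postsaccadic, suppressed, tonic), has a
receptive field at one of the two target locations, and may be modulated by
joint rank (JR), symbolic distance (SD), the rank of the in-RF item (a
transient code that ramps up and decays over learning), and trial outcome.

The response to a single stimulus is softplus(baseline + amplitude ·
template(t) · spatial gain · (1 + modulations)); the response to a pair of
stimuli is the average of the two single-stimulus responses ("response
averaging"), evaluated pointwise in time.  The default 2× in-RF spatial gain
reproduces the characteristic ~2:1 in- vs out-of-field response ratio.

Spikes are drawn from the rate function on a 1 ms grid (per-bin Poisson
counts with uniform within-bin placement, i.e. an inhomogeneous Poisson
process with piecewise-constant rate), plus an optional 1 kHz synthetic eye
trace per session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

__all__ = [
    "CLUSTER_FAMILIES",
    "NeuronParams",
    "SpikeTrainSet",
    "rate_function",
    "simulate_unit",
    "sample_population",
    "generate_eye_trace",
    "rank_code",
]

CLUSTER_FAMILIES = (
    "visual_transient",
    "visual_sustained",
    "presaccadic",
    "postsaccadic",
    "suppressed",
    "tonic",
)

_DT = 0.001  # s; rate-function grid and spike-sampling resolution


def _alpha(x: np.ndarray, tau: float) -> np.ndarray:
    """Alpha function (x/tau)·exp(1 − x/tau) for x > 0, else 0; peak 1 at tau."""
    x = np.asarray(x, float)
    out = np.where(x > 0, (x / tau) * np.exp(1.0 - x / tau), 0.0)
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def template_drive(family: str, t: np.ndarray, t_stim: float, t_sacc: float) -> np.ndarray:
    """Normalized temporal drive of a family at absolute times ``t`` (s).

    Shapes were chosen to be mutually distinguishable (pairwise profile
    correlation well below the 0.7 cluster-membership cutoff) while covering
    the qualitative response types seen in parietal recordings.
    """
    ts = t - t_stim
    tk = t - t_sacc
    if family == "visual_transient":
        return _alpha(ts - 0.04, 0.03)
    if family == "visual_sustained":
        return _sigmoid((ts - 0.07) / 0.015) * _sigmoid(-(tk - 0.15) / 0.04)
    if family == "presaccadic":
        ramp = np.clip((tk + 0.6) / 0.6, 0.0, 1.0) ** 2
        return ramp * _sigmoid(-tk / 0.01)
    if family == "postsaccadic":
        return _alpha(tk - 0.03, 0.08)
    if family == "suppressed":
        return -0.8 * _sigmoid((ts - 0.05) / 0.02) * _sigmoid(-(tk - 0.25) / 0.06)
    if family == "tonic":
        # anticipatory: on from fixation, slow decay through the trial
        return _sigmoid((ts + 0.45) / 0.05) * np.exp(-np.maximum(ts + 0.3, 0.0) / 0.5)
    raise ValueError(f"unknown temporal family {family!r}")


def rank_code(rank: float, n_items: int = 7) -> float:
    """Signed linear rank code, zero-mean over the list, range [−1, 1]."""
    return (rank - (n_items + 1) / 2.0) / ((n_items - 1) / 2.0)


@dataclass(frozen=True)
class NeuronParams:
    """Generative parameters of one synthetic unit.

    jr_weights has 11 entries (JR levels 3..13), sd_weights 6 entries (SD
    levels 1..6); both are fractional rate modulations.  rank_amp sets the
    peak of the transient rank-coding gain, which follows an alpha-function
    schedule over choice trials (peak near ``rank_tau`` trials, →0 well after
    the ~250-trial learning plateau).  outcome_gain (default 0) adds a
    post-feedback drive on rewarded trials.
    """

    cluster_id: str = "visual_transient"
    baseline_hz: float = 3.0
    amp_hz: float = 40.0
    spatial_gain: float = 2.0
    jr_weights: tuple[float, ...] = (0.0,) * 11
    sd_weights: tuple[float, ...] = (0.0,) * 6
    rank_amp: float = 0.0
    rank_tau: float = 80.0
    tuning_tau: float | None = 80.0
    outcome_gain: float = 0.0
    # additive drive (Hz) on trials that follow a rewarded trial; default 0,
    # matching the absence of reward-history modulation in parietal data
    history_gain_hz: float = 0.0
    rf_location: int = 0
    n_items: int = 7
    unit_id: int = 0

    def __post_init__(self) -> None:
        if len(self.jr_weights) != 11:
            raise ValueError("jr_weights must have 11 entries (JR 3..13)")
        if len(self.sd_weights) != 6:
            raise ValueError("sd_weights must have 6 entries (SD 1..6)")
        if self.cluster_id not in CLUSTER_FAMILIES:
            raise ValueError(f"unknown cluster_id {self.cluster_id!r}")

    def rank_gain(self, choice_trial: float) -> float:
        """Transient rank-tuning amplitude at a given choice-trial index."""
        if choice_trial <= 0 or self.rank_amp == 0.0:
            return 0.0
        x = choice_trial / self.rank_tau
        return self.rank_amp * x * np.exp(1.0 - x)

    def tuning_ramp(self, choice_trial: float) -> float:
        """Saturating growth of JR/SD tuning with learning (stable after
        the ~250-trial plateau); 1.0 when ``tuning_tau`` is None."""
        if self.tuning_tau is None:
            return 1.0
        return 1.0 - float(np.exp(-max(choice_trial, 0.0) / self.tuning_tau))


@dataclass
class SpikeTrainSet:
    """Per-unit spike times (s, session clock) plus unit metadata."""

    spike_times: np.ndarray
    params: NeuronParams

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, float)
        if st.size and (np.any(np.diff(st) < 0) or st[0] < 0):
            raise ValueError("spike times must be sorted and nonnegative")
        self.spike_times = st


def _single_stim_drive(
    unit: NeuronParams,
    t: np.ndarray,
    trial: pd.Series,
    rank: float,
    in_rf: bool,
    modulation: float,
) -> np.ndarray:
    tmpl = template_drive(unit.cluster_id, t, trial["t_stimulus_on"], trial["t_saccade"])
    spatial = unit.spatial_gain if in_rf else 1.0
    rank_term = 0.0
    if in_rf and not np.isnan(trial.get("choice_trial_index", np.nan)):
        gain = unit.rank_gain(float(trial["choice_trial_index"]))
        rank_term = gain * rank_code(rank, unit.n_items)
    elif in_rf and trial["phase"] == 1:
        # phase 1 precedes learning: no rank code
        rank_term = 0.0
    return unit.amp_hz * tmpl * spatial * (1.0 + modulation + rank_term)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def rate_function(unit: NeuronParams, trial: pd.Series, t: np.ndarray) -> np.ndarray:
    """Firing rate (Hz) of ``unit`` at absolute session times ``t`` in a trial.

    Pair (choice) trials return the pointwise mean of the two single-stimulus
    rates, each computed with the trial's JR/SD modulation; single-stimulus
    trials use only the presented item's drive.
    """
    t = np.asarray(t, float)
    outcome_drive = 0.0
    if unit.outcome_gain != 0.0 and bool(trial["rewarded"]):
        outcome_drive = unit.outcome_gain * unit.amp_hz * _alpha(
            t - trial["t_feedback"] - 0.05, 0.08
        )
    if unit.history_gain_hz != 0.0 and bool(trial.get("prev_rewarded", False)):
        outcome_drive = outcome_drive + unit.history_gain_hz
    if trial["phase"] == 1:
        drive = _single_stim_drive(
            unit, t, trial, trial["single_rank"], bool(trial["chosen_location"] == 0),
            modulation=0.0,
        )
        return _softplus(unit.baseline_hz + drive + outcome_drive)
    jr = int(trial["jr"])
    sd = int(trial["sd"])
    ramp = unit.tuning_ramp(float(trial["choice_trial_index"]))
    modulation = ramp * (unit.jr_weights[jr - 3] + unit.sd_weights[sd - 1])
    in_rf_item = int(trial["in_rf_item"])
    other = int(trial["rank_low"]) if in_rf_item == int(trial["rank_high"]) else int(trial["rank_high"])
    r_in = _softplus(
        unit.baseline_hz
        + _single_stim_drive(unit, t, trial, in_rf_item, True, modulation)
        + outcome_drive
    )
    r_out = _softplus(
        unit.baseline_hz
        + _single_stim_drive(unit, t, trial, other, False, modulation)
        + outcome_drive
    )
    return 0.5 * (r_in + r_out)


def simulate_unit(
    unit: NeuronParams,
    trials: pd.DataFrame,
    rng_seed: int = 0,
    pre_s: float = 0.4,
) -> SpikeTrainSet:
    """Sample a session's spike train for one unit.

    Rates are evaluated on a 1 ms grid from ``pre_s`` before fixation onset to
    trial end; bin counts are Poisson(rate·dt) with uniform within-bin spike
    placement (exact for the piecewise-constant rate).  Deterministic given
    the seed.  Spikes are emitted only within trial spans.
    """
    if len(trials) == 0:
        raise ValueError("trials must be nonempty")
    rng = np.random.default_rng(rng_seed)
    all_spikes: list[np.ndarray] = []
    for _, trial in trials.iterrows():
        t0 = trial["t_fix_on"] - pre_s
        t1 = trial["t_trial_end"]
        grid = np.arange(t0, t1, _DT)
        rate = rate_function(unit, trial, grid + 0.5 * _DT)
        counts = rng.poisson(rate * _DT)
        nz = np.nonzero(counts)[0]
        if nz.size:
            reps = counts[nz]
            starts = np.repeat(grid[nz], reps)
            spikes = starts + rng.uniform(0.0, _DT, size=starts.size)
            all_spikes.append(np.sort(spikes))
    times = np.concatenate(all_spikes) if all_spikes else np.empty(0)
    return SpikeTrainSet(np.sort(times), unit)


def sample_population(
    n_units: int,
    rng_seed: int = 0,
    jr_amp: float = 0.35,
    sd_amp: float = 0.15,
    rank_amp: float = 0.0,
    rank_fraction: float = 0.5,
    outcome_gain: float = 0.0,
    n_items: int = 7,
) -> list[NeuronParams]:
    """Draw a heterogeneous population covering all six temporal families.

    Units cycle through the families; each gets a lognormal baseline, a
    Gaussian JR tuning bump at a random preferred level (amplitude jr_amp), a
    monotone SD modulation with amplitude ~sd_amp (sign mostly positive, i.e.
    most units fire more for larger symbolic distance), and — for a
    ``rank_fraction`` subset — a transient rank code of amplitude rank_amp.
    """
    rng = np.random.default_rng(rng_seed)
    jr_levels = np.arange(3, 14, dtype=float)
    sd_levels = np.arange(1, 7, dtype=float)
    units = []
    for i in range(n_units):
        family = CLUSTER_FAMILIES[i % len(CLUSTER_FAMILIES)]
        baseline = float(rng.lognormal(mean=np.log(3.0), sigma=0.4))
        if family == "suppressed":
            baseline += 8.0  # room to suppress below
        pref_jr = float(rng.uniform(3, 13))
        width = float(rng.uniform(1.5, 3.5))
        jr_w = jr_amp * np.exp(-0.5 * ((jr_levels - pref_jr) / width) ** 2)
        jr_w -= jr_w.mean()
        sd_sign = 1.0 if rng.uniform() < 0.75 else -1.0
        sd_w = sd_sign * sd_amp * (sd_levels - sd_levels.mean()) / 2.5
        has_rank = rng.uniform() < rank_fraction
        units.append(NeuronParams(
            cluster_id=family,
            baseline_hz=baseline,
            amp_hz=float(rng.uniform(30.0, 50.0)),
            jr_weights=tuple(jr_w),
            sd_weights=tuple(sd_w),
            rank_amp=rank_amp if has_rank else 0.0,
            outcome_gain=outcome_gain,
            rf_location=0,
            n_items=n_items,
            unit_id=i,
        ))
    return units


# ---------------------------------------------------------------------------
# Synthetic eye traces
# ---------------------------------------------------------------------------

def generate_eye_trace(
    trials: pd.DataFrame,
    rng_seed: int = 0,
    eccentricity_deg: float = 10.0,
    sample_rate_hz: float = 1000.0,
    jitter_deg: float = 0.05,
    saccade_scale_ms: float = 5.0,
    detect_threshold: float = 30.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """1 kHz horizontal/vertical eye positions for a session.

    The eye fixates the centre with small smoothed jitter; at each trial's
    saccade time the position follows a logistic step of amplitude equal to
    the target eccentricity toward the chosen location (location 0 at
    +eccentricity on the horizontal axis, location 1 diametrically opposite),
    returning to centre at trial end.  The logistic is centred so that radial
    speed first crosses ``detect_threshold`` at the nominal saccade time,
    which is what a threshold detector defines as saccade onset.

    Returns (t, h, v) with t in seconds on the session clock.
    """
    dt = 1.0 / sample_rate_hz
    t_end = float(trials["t_trial_end"].iloc[-1]) + 0.5
    t = np.arange(0.0, t_end, dt)
    h = np.zeros_like(t)
    v = np.zeros_like(t)

    s = saccade_scale_ms / 1000.0
    # logistic position x(t) = A·sigmoid((t − tc)/s); speed A/(4s) at centre.
    # Solve for the offset u0 < 0 where speed == threshold, and centre the
    # sigmoid at (saccade time − s·u0) so the threshold crossing lands on it.
    amp = eccentricity_deg
    vmax = amp / s  # deg/s times sigmoid'(0)=0.25 → peak amp/(4s)
    q = detect_threshold / vmax  # = sigmoid(u)(1−sigmoid(u))
    sig = 0.5 * (1.0 - np.sqrt(max(0.0, 1.0 - 4.0 * q)))
    u0 = float(np.log(sig / (1.0 - sig)))
    for _, trial in trials.iterrows():
        target = amp if trial["chosen_location"] == 0 else -amp
        tc = trial["t_saccade"] - s * u0
        seg = (t >= trial["t_stimulus_on"]) & (t < trial["t_trial_end"])
        h[seg] += target * _sigmoid((t[seg] - tc) / s)
        # return to centre at trial end
        back = (t >= trial["t_trial_end"]) & (t < trial["t_trial_end"] + 0.2)
        h[back] += target * _sigmoid(-(t[back] - trial["t_trial_end"] - 0.05) / s)

    rng = np.random.default_rng(rng_seed)
    if jitter_deg > 0:
        from scipy.ndimage import gaussian_filter1d

        h += gaussian_filter1d(rng.normal(0, jitter_deg, t.size), 15.0)
        v += gaussian_filter1d(rng.normal(0, jitter_deg, t.size), 15.0)
    return t, h, v
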