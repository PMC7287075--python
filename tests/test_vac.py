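"""Variance accounted for: binning, GP smoothing, Welch partial eta-squared."""

import numpy as np
import pandas as pd
import pytest

import serialorder as so
from serialorder.vac import partial_eta_squared, welch_anova_oneway

from conftest import make_trials_df


def test_bin_counts_conservation(small_session, default_unit_spikes):
    spikes = default_unit_spikes[0].spike_times
    window = so.EpochWindow("stimulus", -250, 0)
    counts, centers = so.bin_counts(spikes, small_session, window)
    assert counts.shape == (len(small_session), 25)
    assert np.allclose(np.diff(centers), 10.0)
    rates = so.epoch_spike_rate(spikes, small_session, window)
    assert np.array_equal(counts.sum(axis=1), np.round(rates * 0.25).astype(int))


def test_bin_counts_trivial_cases():
    trials = make_trials_df([10.0])
    window = so.EpochWindow("stimulus", 0, 100)
    counts, _ = so.bin_counts(np.empty(0), trials, window)
    assert counts.sum() == 0
    counts, _ = so.bin_counts(np.array([10.055]), trials, window)
    assert counts.sum() == 1 and counts[0, 5] == 1


def test_partial_eta_squared_formula():
    assert partial_eta_squared(1.0, 1.0, 10.0) == pytest.approx(1.0 / 11.0)
    assert partial_eta_squared(0.0, 2.0, 20.0) == 0.0


def test_welch_two_groups_equals_t_squared():
    """For two groups Welch's F equals the squared Welch t statistic."""
    from scipy import stats
    rng = np.random.default_rng(0)
    for _ in range(100):
        a = rng.normal(0, 1, rng.integers(5, 30))
        b = rng.normal(rng.normal(), 2, rng.integers(5, 30))
        f, df1, df2 = welch_anova_oneway([a, b])
        t, _ = stats.ttest_ind(a, b, equal_var=False)
        assert f == pytest.approx(t ** 2, rel=1e-10)
        assert df1 == 1.0


def test_welch_identical_means_small_f():
    rng = np.random.default_rng(1)
    groups = [rng.normal(5.0, 1.0, 200) for _ in range(4)]
    f, _, _ = welch_anova_oneway(groups)
    res = so.welch_partial_eta2(np.concatenate(groups),
                                np.repeat(np.arange(4), 200))
    assert res.eta_p2 < 0.02
    assert f < 3.0


def test_welch_input_validation():
    with pytest.raises(ValueError):
        welch_anova_oneway([np.array([1.0, 2.0])])
    with pytest.raises(ValueError, match="fewer than 2"):
        welch_anova_oneway([np.array([1.0, 2.0]), np.array([3.0])])
    with pytest.raises(ValueError, match="zero variance"):
        welch_anova_oneway([np.array([1.0, 1.0]), np.array([2.0, 3.0])])


def test_eta_p2_affine_invariant():
    rng = np.random.default_rng(2)
    vals = rng.normal(size=120)
    labels = rng.integers(0, 3, 120)
    a = so.welch_partial_eta2(vals, labels)
    b = so.welch_partial_eta2(5.0 * vals + 3.0, labels)
    assert a.eta_p2 == pytest.approx(b.eta_p2, rel=1e-12)


def _grid_inputs(n_trials=40, n_bins=8, seed=0):
    rng = np.random.default_rng(seed)
    jr = rng.integers(3, 14, n_trials).astype(float)
    sd = rng.integers(1, 7, n_trials).astype(float)
    centers = 10.0 * np.arange(n_bins) + 5.0
    return rng, jr, sd, centers


def test_gpr_flat_data_flat_posterior():
    """Constant-rate Poisson data yield a posterior that is flat within its
    own credible envelope, at the right overall level."""
    rng, jr, sd, centers = _grid_inputs()
    counts = rng.poisson(2.0, (40, 8))
    rate, post_sd = so.gpr_smooth(counts, centers, np.arange(40.0), jr, sd)
    sq = np.sqrt(rate * 0.01)  # back to the sqrt-count scale
    dev = np.abs(sq - sq.mean())
    assert np.mean(dev < 2.5 * post_sd) > 0.95
    # the sqrt transform biases the back-transformed level down a little:
    # E[sqrt(Poisson(2))]² ≈ 1.79, i.e. ≈180 sp/s for 2 spikes per 10 ms
    assert 150.0 < rate.mean() < 215.0


def test_gpr_recovers_additive_jr_effect():
    """Noiseless counts varying only with JR are reproduced within 5%."""
    _, jr, sd, centers = _grid_inputs(60, 6, seed=3)
    base = 5.0 + 0.5 * (jr - 8.0)  # counts per bin, noiseless in JR
    counts = np.tile(base[:, None], (1, 6))
    spec = so.GprSpec(noise_level=1e-4)
    rate, _ = so.gpr_smooth(counts, centers, np.arange(60.0), jr, sd, spec)
    per_trial = rate.mean(axis=1) / 100.0  # back to counts per bin
    assert np.all(np.abs(per_trial - base) / base < 0.05)


def test_gpr_posterior_sd_shrinks_with_noise():
    rng, jr, sd, centers = _grid_inputs(30, 6, seed=4)
    counts = np.tile(3.0, (30, 6))
    counts = counts + rng.normal(0, 0.01, counts.shape)
    _, sd_hi = so.gpr_smooth(counts, centers, np.arange(30.0), jr, sd,
                             so.GprSpec(noise_level=0.5))
    _, sd_lo = so.gpr_smooth(counts, centers, np.arange(30.0), jr, sd,
                             so.GprSpec(noise_level=1e-4))
    assert sd_lo.mean() < 0.1 * sd_hi.mean()


def test_gpr_requires_two_levels():
    _, jr, sd, centers = _grid_inputs(20, 4, seed=5)
    with pytest.raises(ValueError):
        so.gpr_smooth(np.zeros((20, 4)), centers, np.arange(20.0),
                      np.full(20, 8.0), sd)


def test_vac_scatter_summary():
    results = []
    rng = np.random.default_rng(6)
    jr_vac = rng.uniform(0.05, 0.4, 30)
    for u in range(30):
        results.append(so.VacResult(u, "visual", "jr", 1.0, 1, 10, jr_vac[u]))
        results.append(so.VacResult(u, "visual", "sd", 1.0, 1, 10, jr_vac[u] * 0.5))
    out = so.vac_scatter(results, "visual")
    assert out["spearman_r"] == pytest.approx(1.0)
    assert out["n_jr_gt_sd"] == 30 and out["n_sd_gt_jr"] == 0
    pref = {u: (3 if u < 10 else 8) for u in range(30)}
    out2 = so.vac_scatter(results, "visual", preferred_jr=pref,
                          exclude_extreme_jr=True)
    assert len(out2["table"]) == 20


def test_vac_scatter_independent_vacs_uncorrelated():
    rng = np.random.default_rng(7)
    results = []
    for u in range(200):
        results.append(so.VacResult(u, "visual", "jr", 1, 1, 10, rng.uniform()))
        results.append(so.VacResult(u, "visual", "sd", 1, 1, 10, rng.uniform()))
    out = so.vac_scatter(results, "visual")
    assert abs(out["spearman_r"]) < 0.15


def test_vac_pipeline_single_unit_directional(stim7):
    """A JR-tuned, SD-blind unit shows VAC(JR) > VAC(SD) in the visual and
    presaccadic epochs (closed loop on a small session)."""
    sched = so.build_session_schedule(stim7, 3, rng_seed=81)
    trials = so.simulate_session(sched, rng_seed=82)
    ct = trials[trials.phase == 2]
    jr_w = 0.6 * np.cos(np.linspace(0, np.pi, 11))
    unit = so.NeuronParams(jr_weights=tuple(jr_w), tuning_tau=None)
    spikes = so.simulate_unit(unit, trials, rng_seed=83).spike_times
    scheme = {k: so.VAC_EPOCHS[k] for k in ("baseline", "visual", "presaccadic")}
    res = so.vac_for_unit(spikes, ct, scheme=scheme,
                          spec=so.GprSpec(max_points=800))
    table = pd.DataFrame([vars(r) for r in res]).pivot(
        index="epoch", columns="variable", values="eta_p2")
    assert (table["jr"] > table["sd"]).all()
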