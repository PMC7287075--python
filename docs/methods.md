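# Methods

`serialorder` re-implements, as reusable and tested code, the analysis chain
of a transitive-inference (TI) electrophysiology experiment: macaques learn
the implied order of a 7-item picture list from pairwise presentations while
posterior parietal neurons are recorded. Because no recordings are bundled,
every analysis is driven by synthetic session generators whose defaults are
calibrated to the statistical structure such experiments report. This note
describes the models, the defaults and why they were chosen, the numerical
choices, and what the passing tests do — and do not — establish about real
data.

## Task model

A list of `n = 7` items carries ranks 1..n (labels A..G). Every unordered
pair (A, B) with ranks a < b is summarised by its **symbolic distance**
SD = b − a and **joint rank** JR = a + b. The two are exactly uncorrelated
over the 21 balanced pairs (the map i → 8−i reflects JR while preserving
SD), yet jointly invertible: b = (JR + SD)/2, a = (JR − SD)/2; `decompose_ranks`
implements this inverse and rejects parity-inconsistent inputs.

Sessions have two phases. Phase 1: five blocks of 2n single-stimulus trials
(each item once inside and once outside the recorded neuron's receptive
field per block, shuffled). Phase 2: up to 20 blocks of 42 choice trials;
each block contains every pair exactly twice, once per positional
arrangement, shuffled within block. Trial timing: the fixation delay is a
truncated shifted exponential on [0.4, 1.2] s whose rate is solved
numerically so the mean is 0.5 s (the stated skew/range/mean constrain but
do not identify the law; the truncated exponential is the simplest
positively skewed choice); hold and reward intervals are uniform on
[0.4, 0.6] and [0.35, 0.65] s; responses must occur within 1.5 s.

Analysis epochs are half-open windows [start, end) in ms relative to
stimulus or saccade onset. Two named schemes are provided (a VAC scheme with
baseline −250..0, visual +5..+150, presaccadic −100..0, postsaccadic
0..+500; an outcome scheme with background −200..0, visual +40..+150,
presaccadic −150..0) plus the +40..+150 identity window; the coexistence of
the 5–150 and 40–150 "visual" windows is deliberate — selection is
per-analysis.

## Behavioral generator

The agent is statistical, not mechanistic: the analyses need behavior with
the right structure, not a theory of learning. On choice trial *t*,

P(correct) = logistic( b₀ + b_sd(t)·SD + b_term(t)·[terminal pair] ),

with both slopes ramping as 1 − exp(−(t−1)/τ_learn). Defaults: b₀ = 0,
b_sd_max = 0.4, b_term_max = 0.35, τ_learn = 100 trials. These were chosen
once so that accuracy starts at chance, plateaus near 0.75 by ~250–300
trials, and is monotone in SD with elevated terminal pairs. The terminal
bonus ramps with learning because before learning nothing distinguishes the
end items.

Saccade latency is truncated-normal on (0, 1500] ms with mean
232 − 1.4·SD ms and SD 31 ms, giving the reported ~7 ms spread of per-SD
means over SD 1..6.

The spatial win-stay/lose-shift bias is applied as an independent post-hoc
override so that rank learning and spatial bias are separately controllable:
after a rewarded trial the location is forced to repeat with probability
2·(p_winstay − 0.5) (default p_winstay = 0.56); after non-reward it is
forced to switch with probability 2·(0.5 − p_loseshift_stay) (default
0.48). If unforced choices repeated a side exactly half the time this would
reproduce the configured marginals exactly. One subtlety: a counterbalanced
42-trial block is a random permutation of a balanced arrangement set, so the
unbiased agent repeats a side slightly *less* than half the time (≈0.493),
and the realized repeat-after-reward probability is ≈0.554–0.556 rather than
0.560. This is a property of the block design itself, and the parameter
recovery tests assert agreement within 1%.

Two biases are off by default, mirroring the null findings they emulate:
`item_stay_bias` (approach an item whose last choice was rewarded; the
recovered conditional-probability contrast is attenuated because the
override can only act when the two presented items' reward histories differ)
and, on the neural side, `history_gain_hz` (next-trial reward gain).

## Neural generator

Each unit draws from one of six parametric temporal families — visual
transient, visual sustained, presaccadic ramp, postsaccadic, suppressed,
tonic/anticipatory — standing in for empirically clustered response types.
The shapes were tuned so that their smoothed session profiles are mutually
separable at the r = 0.7 correlation cutoff (pairwise positive correlations
≲ 0.65), which is what cluster-count recovery presupposes.

The single-stimulus response is softplus(baseline + amp·template(t)·spatial
·(1 + m)) where spatial is a multiplicative in-RF gain (default 2.0,
yielding the characteristic ~2:1 in/out response ratio) and the modulation
m collects: per-level JR and SD weights (fractional; population sampler
defaults: Gaussian JR tuning at a random preferred level with amplitude
0.35, monotone SD modulation with amplitude 0.15 and mostly positive sign),
scaled by a saturating learning ramp 1 − exp(−t/τ) with τ = 80 choice
trials (tuning emerges over the first ~250 trials, then is stable); and a
transient rank code rank_amp·(t/τ_r)·e^{1−t/τ_r} (τ_r = 80) applied to a
signed, zero-mean linear code of the in-RF item's rank — present during
learning, gone at plateau. The response to a pair of stimuli is the
**pointwise mean** of the two single-stimulus responses (response
averaging), each carrying the trial's JR/SD modulation. Outcome modulation
defaults to zero.

Spikes are sampled exactly from the 1 ms piecewise-constant rate (per-bin
Poisson counts with uniform within-bin placement) and only within per-trial
spans; no analysis window extends between trials. Deeply suppressed units
can be genuinely silent in short windows; analyses drop such degenerate
units, as one would drop an unresponsive recording.

Synthetic eye traces are 1 kHz positions: centre fixation with smoothed
jitter, and a logistic step of amplitude equal to the target eccentricity
(10°, scale 5 ms) at each saccade. The logistic is centred such that radial
speed first crosses the default 30°/s detection threshold at the nominal
saccade time — i.e. "saccade onset" is defined as detectable movement onset.

## Eye kinematics

Velocity is position convolved with the derivative of a temporal Gaussian,
−k·t·exp(−t²/τ²), τ = 8 ms, k normalised so a linear ramp returns its slope
exactly (unit gain). The kernel is antisymmetric and applied centred, hence
zero phase. (The negative sign in the exponent is the standard Gaussian
form; a positive exponent would diverge.) Radial speed is the Euclidean norm
of the two velocity components. Saccade latency is the first crossing of a
speed threshold sustained ≥5 ms after stimulus onset; threshold and duration
are package choices, recovered to within ±5 ms in the generator closed loop.

## Spike pipeline

Per-trial rates are counts in a peri-event window divided by its duration;
variable-length stimulus→saccade windows are rate-normalised. Session
z-scores use the population-SD convention (divide by N), fixed for
reproducibility, so z({0, 10}) = ±1 and the z series has SD exactly 1.

Trial-averaged rates use a Gaussian kernel whose bandwidth minimises a
binned least-squares cross-validation estimate of the MISE over a log-spaced
grid (evaluated in O(grid·lags) via the autocorrelation of 1 ms-binned
counts); when the grid brackets no interior minimum the estimator falls back
to Silverman's rule. Eye traces use Silverman's rule directly. The KDE is
evaluated as a Gaussian-smoothed histogram on a 1 ms grid and normalised by
trial count, so it integrates to the mean spike count per trial up to edge
truncation. Note that for featureless (homogeneous) data the cross-validated
bandwidth is small — the criterion trades bias for variance — so pointwise
wiggle is expected while the average level is accurate.

## Population analyses

Unit profiles (z-scored KDE rates, stimulus-aligned −250..+750 ms) are
clustered agglomeratively under correlation distance (1 − Pearson r) with
average linkage — the natural pairing for a correlation cutoff — cut at
distance 0.3 (r = 0.7), with optimal leaf ordering; constant profiles are
excluded. Dendrograms serialise to Newick.

The optimal linear estimator (OLE) is ordinary least squares from the
population vector of z-scored rates to a scalar trial variable (JR or SD);
rank-deficient designs fall back to the minimum-norm solution with a
warning. Uncertainty comes from a trial bootstrap in which each resample is
used for refitting **and** evaluation (per-level means over the resampled
trials' predictions); evaluating on fixed trials would ignore the dominant
variance component and badly undercover. Default 10,000 iterations, with
1,000 as a fast mode. Note OLS predictions are shrunk toward the target
mean, so per-level estimates are unbiased only at central levels; the
coverage calibration is therefore run at the central level. Across sessions,
pseudo-populations are assembled by aligning trials on (pair, arrangement,
occurrence index), keeping keys present in all sessions.

## Variance accounted for (VAC)

Per unit and epoch: 10 ms bin counts → Gaussian-process smoothing over
(trial, time, JR, SD) → epoch-averaged per-trial rates → baseline
subtraction → Welch one-way ANOVA across JR (or SD) levels → partial
eta-squared η²p = F·df1/(F·df1 + df2). η²p measures the *degree* of tuning
without assuming its *form*; JR and SD enter the kernel as continuous
inputs, encoding the prior that trials at similar times with similar JR/SD
behave similarly.

The GP uses a squared-exponential kernel with per-dimension length-scales on
standardised inputs (defaults 1.0 = the median heuristic), a Gaussian
observation model on square-root-transformed counts — variance-stabilised,
so the noise level defaults to 1/4, the variance of sqrt-Poisson counts —
and an exact solve with training points capped at 1,500 by seeded subsample.
Marginal-likelihood optimisation is available (`optimize=True`) with the
median heuristic as initialisation and fallback. Because JR and SD are not
fully independent (extreme joint ranks force small symbolic distances), a
purely JR-tuned cell accounts for some variance across SD levels too; the
directional claim tested is therefore about means across units, not about
single cells.

Welch's F is implemented in closed form and verified against an independent
implementation (pingouin) to 1e-10 on 1,000 random datasets.

## Resampling statistics

Bootstrap: N-with-replacement resamples, percentile CIs. Shuffle tests:
labels permuted among trials (multiset preserved), one-sided
p = (1 + #{null ≥ observed})/(1 + n_perm) — the add-one convention, never
exactly zero. Best/worst identity analysis: per unit, the mean z of the
best (argmax, ties toward lower rank) and worst stimulus, observed vs
label-shuffled, compared by a paired t-test across units; the
single-stimulus phase is restricted to in-RF presentations, because pooling
in- and out-of-field trials would let the shuffle break the spatial balance
and bias the shuffled difference upward. Outcome tests are two-sided
rank-sum tests (η² via the normal approximation z²/N); the factor panel uses
Kruskal–Wallis with generalized η²_H = (H − k + 1)/(n − k). No
multiple-testing correction is applied across units; population summaries
are fractions significant at α = 0.05.

## Problem sizes and determinism

All randomness flows through explicit integer seeds (NumPy `default_rng` /
`SeedSequence`); (seed, config) determine outputs byte-for-byte. The test
suite and the acceptance script use desk-scale problem sizes chosen as the
package's own defaults: 100 seeds × 42 trials for chance-level checks, 141
sessions × 840 trials for win-stay recovery, 142 units for cluster-count
recovery, 10–30 units and 2–10 pair blocks for the VAC, decoding, and
rank-transience closed loops.

## What the synthetic loops do and do not show

Passing tests establish that the analysis chain is internally correct: it
recovers planted parameters, calibrates to nominal error rates on null
generators, and matches independent oracles where those exist. The
generators emulate the *statistical* structure of the experiment — learning
curves, SD/JR tuning, response averaging, transient rank codes, spatial
bias — but not biophysics (no spike waveforms, no cross-unit noise
correlations, no fixation breaks or aborted trials, no real images), and the
real study's effect magnitudes (accuracy–SD correlations, VAC values,
significant-unit fractions) are calibration targets for defaults, not
quantities these tests can verify against data. Conclusions about real
recordings require real recordings.
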