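# serialorder

Analysis toolkit for **transitive-inference (TI) serial-learning experiments
with concurrent electrophysiology**. In such experiments a subject (here,
the model system is the macaque with posterior parietal / LIP recordings)
learns the implied order of a 7-item picture list purely from pairwise
presentations: two images appear, a saccade to the lower-ranked one is
rewarded, and over a few hundred trials behavior reorganises around the
list structure. The package is aimed at researchers who want the full
analysis chain of such a study as tested, reusable code, driven end-to-end
by synthetic session generators.

Every pair of ranks a < b is summarised by two jointly invertible
quantities,

- symbolic distance **SD = b − a** (relative position: accuracy and
  learning rate increase with SD),
- joint rank **JR = a + b** (absolute position: uncorrelated with SD over
  the balanced pair set),

with b = (JR + SD)/2 and a = (JR − SD)/2. The toolkit covers:

- **Task model** — pair enumeration, SD/JR arithmetic and decomposition,
  two-phase counterbalanced block schedules, trial-timing distributions,
  named peri-event analysis epochs.
- **Synthetic generators** — a logistic learning agent with SD slope,
  terminal-item bonus, spatial win-stay/lose-shift bias and latency model; 
  Poisson spiking units in six temporal-profile families with receptive-field
  gain, response averaging for pairs, JR/SD tuning that emerges with
  learning, and a transient rank code; 1 kHz synthetic eye traces.
- **Pipelines** — eye-velocity filtering (derivative-of-Gaussian, unit
  gain, zero phase) and saccade-latency detection; epoch spike rates,
  session z-scores z(FR) = (FR − μ)/σ, MISE-optimal kernel rate estimates,
  condition-sorted PSTHs; correlation-distance hierarchical clustering of
  temporal profiles (r = 0.7 cutoff); optimal-linear-estimator (OLE)
  population decoding of JR/SD with bootstrap CIs; Gaussian-process
  smoothing over (trial, time, JR, SD) and variance-accounted-for via Welch
  partial eta-squared, η²p = F·df1/(F·df1 + df2); permutation ("shuffle"),
  bootstrap, rank-sum and Kruskal–Wallis machinery for the unit-level tests.
- **IO / CLI** — round-trippable plain-text session bundles and a
  `serialorder` command (`simulate`, `analyze-behavior`, `analyze-neural`,
  `decode`, `vac`, `report`).

See `docs/methods.md` for the models, defaults, and numerical choices.

## Worked example

```python
import serialorder as so

stim = so.StimulusList(7)
pair = so.StimPair(2, 3)  # "BC"
print(f"pair BC: SD={pair.symbolic_distance}, JR={pair.joint_rank}")
print("decompose (JR=8, SD=6) ->", so.decompose_ranks(8, 6))  # the pair "AG"

schedule = so.build_session_schedule(stim, n_pair_blocks=10, rng_seed=1)
trials = so.simulate_session(schedule, rng_seed=2)
ct = trials[trials.phase == 2]
late = ct[ct.choice_trial_index > 300]
print(f"{len(trials)} trials; accuracy after trial 300: {late.correct.mean():.3f}")

sessions = [so.simulate_session(so.build_session_schedule(stim, 10, rng_seed=s),
                                rng_seed=100 + s) for s in range(20)]
rt = so.rt_by_sd(sessions)
print(f"latency range across SD levels: {rt['range_ms']:.1f} ms "
      f"(ANOVA p={rt['p']:.2g}, n={rt['n']})")
ws = so.winstay_loseshift(sessions)
print(f"repeat after reward: {ws['after_reward']['mean']:.3f}; "
      f"after non-reward: {ws['after_noreward']['mean']:.3f}")

unit = so.sample_population(1, rng_seed=3, jr_amp=0.5)[0]
spikes = so.simulate_unit(unit, trials, rng_seed=4)
rates = so.epoch_spike_rate(spikes.spike_times, ct, so.IDENTITY_WINDOW)
res = so.welch_partial_eta2(rates, ct.jr.to_numpy(), epoch="visual", variable="jr")
print(f"unit family: {unit.cluster_id}; "
      f"VAC for joint rank (raw visual-window rates): eta_p2 = {res.eta_p2:.3f}")
```

Output, and what it means:

```
pair BC: SD=1, JR=5
decompose (JR=8, SD=6) -> (1, 7)
490 trials; accuracy after trial 300: 0.800
latency range across SD levels: 7.7 ms (ANOVA p=4.8e-08, n=8400)
repeat after reward: 0.557; after non-reward: 0.463
unit family: visual_transient; VAC for joint rank (raw visual-window rates): eta_p2 = 0.254
```

The agent starts at chance and is well above it after 300 choice trials;
mean saccade latency decreases only ~7 ms from adjacent pairs (SD 1) to the
end pair (SD 6) yet the effect is highly reliable at this trial count; the
spatial win-stay/lose-shift bias reproduces the configured repeat
probabilities; and a JR-tuned visual unit shows substantial variance
accounted for by joint rank in the visual window.

The same pipeline runs from the shell:

```bash
serialorder simulate --seed 5 --out data/        # synthetic session bundles
serialorder analyze-behavior data/ --out results/
serialorder decode data/ --out results/
serialorder vac data/ --out results/
serialorder report results/ --out results/summary.md
```

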