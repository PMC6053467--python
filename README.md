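# fourhz

Spike-train and local-field-potential analysis of task-dependent **4 Hz
(3–6 Hz) oscillations** in a two-region (VTA–PFC) recording preparation,
with a calibrated synthetic-session generator so every stage can be
validated without access to the original recordings.

The package is aimed at systems neuroscientists analysing simultaneous
single-unit and LFP recordings from mice performing a delayed
non-match-to-sample T-maze working-memory task, and at anyone who wants a
tested, reusable implementation of the analysis primitives involved:

* **Spectral** — 3-cycle complex Morlet transform WT(f, t) on a 1–25 Hz
  grid; coherence at each (f, t) from the cross-spectrum summed over six
  timepoints spaced one cycle apart,
  C(f,t) = |Σ₆ WTₐ·WT_b*| / √(Σ₆|WTₐ|²·Σ₆|WT_b|²) ∈ [0, 1];
  3–6 Hz band averaging; maze-position-resolved power/coherence maps; and
  lagged band-power cross-correlation (±250 ms, 5 ms steps) for
  directionality.
* **Spike–field phase locking** — linear-phase FIR bandpass (3–6 Hz),
  Hilbert phase (0 = peak), nearest-sample spike-phase assignment, mean
  resultant length MRL = |Σ e^{iφ}|/n with Rayleigh's test, and a
  bias-controlled sample-vs-choice comparison (≥ 50 spikes per phase, the
  larger side subsampled 1000×, MRL averaged over draws).
* **Rhythmic firing** — auto/cross-correlograms (10 ms bins), nonlinear
  least-squares fit of a·exp(−b·t²) + c·sin(d·t + e), circular–linear
  correlation r between the fitted sinusoid phase and the bin counts, and a
  surrogate null from jittering every spike by ±1000 ms (1000 surrogates;
  rhythmic if r exceeds the 95th surrogate percentile; "4 Hz" if the fitted
  frequency d/2π lies in 3–6 Hz).
* **Unit classification** — putative DA (< 10 Hz baseline and ≥ 50 %
  apomorphine suppression) vs GABA (> 10 Hz) rules, plus a permutation test
  on group firing rates.
* **Task coding** — rank-sum sample/choice selectivity on center-arm rates,
  Time × Direction ANOVA around turn onset, sign-rank reward responses
  (−500…+500 ms vs the −1000…−500 ms baseline), leave-one-out linear
  discriminant population decoding of task phase, Fisher/binomial
  proportion tests, and category-overlap-vs-independence counts.
* **Behavior** — projection of 25 Hz trajectories onto the T-maze skeleton
  (linear positions 1–100; 1 = bottom of the center arm, ≈50–60 = junction,
  100 = goal-arm end), turn-onset detection (15 consecutive samples of
  consistent horizontal motion), reward-arrival detection, running speed,
  and the ≥ 7/10-correct-for-3-days learning criterion.
* **Synthetic sessions** (`fourhz.synthetic`) — band-limited coherent LFP
  pairs with task-phase-dependent amplitude, von Mises phase-locked and
  sinusoidally rate-modulated inhomogeneous-Poisson spike trains,
  task-modulated populations, and T-maze trajectories, all with recorded
  ground truth and deterministic seeding.

## Worked example

```python
import numpy as np
from fourhz import synthetic, spike_phase, rhythmicity

# a 10-trial synthetic session: choice-phase 4 Hz oscillation twice as strong
session = synthetic.gen_session(n_trials=10, n_units=4, seed=42)
unit = session.units[0]  # DA-like, kappa = 1.5, choice/sample ratio 2

phases = spike_phase.spike_phases_for_lfp(unit, session.lfp_vta)
stats = spike_phase.phase_lock_stats(phases)
print(f"unit {unit.unit_id}: n={stats.n_spikes} spikes, "
      f"MRL={stats.mrl:.3f}, preferred phase={stats.preferred_phase:+.2f} rad, "
      f"Rayleigh p={stats.rayleigh_p:.2e}")

train = synthetic.gen_rhythmic_train(mod_freq=4.5, mod_depth=0.8,
                                     base_rate=5.0, duration_s=600.0, seed=1)
fit = rhythmicity.jitter_surrogate_test(train, n_surr=1000, seed=2)
print(f"rhythmic: {fit.is_rhythmic}, 4 Hz: {fit.is_4hz}, "
      f"frequency = {fit.freq_hz:.2f} Hz, r = {fit.r_obs:.3f} "
      f"(surrogate 95th pct = {fit.surrogate_q95:.3f})")
```

Output:

```
unit u000: n=1631 spikes, MRL=0.596, preferred phase=-3.12 rad, Rayleigh p=2.45e-279
rhythmic: True, 4 Hz: True, frequency = 4.48 Hz, r = 0.945 (surrogate 95th pct = 0.462)
```

The first line shows a unit generated with von Mises concentration
κ = 1.5 at the oscillation trough (μ = π): the measured MRL of 0.60 sits
near the analytic expectation I₁(1.5)/I₀(1.5) ≈ 0.596 and the preferred
phase recovers −π ≈ the trough. The second line shows the rhythmicity
detector recovering a 4.5 Hz sinusoidal rate modulation: the observed
circular–linear r (0.95) far exceeds the jitter-surrogate threshold (0.46)
and the fitted frequency is within 0.02 Hz of the ground truth.

A full per-session analysis (linearization → spectral → phase locking →
rhythmicity → classification → task coding, with a manifest and all
intermediates as delimited text) runs from the shell:

```bash
fourhz simulate --seed 42 --n-trials 10 --n-units 4 --out session/
fourhz run-all session/ --seed 42 --out results/
fourhz validate --seed 0 --quick   # simulation-based calibration report
```

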