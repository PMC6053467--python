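# Methods

This note documents the models, conventions, and design choices behind
`fourhz`, in the spirit of the model documentation of packages like
statsmodels or msprime. It states no empirical number that the test suite
or `scripts/acceptance.py` does not itself compute.

## Setting

The pipeline quantifies task-dependent 3–6 Hz ("4 Hz") oscillatory
coordination between the ventral tegmental area (VTA) and medial prefrontal
cortex (PFC) in recordings from mice performing a delayed
non-match-to-sample T-maze working-memory task. Each trial has a *sample*
run (one goal arm forced) and, after a short delay, a *choice* run (the
animal must enter the opposite arm). Overt behavior is matched between the
two run types; only the choice run requires working memory, so
sample-vs-choice contrasts isolate working-memory demand. Because the
recordings the pipeline was designed around are not publicly deposited, the
package ships a synthetic-session generator with known ground truth, and
all validation is property-based.

## Behavior

Trajectories are tracked at 25 Hz (40 ms sampling). Each run is linearized
by orthogonal projection onto a two-segment ideal path — the center-arm
axis, then the chosen goal-arm axis — with an affine map of the center arm
to positions [1, 50] and the goal arm to [51, 100]. Position 1 is the
bottom of the center arm, 50 the junction, 100 the end of the goal arm;
"center arm" analyses use positions 1–50. The projection method is a design
choice (only the endpoints and the junction range are fixed by convention);
linearization is idempotent for on-path trajectories and invariant to rigid
translation when the maze geometry is supplied in the same frame.

Turn onset is the first sample of the first 15 consecutive samples whose
forward horizontal displacement Δx = x[i+1] − x[i] is nonzero with constant
sign; zero-displacement samples break a streak ("consistent leftward or
rightward motion" operationalized strictly). Reward arrival is the first
sample with linear position ≥ 99; the threshold is a design choice (the
convention names only "arrival at the reward well"). Running speed is a
centered finite difference smoothed with a 5-sample (200 ms) moving
average. The learning criterion is ≥ 7 correct of 10 daily trials on three
consecutive days; `days_to_criterion` returns the last day of the first
such streak.

## Spectral analysis

The Morlet wavelet at frequency f is a complex exponential under a Gaussian
envelope with σ_t = n_cycles/(2πf), n_cycles = 3, truncated at ±3σ_t.
Wavelets are amplitude-normalized so a unit-amplitude sinusoid at a grid
frequency yields |WT| = 1 in the record interior; with this normalization
band "power" is an amplitude (µV) and squares to conventional power. Any
consistent normalization cancels in coherence. The default grid is 1–25 Hz
in 0.5 Hz steps (the spacing is a design choice). Samples within 1.5 cycles
of either record edge are flagged (cone of influence) and excluded from
averages. The frequency selectivity of a 3-cycle wavelet is deliberately
broad: its amplitude response to an off-band tone is
exp(−(n·Δf/f_c)²/2) — e.g. ≈ 0.32 at 8 Hz for a 4 Hz tone — and the tests
assert exactly this analytic response.

Coherence at (f, t) sums the cross-spectrum WTₐ·WT_b* over six timepoints
spaced one cycle (1/f) apart and normalizes by the autospectra summed over
the same points, measuring phase-relationship consistency over ~6 cycles.
The six offsets are symmetric, {−2.5, −1.5, −0.5, +0.5, +1.5, +2.5}/f —
whether the center point itself is included is not fixed by the convention;
symmetry was chosen to avoid lag bias. Cauchy–Schwarz confines the value to
[0, 1]. Because adjacent cycle-spaced wavelet coefficients are correlated
(the wavelet spans 3 cycles), the estimator has a substantial floor under
independence: its white-noise null level is ≈ 0.4, which the validation
suite measures by Monte Carlo rather than assuming.

Band series are unweighted means over grid frequencies in [3, 6] Hz
(inclusive). Position-resolved maps assign each behavioral sample the value
of the nearest-in-time series sample (a gap > 50 ms triggers a
clock-misalignment warning) and average within integer positions 1–100 per
task phase. The lagged power correlation is the Pearson correlation of two
band-amplitude series at shifts of ±250 ms in 5 ms steps; positive lag
means the first region leads. Amplitude (not squared) enters by default —
the convention leaves this open and squaring does not move the peak lag.

## Spike–field phase locking

The LFP is bandpass filtered with a windowed-sinc (Hamming) linear-phase
FIR whose impulse response spans 2 s (≥ 6 cycles at 3 Hz); applying the
centered kernel compensates the group delay exactly. The phase is the
argument of the Hilbert analytic signal with **0 at the oscillation peak
and ±π at the trough**; this origin convention is not fixed by the field
and is declared in every output header. Each spike takes the phase of the
nearest LFP sample; spikes within 0.5 s of the record edges are excluded.

Phase locking is the mean resultant length MRL = |Σ e^{iφ}|/n, and
significance comes from Rayleigh's test with the standard small-sample
correction p = exp(√(1+4n+4(n²−R²)) − (1+2n)). The MRL estimator has a
positive, strongly n-dependent bias, so sample-vs-choice comparisons (a)
require ≥ 50 spikes in both task phases and (b) subsample the larger side
without replacement to the smaller side's count 1000 times, averaging MRL
across draws. The bias-equalization property asserted by the tests is that
the *mean signed difference* between a subsampled large side and an
independent small side from the same population is ≤ 0.02; the per-seed
absolute difference is dominated by sampling noise (SD ≈ 0.08 at n = 60 for
κ = 1) and is not a meaningful target for any unbiased procedure.

## Rhythmic firing

Autocorrelograms count follower spikes 10–500 ms after each reference spike
(cross-correlograms ±500 ms around it) in 10 ms bins, restricted to
within-window spike pairs. The correlogram is fitted with
a·exp(−b·t²) + c·sin(d·t + e) (t in ms; b ≥ 0, d > 0) by least squares.
For fixed (b, d) the model is linear in the remaining parameters, so the
fit is a multi-start linear solve over a grid of frequencies d/2π from 1 to
12 Hz in 0.25 Hz steps crossed with seven Gaussian widths, followed by a
bounded nonlinear polish of the best start; the grid and bounds are
implementation additions (no initialization is prescribed by the
convention). Rhythmicity strength is the circular–linear correlation r
between the per-bin fitted sinusoid phase (d·t+e mod 2π) and the bin
counts (the `circ_corrcl` statistic, scale- and offset-invariant).

The null distribution comes from 1000 surrogates in which **every spike is
independently jittered** by Uniform(−1000, +1000) ms, re-restricted to the
task windows, and re-analysed identically (grid fit, no polish — the
observed r uses the same grid-only procedure so the comparison is
like-for-like; the polish only refines the reported frequency). Per-spike
jitter was chosen over a whole-train shift because a rigid shift preserves
the autocorrelogram and would yield a vacuous null. A unit is rhythmic if
its r strictly exceeds the 95th percentile (the ⌈0.95·n⌉-th order
statistic) of the surrogate r values, and "4 Hz" if additionally the fitted
frequency lies in [3, 6] Hz. Correlogram counts are raw (not normalized);
r is scale-invariant so the choice is immaterial. The stacked-pseudoinverse
grid fit makes a full 1000-surrogate test of a 600 s train run in about a
second, which is what makes the 200-unit type-I calibration feasible.

## Unit classification

Putative DA: baseline (home-cage) rate < 10 Hz *and* post-apomorphine rate
≤ 50 % of baseline. Putative GABA: baseline ≥ 10 Hz. Otherwise
unclassified (excluded from class-specific analyses). A baseline of exactly
10 Hz is assigned GABA and exactly 50 % suppression counts as DA; both
boundaries are measure-zero and resolved explicitly. Group rates are
compared with a two-sided permutation test on the difference of means
(10 000 relabelings, add-one correction p = (1+#extreme)/(n_perm+1)).

## Task coding

Per-run firing rates run from run start to the first sample at linear
position ≥ 50 (the decision point). Sample-vs-choice selectivity uses the
two-sided Wilcoxon rank-sum; the implementation uses the tie-corrected
asymptotic Mann–Whitney form because count-derived rates are heavily tied.
Correct and error trials are pooled by default (a config switch restricts
to correct trials). Turn coding bins rates in ten 100 ms bins from −500 to
+500 ms around turn onset and fits a Time × Direction two-way ANOVA (sample
and choice runs combined); a unit is turn-selective on a significant
Direction main effect **or** interaction at α = .05. Note that this OR over
two 5 %-level tests has a nominal null flag rate of ~9.8 % by construction;
the calibration suite therefore checks that each *component* effect holds
its 5 % level and reports the OR-flag rate separately. The ANOVA uses a
closed-form sums-of-squares decomposition, exact here because every turn
contributes every time bin (proportional cell frequencies ⇒ orthogonal
factors); it is verified against statsmodels in the tests. Reward
responsiveness compares the rate −500…+500 ms around reward-well arrival
against the −1000…−500 ms baseline with a one-sided (greater) sign-rank
(zero differences split; the unequal window lengths make the null
difference distribution slightly asymmetric, which inflates the measured
false-positive rate to ~6–7 % at 40 arrivals — an inherent property of the
procedure, not of the implementation).

The population decoder is a two-class Gaussian linear discriminant with
pooled covariance, diagonal shrinkage ε = 10⁻⁶, and **uniform class
priors**, evaluated by leave-one-out over runs. Uniform priors matter:
under leave-one-out the training fold always lacks one member of the
held-out class, so empirical priors systematically favor the wrong class
and push null accuracy well below 50 %; with uniform priors chance-level
data decodes at ≈ 48–50 %. Sessions contribute only with ≥ 2 neurons of
the class and ≥ 4 labeled runs. Proportions of selective cells are compared
with Fisher's exact test and against the α = .05 chance rate with exact
binomial tests; no multiple-comparison correction is applied across units
(per-unit α = .05 convention — a documented caveat, not an oversight).
Category overlap compares observed counts in the 2³ membership cells of
(task-phase, turn, reward) selectivity against products of marginal
proportions.

## Synthetic data

The band-limited oscillator is a sinusoid whose instantaneous frequency
performs an Ornstein–Uhlenbeck walk (relaxation time 2 s, stationary SD a
quarter of the bandwidth) clamped to 3–6 Hz — unlike filtered noise this
gives a controllable amplitude and an exactly defined phase for
calibration. The VTA/PFC pair mixes a shared oscillator with per-region
independent ones, coupling·shared + (1−coupling)·independent, scaled by a
task-phase amplitude envelope (choice amplitude 2× sample by default,
baseline half the smaller amplitude outside runs) plus white noise. LFP
rate defaults to 2 kHz; calibration simulations use 500 Hz (the band tops
out at 6 Hz) to keep the suite fast.

Spike trains are inhomogeneous Poisson processes sampled by thinning with a
documented rate ceiling: phase-locked units use intensity
base_rate·exp(κ·cos(φ(t)−μ))/I₀(κ) (time-average 1, so the nominal rate is
conserved; ceiling base_rate·e^κ/I₀(κ)), rhythmic units use
base_rate·(1+depth·sin(2π·f·t)), and task-modulated units multiply the rate
by the choice/sample ratio inside choice runs. The empirical MRL of
phase-locked trains converges to the analytic von Mises resultant
I₁(κ)/I₀(κ), which the tests assert at κ ∈ {0, 1, 2} (±0.03 at n ≈ 5000).
Behavior runs traverse the 40-unit center arm and a 40-unit goal arm at a
constant 20 units/s (a realistic mouse running speed for a 40 cm arm), with
5–10 s sample→choice delays and runs aligned to the 40 ms tracking grid;
the generator records true turn onsets and reward arrivals for recovery
tests. One seed per session is split into per-component sub-streams, so
adding units never changes the LFP or behavior draw.

What the generator does **not** emulate: 1/f background in the LFP (the
noise is white; no noise spectrum is prescribed and the level is a free
config parameter), spike waveforms, bursting, refractoriness,
rate-amplitude correlations, or any biophysics of the underlying circuit.
Passing calibrations therefore demonstrate correctness of the estimators
under the assumed statistical structure, not robustness to every property
of real recordings.

## Problem sizes and numerical choices

The validation suite (and `scripts/acceptance.py`) uses: 20 × 5000 von
Mises draws for MRL calibration and 1000 × 200 for Rayleigh type-I; 100
seeds of n = 60 vs 600 with 1000 subsamples for the bias control; 100 s
LFP segments (500 Hz) for coherence, with 3 realizations per coupling value
and a 20-pair white-noise null; 200 homogeneous and 100 modulated 600 s
trains (5 Hz) for the rhythmicity detector with 200 surrogates per unit —
a reduced-precision surrogate count, flagged in the validation report;
the library default is 1000 and is exercised on single units in the tests;
100 two-neuron 20-trial sessions for the decoder; 1000 null and 100
effect-bearing units per task-coding test. Tolerances follow the analytic
or Monte-Carlo dispersion of each quantity and are stated in the tests.

Degenerate inputs are signals, not crashes: units below spike floors are
excluded with reasons (≥ 50 spikes per task phase for MRL comparisons,
≥ 100 for correlograms, ≥ 5 trials/turns/arrivals for the per-unit tests),
zero-variance rate sets are excluded, constant band series raise an
undefined-correlation error, and a stage failure in `run_session` is
recorded in the manifest while independent stages still run. All
stochastic steps are seeded from the config; re-running a session
reproduces every output file bitwise (floats are written at %.17g and read
with round-trip parsing).

## Known limitations

* The coherence floor (~0.4 under independence) means absolute coherence
  values are estimator-specific; only contrasts (sample vs choice, coupled
  vs uncoupled) are interpretable.
* The reward sign-rank and the OR-rule turn flag have null rates that
  deviate from 5 % for structural reasons discussed above.
* The linearization assumes a T-maze with straight arms and maze-aligned
  coordinates; turn detection uses horizontal displacement and requires
  the caller to supply maze-aligned tracking.
* Pharmacological classification consumes summary rates; estimating them
  from raw drug-epoch spikes is out of scope.
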