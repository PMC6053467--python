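"""Synthetic session generator with known ground truth.

Every analysis stage in this package was designed for recordings that are
not publicly deposited, so the generator produces sessions with exactly the
statistical structure those analyses assume:

* a pair of 3-6 Hz band-limited LFP traces whose oscillation amplitude
  depends on the task phase and whose inter-region coherence is set by a
  single coupling parameter,
* spike trains phase-locked to the LFP with von Mises concentration
  ``kappa`` (inhomogeneous Poisson, intensity
  ``base_rate * exp(kappa*cos(phi(t)-mu)) / I0(kappa)``),
* spike trains with sinusoidal rate modulation at a set frequency,
* task-phase modulated Poisson populations (choice/sample rate ratio),
* 25 Hz T-maze trajectories for sample/choice runs under the
  non-match-to-sample rule.

The band-limited oscillator is a sinusoid whose instantaneous frequency
performs an Ornstein-Uhlenbeck walk clamped to the band: this gives a
controllable amplitude and a well-defined phase for calibration, unlike
filtered noise.  All spike generation uses thinning with the documented rate
ceiling, so runtime is bounded by ``ceiling * duration`` candidates.

Randomness: one seed per session, split per component through
``np.random.default_rng([seed, offset])`` sub-streams, so adding units never
perturbs the LFP draw.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import i0

from . import spike_phase
from .core import (
    BehaviorTrack,
    GroundTruth,
    InconsistentSessionError,
    InvalidParameterError,
    LfpSignal,
    MazeGeometry,
    PharmacologySummary,
    SpikeTrain,
    SyntheticSession,
    run_windows,
    validate_trials,
)

BEHAVIOR_RATE = 25.0  # Hz, tracking sample rate (40 ms interval)
LFP_RATE = 2000.0  # Hz, nominal LFP digitization rate

# fixed sub-seed offsets for per-component RNG streams
_SUB_LFP = 1
_SUB_BEHAVIOR = 2
_SUB_UNITS = 1000  # unit k uses offset _SUB_UNITS + k


def _component_rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(offset)])


# --------------------------------------------------------------------------- #
# band-limited oscillator


def _ou_band_oscillator(
    n: int, rate: float, band: tuple, rng: np.random.Generator, tau_s: float = 2.0
) -> np.ndarray:
    """Unit-amplitude sinusoid with an OU instantaneous-frequency walk.

    The frequency relaxes toward the band center with time constant
    ``tau_s`` and is clamped to the band; the stationary SD is a quarter of
    the bandwidth.
    """
    lo, hi = band
    fc = 0.5 * (lo + hi)
    sd = 0.25 * (hi - lo)
    dt = 1.0 / rate
    sigma = sd * np.sqrt(2.0 / tau_s)
    # exact OU update per step
    alpha = np.exp(-dt / tau_s)
    noise_sd = sigma * np.sqrt(tau_s / 2.0 * (1 - alpha * alpha))
    steps = rng.standard_normal(n)
    steps[0] = 0.0
    # AR(1) recursion via an IIR filter (f - fc follows x[i] = alpha*x[i-1] + noise)
    f = fc + lfilter([noise_sd], [1.0, -alpha], steps)
    np.clip(f, lo, hi, out=f)
    phase0 = rng.uniform(0, 2 * np.pi)
    phase = phase0 + 2 * np.pi * np.cumsum(f) * dt
    return np.sin(phase)


def _amplitude_envelope(
    n: int, rate: float, amp_by_phase, trials: pd.DataFrame | None, baseline_amp: float | None
) -> np.ndarray:
    """Per-sample oscillation amplitude: amp_by_phase[phase] inside runs,
    baseline elsewhere."""
    if np.isscalar(amp_by_phase):
        return np.full(n, float(amp_by_phase))
    amps = {k: float(v) for k, v in amp_by_phase.items()}
    if baseline_amp is None:
        baseline_amp = 0.5 * min(amps.values())
    env = np.full(n, float(baseline_amp))
    if trials is not None:
        t = np.arange(n) / rate
        for _, row in trials.iterrows():
            sel = (t >= row["t_start"]) & (t <= row["t_end"])
            env[sel] = amps[row["phase"]]
    return env


def gen_lfp_pair(
    duration_s: float,
    rate_hz: float = LFP_RATE,
    band: tuple = (3.0, 6.0),
    amp_by_phase=20.0,
    coupling: float = 1.0,
    noise_sd: float = 5.0,
    trials: pd.DataFrame | None = None,
    seed: int = 0,
    baseline_amp: float | None = None,
) -> tuple[LfpSignal, LfpSignal]:
    """Generate a coupled (VTA, PFC) LFP pair.

    Each region mixes a shared band-limited oscillator with an independent
    same-band oscillator, ``coupling*shared + (1-coupling)*independent``,
    scales by the task-phase amplitude envelope, and adds white noise.
    """
    params = [duration_s, rate_hz, coupling, noise_sd]
    if not np.all(np.isfinite(params)):
        raise InvalidParameterError("non-finite LFP generator parameter")
    if not (0.0 <= coupling <= 1.0):
        raise InvalidParameterError("coupling must lie in [0, 1]")
    if rate_hz < 4 * band[1]:
        raise InvalidParameterError("rate_hz must be >= 4x the band upper edge")
    if trials is not None:
        trials = validate_trials(trials)
        if trials["t_end"].max() > duration_s:
            raise InconsistentSessionError("trial windows extend past the LFP duration")

    n = int(round(duration_s * rate_hz))
    rng = _component_rng(seed, _SUB_LFP)
    shared = _ou_band_oscillator(n, rate_hz, band, rng)
    indep_a = _ou_band_oscillator(n, rate_hz, band, rng)
    indep_b = _ou_band_oscillator(n, rate_hz, band, rng)
    env = _amplitude_envelope(n, rate_hz, amp_by_phase, trials, baseline_amp)
    a = env * (coupling * shared + (1 - coupling) * indep_a)
    b = env * (coupling * shared + (1 - coupling) * indep_b)
    if noise_sd > 0:
        a = a + noise_sd * rng.standard_normal(n)
        b = b + noise_sd * rng.standard_normal(n)
    return (
        LfpSignal(a, rate=rate_hz, region="VTA"),
        LfpSignal(b, rate=rate_hz, region="PFC"),
    )


# --------------------------------------------------------------------------- #
# spike trains


def _thinned_poisson(
    intensity: np.ndarray, rate: float, lam_max: float, duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inhomogeneous Poisson times by thinning a rate-``lam_max`` process.

    ``intensity`` is the target rate sampled at ``rate``; candidates are
    accepted with probability ``intensity(t)/lam_max`` (nearest sample).
    """
    if lam_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(lam_max * duration)
    t = np.sort(rng.uniform(0.0, duration, size=n_cand))
    idx = np.minimum((t * rate).astype(int), intensity.size - 1)
    accept = rng.uniform(0.0, 1.0, size=n_cand) < intensity[idx] / lam_max
    return t[accept]


def gen_phase_locked_train(
    lfp: LfpSignal,
    band: tuple = (3.0, 6.0),
    kappa: float = 2.0,
    mu: float = 0.0,
    base_rate: float = 5.0,
    seed: int = 0,
    unit_id: str = "plock",
) -> SpikeTrain:
    """Spike train phase-locked to the band-filtered LFP phase.

    Intensity ``base_rate * exp(kappa*cos(phi(t)-mu)) / I0(kappa)``; the time
    average of the von Mises kernel is 1, so the expected count stays
    ``base_rate * duration``.  Rate ceiling: ``base_rate*exp(kappa)/I0(kappa)``.
    """
    if kappa < 0:
        raise InvalidParameterError("kappa must be >= 0")
    if base_rate <= 0:
        raise InvalidParameterError("base_rate must be > 0")
    filt = spike_phase.bandpass_filter(lfp, band)
    phase = spike_phase.instantaneous_phase(filt, band).phase
    intensity = base_rate * np.exp(kappa * np.cos(phase - mu)) / i0(kappa)
    lam_max = base_rate * np.exp(kappa) / i0(kappa)
    rng = np.random.default_rng(seed)
    t = _thinned_poisson(intensity, lfp.rate, lam_max, lfp.duration, rng) + lfp.t0
    return SpikeTrain(t, unit_id=unit_id, region=lfp.region)


def gen_rhythmic_train(
    mod_freq: float = 4.5,
    mod_depth: float = 0.8,
    base_rate: float = 5.0,
    duration_s: float = 600.0,
    seed: int = 0,
    unit_id: str = "rhythm",
) -> SpikeTrain:
    """Sinusoidally rate-modulated Poisson train:
    ``lambda(t) = base_rate * (1 + mod_depth*sin(2*pi*mod_freq*t))``."""
    if not (0.0 <= mod_depth <= 1.0):
        raise InvalidParameterError("mod_depth must lie in [0, 1] (rate never negative)")
    if base_rate <= 0 or duration_s <= 0:
        raise InvalidParameterError("base_rate and duration must be > 0")
    rng = np.random.default_rng(seed)
    lam_max = base_rate * (1 + mod_depth)
    n_cand = rng.poisson(lam_max * duration_s)
    t = np.sort(rng.uniform(0.0, duration_s, size=n_cand))
    lam = base_rate * (1 + mod_depth * np.sin(2 * np.pi * mod_freq * t))
    accept = rng.uniform(0.0, 1.0, size=n_cand) < lam / lam_max
    return SpikeTrain(t[accept], unit_id=unit_id, region="VTA")


def gen_task_modulated_population(
    n_units: int,
    phase_rate_ratios,
    trials: pd.DataFrame,
    seed: int = 0,
    base_rate: float = 4.0,
    duration_s: float | None = None,
    region: str = "VTA",
) -> list[SpikeTrain]:
    """Poisson units firing at ``base_rate`` except during choice runs, where
    the rate is ``base_rate * ratio``."""
    ratios = np.asarray(phase_rate_ratios, dtype=float)
    if ratios.size != n_units:
        raise InvalidParameterError("need one phase_rate_ratio per unit")
    if np.any(ratios <= 0):
        raise InvalidParameterError("phase_rate_ratios must be > 0")
    trials = validate_trials(trials)
    if duration_s is None:
        duration_s = float(trials["t_end"].max()) + 1.0
    choice_w = run_windows(trials, "choice")
    units = []
    for k, ratio in enumerate(ratios):
        rng = _component_rng(seed, _SUB_UNITS + k)
        # piecewise-constant rate: thinning against the ceiling
        lam_max = base_rate * max(ratio, 1.0)
        n_cand = rng.poisson(lam_max * duration_s)
        t = np.sort(rng.uniform(0.0, duration_s, size=n_cand))
        lam = np.full(t.size, base_rate)
        for a, b in choice_w:
            lam[(t >= a) & (t <= b)] = base_rate * ratio
        accept = rng.uniform(0.0, 1.0, size=n_cand) < lam / lam_max
        units.append(SpikeTrain(t[accept], unit_id=f"task{k:03d}", region=region))
    return units


# --------------------------------------------------------------------------- #
# behavior


def gen_behavior_session(
    n_trials: int,
    run_speed: float = 20.0,
    seed: int = 0,
    delay_range_s: tuple = (5.0, 10.0),
    iti_range_s: tuple = (10.0, 15.0),
    p_error: float = 0.0,
    geometry: MazeGeometry | None = None,
) -> tuple[BehaviorTrack, pd.DataFrame, dict]:
    """25 Hz T-maze trajectory plus the trial table.

    Each trial is a sample run (one goal arm forced) and, after a 5-10 s
    delay, a choice run; the choice is the opposite arm with probability
    ``1 - p_error`` and trials are marked correct under the non-match rule.
    During runs the animal moves at ``run_speed`` maze-units/s along the
    center arm (40 units) and then the goal arm (40 units); between runs it
    sits at the maze start.  Returns ``(track, trials, truth)`` where
    ``truth`` records per-run turn onsets and reward-well arrivals.
    """
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    if run_speed <= 0:
        raise InvalidParameterError("run_speed must be > 0")
    geo = geometry or MazeGeometry()
    rng = _component_rng(seed, _SUB_BEHAVIOR)
    dt = 1.0 / BEHAVIOR_RATE
    center_vec = geo.junction - geo.center_start
    arm_len = float(np.linalg.norm(center_vec))
    run_len = 2 * arm_len
    run_dur = run_len / run_speed

    events = []  # (t_start, arm) per run, interleaved with delays
    rows = []
    truth_turn, truth_arrival = [], []
    t = float(rng.uniform(*delay_range_s))
    for trial in range(n_trials):
        sample_arm = "L" if rng.uniform() < 0.5 else "R"
        wrong = rng.uniform() < p_error
        choice_arm = sample_arm if wrong else ("L" if sample_arm == "R" else "R")
        for phase, arm in (("sample", sample_arm), ("choice", choice_arm)):
            t_start = np.ceil(t / dt) * dt  # align run starts to the 25 Hz grid
            t_end = t_start + run_dur
            rows.append(
                dict(trial=trial, phase=phase, t_start=t_start, t_end=t_end,
                     goal_arm=arm, correct=(choice_arm != sample_arm))
            )
            truth_turn.append(t_start + arm_len / run_speed)
            # linear position 99 corresponds to 48/49 of the goal arm
            truth_arrival.append(t_start + (arm_len + arm_len * 48.0 / 49.0) / run_speed)
            gap = delay_range_s if phase == "sample" else iti_range_s
            t = t_end + float(rng.uniform(*gap))
    trials = validate_trials(pd.DataFrame(rows))

    n_samp = int(np.ceil((trials["t_end"].max() + 1.0) / dt)) + 1
    ts = np.arange(n_samp) * dt
    x = np.full(n_samp, geo.center_start[0])
    y = np.full(n_samp, geo.center_start[1])
    u_center = center_vec / arm_len
    for _, row in trials.iterrows():
        sel = (ts >= row["t_start"]) & (ts <= row["t_end"])
        s = np.clip(run_speed * (ts[sel] - row["t_start"]), 0.0, run_len)
        goal_vec = geo.goal_ends[row["goal_arm"]] - geo.junction
        u_goal = goal_vec / np.linalg.norm(goal_vec)
        on_center = s <= arm_len
        px = np.where(
            on_center,
            geo.center_start[0] + s * u_center[0],
            geo.junction[0] + (s - arm_len) * u_goal[0],
        )
        py = np.where(
            on_center,
            geo.center_start[1] + s * u_center[1],
            geo.junction[1] + (s - arm_len) * u_goal[1],
        )
        x[sel] = px
        y[sel] = py
    track = BehaviorTrack(ts, x, y)
    truth = {
        "turn_onsets": np.asarray(truth_turn),
        "reward_arrivals": np.asarray(truth_arrival),
        "run_speed": run_speed,
        "geometry": geo,
    }
    return track, trials, truth


# --------------------------------------------------------------------------- #
# full sessions


def gen_unit(
    truth: GroundTruth,
    lfp: LfpSignal,
    trials: pd.DataFrame | None,
    seed_offset: int,
    unit_id: str,
    region: str = "VTA",
) -> SpikeTrain:
    """One unit combining phase locking, sinusoidal modulation, and task
    modulation; the intensity is the product of the three factors and spikes
    are drawn by a single thinning pass."""
    rng = _component_rng(truth.seed, seed_offset)
    phase = spike_phase.instantaneous_phase(
        spike_phase.bandpass_filter(lfp, truth.lfp_band_hz), truth.lfp_band_hz
    ).phase
    tgrid_rate = lfp.rate
    duration = lfp.duration
    lam_max = (
        truth.base_rate
        * max(truth.phase_rate_ratio, 1.0)
        * np.exp(truth.kappa) / i0(truth.kappa)
        * (1 + truth.mod_depth)
    )
    n_cand = rng.poisson(lam_max * duration)
    t = np.sort(rng.uniform(0.0, duration, size=n_cand))
    idx = np.minimum((t * tgrid_rate).astype(int), phase.size - 1)
    lam = truth.base_rate * np.exp(truth.kappa * np.cos(phase[idx] - truth.mu)) / i0(truth.kappa)
    if truth.mod_depth > 0:
        lam *= 1 + truth.mod_depth * np.sin(2 * np.pi * truth.mod_freq * t)
    if trials is not None and truth.phase_rate_ratio != 1.0:
        for a, b in run_windows(trials, "choice"):
            lam[(t >= a) & (t <= b)] *= truth.phase_rate_ratio
    accept = rng.uniform(0.0, 1.0, size=n_cand) < lam / lam_max
    return SpikeTrain(t[accept] + lfp.t0, unit_id=unit_id, region=region)


def gen_session(
    n_trials: int = 10,
    n_units: int = 4,
    seed: int = 0,
    run_speed: float = 20.0,
    osc_amp_sample: float = 20.0,
    osc_amp_choice: float = 40.0,
    coupling: float = 0.8,
    noise_sd: float = 5.0,
    kappa: float = 1.5,
    phase_rate_ratio: float = 2.0,
    base_rate: float = 5.0,
) -> SyntheticSession:
    """A complete synthetic session with self-consistent ground truth.

    Defaults emulate the task structure the analyses assume: a stronger
    choice-phase oscillation (amplitude ratio 2), moderately coupled VTA/PFC
    LFPs, and units that are phase-locked and choice-preferring.  Units
    alternate DA-like (low rate, apomorphine-suppressed) and GABA-like
    (high rate) pharmacology.
    """
    track, trials, beh_truth = gen_behavior_session(n_trials, run_speed, seed=seed)
    duration = float(track.timestamps[-1]) + 1.0 / BEHAVIOR_RATE
    lfp_vta, lfp_pfc = gen_lfp_pair(
        duration_s=duration,
        amp_by_phase={"sample": osc_amp_sample, "choice": osc_amp_choice},
        coupling=coupling,
        noise_sd=noise_sd,
        trials=trials,
        seed=seed,
    )
    units, unit_truth, pharm = [], [], []
    for k in range(n_units):
        da_like = k % 2 == 0
        gt = GroundTruth(
            osc_amp_sample=osc_amp_sample,
            osc_amp_choice=osc_amp_choice,
            coupling=coupling,
            kappa=kappa,
            mu=float(np.pi) if da_like else 0.0,
            mod_freq=4.5,
            mod_depth=0.0,
            base_rate=base_rate if da_like else 4.0 * base_rate,
            phase_rate_ratio=phase_rate_ratio if da_like else 1.0,
            seed=seed,
        )
        unit = gen_unit(gt, lfp_vta, trials, _SUB_UNITS + k, f"u{k:03d}", region="VTA")
        unit.cell_class = "DA" if da_like else "GABA"
        units.append(unit)
        unit_truth.append(gt)
        rng = _component_rng(seed, _SUB_UNITS + 500 + k)
        base = gt.base_rate * float(rng.uniform(0.9, 1.1))
        post = base * (0.3 if da_like else 1.05)
        pharm.append(PharmacologySummary(unit.unit_id, base, post))
    truth = dict(beh_truth)
    truth.update(
        osc_amp_sample=osc_amp_sample, osc_amp_choice=osc_amp_choice,
        coupling=coupling, seed=seed,
    )
    return SyntheticSession(
        lfp_vta=lfp_vta, lfp_pfc=lfp_pfc, units=units, unit_truth=unit_truth,
        track=track, trials=trials, pharmacology=pharm, ground_truth=truth,
        session_id=f"synthetic-{seed}",
    )
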