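"""Simulation-based calibration suite.

Because the recordings the pipeline was designed for are not publicly
deposited, validation is property-based: every estimator is run on
synthetic data with known ground truth and checked against analytic or
Monte-Carlo expectations.  The same routines back ``run_validation``, the
acceptance tests, and ``scripts/acceptance.py``.

Problem sizes are chosen so the full default suite runs in minutes on one
CPU; the rhythmicity block supports a reduced-precision surrogate count
(flagged in the report when below 1000).
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0, i1

from . import behavior, classify, rhythmicity, spectral, spike_phase, synthetic, task_coding
from .core import LfpSignal, PharmacologySummary, SpikeTrain

VON_MISES_MRL = {k: float(i1(k) / i0(k)) for k in (0.0, 1.0, 2.0)}


def _seed(base: int, *offsets: int) -> np.random.Generator:
    return np.random.default_rng([int(base) % (2**31), *offsets])


# --------------------------------------------------------------------------- #
# 1. MRL / Rayleigh calibration


def calib_phase_locking(seed: int = 0, kappa: float = 2.0, n: int = 5000,
                        n_seeds: int = 20, n_null: int = 1000, n_null_spikes: int = 200,
                        alpha: float = 0.05) -> dict:
    """Mean MRL of von Mises phase samples vs the analytic I1(k)/I0(k), and
    the Rayleigh type-I rate on uniform phases."""
    rng = _seed(seed, 11)
    mrls = []
    for _ in range(n_seeds):
        phases = rng.vonmises(0.0, kappa, size=n)
        mrls.append(spike_phase.phase_lock_stats(phases).mrl)
    mean_mrl = float(np.mean(mrls))
    expected = float(i1(kappa) / i0(kappa))

    rejections = 0
    for _ in range(n_null):
        phases = rng.uniform(-np.pi, np.pi, size=n_null_spikes)
        if spike_phase.phase_lock_stats(phases).rayleigh_p < alpha:
            rejections += 1
    return dict(
        mean_mrl=mean_mrl, expected_mrl=expected,
        mrl_abs_error=abs(mean_mrl - expected),
        rayleigh_type1_rate=rejections / n_null,
        n=n, n_seeds=n_seeds, n_null=n_null,
    )


# --------------------------------------------------------------------------- #
# 2. matched-subsample bias control


def calib_subsample_bias(seed: int = 0, kappa: float = 1.0, n_small: int = 60,
                         n_big: int = 600, n_seeds: int = 100,
                         n_subsamples: int = 1000) -> dict:
    """Bias equalization: subsampled MRL of an n=600 von Mises population vs
    the plain MRL of an independent n=60 population from the same kappa."""
    rng = _seed(seed, 22)
    diffs = np.empty(n_seeds)
    for i in range(n_seeds):
        small = rng.vonmises(0.0, kappa, size=n_small)
        big = rng.vonmises(0.0, kappa, size=n_big)
        comp = spike_phase.matched_subsample_comparison(
            small, big, n_subsamples=n_subsamples, min_spikes=50,
            seed=int(rng.integers(2**31)),
        )
        diffs[i] = comp.stats_sample.mrl - comp.stats_choice.mrl
    return dict(mean_mrl_difference=float(np.mean(diffs)),
                abs_mean_mrl_difference=float(abs(np.mean(diffs))),
                sd_mrl_difference=float(np.std(diffs)), n_seeds=n_seeds)


# --------------------------------------------------------------------------- #
# 3. coherence estimator


def _band_coherence(lfp_a, lfp_b, band=(3.0, 6.0)) -> float:
    freqs = np.arange(band[0], band[1] + 1e-9, 0.5)
    wa = spectral.morlet_transform(lfp_a, freqs)
    wb = spectral.morlet_transform(lfp_b, freqs)
    coh, defined = spectral.wavelet_coherence(wa, wb)
    return float(np.nanmean(np.where(defined, coh, np.nan)))


def calib_coherence(seed: int = 0, duration_s: float = 100.0, rate: float = 500.0,
                    couplings=(0.0, 0.25, 0.5, 0.75, 1.0), n_null: int = 20) -> dict:
    """Identity check, coupling monotonicity, and the white-noise null."""
    # identical inputs -> coherence exactly 1 where defined
    lfp_a, _ = synthetic.gen_lfp_pair(20.0, rate, coupling=1.0, noise_sd=2.0, seed=seed)
    freqs = np.arange(3.0, 6.0 + 1e-9, 0.5)
    wa = spectral.morlet_transform(lfp_a, freqs)
    coh, defined = spectral.wavelet_coherence(wa, wa)
    identical_dev = float(np.nanmax(np.abs(coh[defined] - 1.0)))

    sweep = []
    for i, c in enumerate(couplings):
        vals = []
        for rep in range(3):  # average realizations: the sweep compares means
            a, b = synthetic.gen_lfp_pair(duration_s, rate, coupling=c, noise_sd=2.0,
                                          seed=seed + 100 * (rep + 1) + i)
            vals.append(_band_coherence(a, b))
        sweep.append(float(np.mean(vals)))
    monotone = bool(np.all(np.diff(sweep) > 0))

    rng = _seed(seed, 33)
    null_vals = np.empty(n_null)
    for i in range(n_null):
        xa = LfpSignal(rng.standard_normal(int(duration_s * rate)), rate, "VTA")
        xb = LfpSignal(rng.standard_normal(int(duration_s * rate)), rate, "PFC")
        null_vals[i] = _band_coherence(xa, xb)
    observed = null_vals[0]
    null_q99 = float(np.quantile(null_vals[1:], 0.99))
    return dict(identical_dev=identical_dev, coupling_sweep=[float(v) for v in sweep],
                monotone=monotone, white_noise_coherence=float(observed),
                null_q99=null_q99, n_null=n_null)


# --------------------------------------------------------------------------- #
# 4. power-lag recovery


def calib_power_lag(seed: int = 0, duration_s: float = 100.0, rate: float = 500.0,
                    shift_ms: float = 50.0) -> dict:
    """A band-power series correlated against itself delayed by 50 ms must
    peak at +50 ms (positive lag = first signal leads)."""
    lfp, _ = synthetic.gen_lfp_pair(duration_s, rate, coupling=1.0, noise_sd=2.0,
                                    seed=seed + 7)
    series = spectral.band_power(lfp, freqs=np.arange(3.0, 6.0 + 1e-9, 0.5))
    shift = int(round(shift_ms / 1000.0 * rate))
    delayed = spectral.BandSeries(
        times=series.times, values=np.roll(series.values, shift),
        band=series.band, rate=series.rate, kind="power")
    # roll wraps the edge; blank the wrapped segment
    delayed.values[:shift] = np.nan
    lags, r = spectral.power_crosscorrelation(series, delayed)
    peak_ms = float(lags[np.nanargmax(r)] * 1000.0)
    return dict(peak_lag_ms=peak_ms, expected_ms=shift_ms, peak_r=float(np.nanmax(r)))


# --------------------------------------------------------------------------- #
# 5. rhythmicity detector


def calib_rhythmicity(seed: int = 0, n_null_units: int = 200, n_power_seeds: int = 100,
                      n_surr: int = 1000, duration_s: float = 600.0,
                      rate_hz: float = 5.0, mod_freq: float = 4.5,
                      mod_depth: float = 0.8) -> dict:
    """Type-I error on homogeneous Poisson units and power on 4.5 Hz
    modulated trains (frequency recovery within 0.3 Hz, is_4hz flag)."""
    rng = _seed(seed, 44)
    false_pos = 0
    for i in range(n_null_units):
        train = synthetic.gen_rhythmic_train(mod_freq, 0.0, rate_hz, duration_s,
                                             seed=int(rng.integers(2**31)))
        fit = rhythmicity.jitter_surrogate_test(train, n_surr=n_surr,
                                                seed=int(rng.integers(2**31)))
        false_pos += int(fit.is_rhythmic)
    detected = 0
    flagged_4hz = 0
    freq_errors = []
    for i in range(n_power_seeds):
        train = synthetic.gen_rhythmic_train(mod_freq, mod_depth, rate_hz, duration_s,
                                             seed=int(rng.integers(2**31)))
        fit = rhythmicity.jitter_surrogate_test(train, n_surr=n_surr,
                                                seed=int(rng.integers(2**31)))
        if fit.is_rhythmic:
            detected += 1
            freq_errors.append(abs(fit.freq_hz - mod_freq))
            flagged_4hz += int(fit.is_4hz)
    return dict(
        type1_rate=false_pos / n_null_units,
        detection_rate=detected / n_power_seeds,
        rate_4hz=flagged_4hz / n_power_seeds,
        mean_freq_error_hz=float(np.mean(freq_errors)) if freq_errors else np.nan,
        max_freq_error_hz=float(np.max(freq_errors)) if freq_errors else np.nan,
        n_surr=n_surr, n_null_units=n_null_units, n_power_seeds=n_power_seeds,
        reduced_precision=bool(n_surr < 1000),
    )


# --------------------------------------------------------------------------- #
# 6. decoder


def _decoder_session(ratio: float, n_trials: int, n_units: int, base_rate: float,
                     seed: int) -> float:
    track, trials, _ = synthetic.gen_behavior_session(n_trials, seed=seed)
    units = synthetic.gen_task_modulated_population(
        n_units, [ratio] * n_units, trials, seed=seed, base_rate=base_rate)
    runs = behavior.linearize_session(track, trials)
    X, y = task_coding.build_rate_matrix(units, trials, runs)
    return task_coding.decode_task_phase(X, y).accuracy


def calib_decoder(seed: int = 0, n_sessions: int = 100, n_trials: int = 20,
                  base_rate: float = 4.0) -> dict:
    """Chance-level accuracy at rate ratio 1, high accuracy at ratio 3, and
    the 2-neuron session floor."""
    rng = _seed(seed, 55)
    null_acc = [
        _decoder_session(1.0, n_trials, 2, base_rate, int(rng.integers(2**31)))
        for _ in range(n_sessions)
    ]
    ratio3 = _decoder_session(3.0, n_trials, 2, base_rate, int(rng.integers(2**31)))
    # 1-neuron sessions are excluded, not decoded
    track, trials, _ = synthetic.gen_behavior_session(6, seed=int(rng.integers(2**31)))
    unit = synthetic.gen_task_modulated_population(1, [2.0], trials,
                                                   seed=int(rng.integers(2**31)))
    runs = behavior.linearize_session(track, trials)
    X, y = task_coding.build_rate_matrix(unit, trials, runs)
    excluded = task_coding.decode_task_phase(X, y).excluded
    return dict(null_accuracy_mean=float(np.mean(null_acc)),
                ratio3_accuracy=float(ratio3),
                single_neuron_excluded=bool(excluded), n_sessions=n_sessions)


# --------------------------------------------------------------------------- #
# 7. per-unit task-coding tests


def _poisson_train(rate: float, duration: float, rng) -> SpikeTrain:
    n = rng.poisson(rate * duration)
    return SpikeTrain(np.sort(rng.uniform(0, duration, size=n)), unit_id="sim")


def calib_task_tests(seed: int = 0, n_null: int = 1000, n_power: int = 100) -> dict:
    """False-positive rates on stationary Poisson units and power at the
    calibration effect sizes for all three per-unit tests."""
    rng = _seed(seed, 66)
    track, trials, truth = synthetic.gen_behavior_session(20, seed=seed)
    runs = behavior.linearize_session(track, trials)
    duration = float(track.timestamps[-1]) + 1.0
    turn_times = truth["turn_onsets"]
    turn_events_null = [(t, "L" if i % 2 == 0 else "R")
                       for i, t in enumerate(turn_times)]
    arrivals = truth["reward_arrivals"]

    fp = dict(task_phase=0, turn_flag=0, turn_direction=0, turn_interaction=0,
              reward=0)
    for _ in range(n_null):
        unit = _poisson_train(4.0, duration, rng)
        res = task_coding.phase_selectivity(unit, trials, runs)
        fp["task_phase"] += int((not res.excluded) and res.selective)
        res = task_coding.turn_selectivity(unit, turn_events_null)
        fp["turn_flag"] += int((not res.excluded) and res.selective)
        rates, dirs = task_coding.turn_aligned_rates(unit, turn_events_null)
        p_dir, p_int, _, _ = task_coding.two_way_anova_rates(rates, dirs)
        fp["turn_direction"] += int(p_dir < task_coding.ALPHA)
        fp["turn_interaction"] += int(p_int < task_coding.ALPHA)
        res = task_coding.reward_responsiveness(unit, arrivals)
        fp["reward"] += int((not res.excluded) and res.selective)

    power = dict(task_phase=0, turn=0, reward=0)
    for _ in range(n_power):
        # task phase: choice/sample rate ratio 3 at base rate 4 Hz
        unit = synthetic.gen_task_modulated_population(
            1, [3.0], trials, seed=int(rng.integers(2**31)), base_rate=4.0)[0]
        res = task_coding.phase_selectivity(unit, trials, runs)
        power["task_phase"] += int((not res.excluded) and res.selective)
        # turn: 2 Hz on L turns, 8 Hz on R turns around onset
        t = []
        for onset, d in turn_events_null:
            r = 2.0 if d == "L" else 8.0
            n = rng.poisson(r * 1.0)
            t.append(rng.uniform(onset - 0.5, onset + 0.5, size=n))
        base = _poisson_train(2.0, duration, rng).timestamps
        unit = SpikeTrain(np.sort(np.concatenate([base] + t)), unit_id="turnpow")
        res = task_coding.turn_selectivity(unit, turn_events_null)
        power["turn"] += int((not res.excluded) and res.selective)
        # reward: rate step 2 -> 8 Hz in the arrival window
        extra = [rng.uniform(a - 0.5, a + 0.5, size=rng.poisson(6.0))
                 for a in arrivals]
        base = _poisson_train(2.0, duration, rng).timestamps
        unit = SpikeTrain(np.sort(np.concatenate([base] + extra)), unit_id="rewpow")
        res = task_coding.reward_responsiveness(unit, arrivals)
        power["reward"] += int((not res.excluded) and res.selective)

    return dict(
        fpr_task_phase=fp["task_phase"] / n_null,
        fpr_turn_flag=fp["turn_flag"] / n_null,
        fpr_turn_direction=fp["turn_direction"] / n_null,
        fpr_turn_interaction=fp["turn_interaction"] / n_null,
        fpr_reward=fp["reward"] / n_null,
        power_task_phase=power["task_phase"] / n_power,
        power_turn=power["turn"] / n_power,
        power_reward=power["reward"] / n_power,
        n_null=n_null, n_power=n_power,
    )


# --------------------------------------------------------------------------- #
# 8. deterministic rules


def calib_rules() -> dict:
    """The fixed classification and learning-criterion rule cases."""
    cases = [
        classify.classify_unit(PharmacologySummary("a", 3.0, 1.0)) == "DA",
        classify.classify_unit(PharmacologySummary("b", 22.0, 25.0)) == "GABA",
        classify.classify_unit(PharmacologySummary("c", 5.0, 4.0)) == "unclassified",
    ]
    days = [
        behavior.days_to_criterion([7, 7, 7]) == 3,
        behavior.days_to_criterion([7, 7, 6, 7, 7, 7]) == 6,
        behavior.days_to_criterion([10] * 8) == 3,
    ]
    return dict(classification_cases_ok=all(cases), criterion_cases_ok=all(days),
                all_ok=all(cases) and all(days))


# --------------------------------------------------------------------------- #
# 9. end-to-end reproducibility


def calib_reproducibility(seed: int, out_root, n_trials: int = 6, n_units: int = 3,
                          n_surrogates: int = 200) -> dict:
    """run_session twice with the same seed must produce bitwise-identical
    result files."""
    import filecmp
    from pathlib import Path

    from .pipeline import PipelineConfig, run_session

    root = Path(out_root)
    session = synthetic.gen_session(n_trials=n_trials, n_units=n_units, seed=seed)
    config = PipelineConfig(seed=seed, n_surrogates=n_surrogates)
    dirs = []
    for rep in ("a", "b"):
        out = root / f"run_{rep}"
        run_session(session, config, out)
        dirs.append(out)
    files_a = sorted(p.name for p in dirs[0].iterdir())
    files_b = sorted(p.name for p in dirs[1].iterdir())
    identical = files_a == files_b and all(
        filecmp.cmp(dirs[0] / f, dirs[1] / f, shallow=False) for f in files_a
    )
    return dict(identical=bool(identical), n_files=len(files_a))


# --------------------------------------------------------------------------- #
# report


def run_validation(seed: int = 0, n_surr: int = 1000, out_root=None,
                   quick: bool = False) -> dict:
    """Run the full calibration suite and report pass/fail per property."""
    import tempfile

    scale = 0.2 if quick else 1.0

    def s(n):
        return max(2, int(round(n * scale)))

    report = {"reduced_precision": bool(n_surr < 1000 or quick), "properties": {}}

    pl = calib_phase_locking(seed, n_seeds=s(20), n_null=s(1000))
    report["properties"]["phase_locking"] = {
        **pl, "pass": pl["mrl_abs_error"] <= 0.03 and 0.03 <= pl["rayleigh_type1_rate"] <= 0.07,
    }
    sb = calib_subsample_bias(seed, n_seeds=s(100))
    report["properties"]["subsample_bias"] = {
        **sb, "pass": sb["abs_mean_mrl_difference"] <= 0.02,
    }
    # the white-noise null bound needs a real Monte-Carlo sample; never shrink
    ch = calib_coherence(seed, n_null=20)
    report["properties"]["coherence"] = {
        **ch,
        "pass": ch["identical_dev"] <= 1e-6 and ch["monotone"]
        and ch["white_noise_coherence"] < ch["null_q99"] + 1e-12,
    }
    lag = calib_power_lag(seed)
    report["properties"]["power_lag"] = {
        **lag, "pass": abs(lag["peak_lag_ms"] - lag["expected_ms"]) <= 5.0,
    }
    rh = calib_rhythmicity(seed, n_null_units=s(200), n_power_seeds=s(100), n_surr=n_surr)
    report["properties"]["rhythmicity"] = {
        **rh,
        "pass": 0.03 <= rh["type1_rate"] <= 0.08 and rh["detection_rate"] >= 0.9
        and rh["rate_4hz"] >= 0.9 and rh["max_freq_error_hz"] <= 0.3,
    }
    dec = calib_decoder(seed, n_sessions=s(100))
    report["properties"]["decoder"] = {
        **dec,
        "pass": 45.0 <= dec["null_accuracy_mean"] <= 55.0
        and dec["ratio3_accuracy"] >= 90.0 and dec["single_neuron_excluded"],
    }
    tt = calib_task_tests(seed, n_null=s(1000), n_power=s(100))
    report["properties"]["task_tests"] = {
        **tt,
        # each elementary test calibrates at its nominal alpha; the turn flag
        # is the OR of two 5%-level effects, so its null rate is ~9.8%
        "pass": all(
            0.03 <= tt[k] <= 0.07
            for k in ("fpr_task_phase", "fpr_turn_direction",
                      "fpr_turn_interaction", "fpr_reward")
        )
        and all(tt[f"power_{v}"] >= 0.95 for v in ("task_phase", "turn", "reward")),
    }
    rules = calib_rules()
    report["properties"]["rules"] = {**rules, "pass": rules["all_ok"]}
    with tempfile.TemporaryDirectory(dir=out_root) as tmp:
        rep = calib_reproducibility(seed, tmp)
    report["properties"]["reproducibility"] = {**rep, "pass": rep["identical"]}
    report["all_pass"] = all(p["pass"] for p in report["properties"].values())
    return report
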