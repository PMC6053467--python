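"""Morlet transform, cycle-spaced coherence, band averaging, position maps,
and lagged power correlation."""

import numpy as np
import pytest

from fourhz import behavior, spectral, synthetic
from fourhz.core import (
    BandSeries,
    IncompatibleTransformError,
    InvalidParameterError,
    LfpSignal,
    NyquistError,
)

RATE = 500.0


def _tone(freq, duration=10.0, amp=1.0, rate=RATE, phase=0.0):
    t = np.arange(0, duration, 1 / rate)
    return LfpSignal(amp * np.sin(2 * np.pi * freq * t + phase), rate)


def _gauss_response(f_center, f_signal, n_cycles=3.0):
    """Analytic amplitude response of an n-cycle Morlet at f_center to a
    tone at f_signal: exp(-(n*(f_signal-f_center)/f_center)^2 / 2)."""
    return np.exp(-((n_cycles * (f_signal - f_center) / f_center) ** 2) / 2)


class TestMorlet:
    def test_zero_signal(self):
        wt = spectral.morlet_transform(LfpSignal(np.zeros(5000), RATE),
                                       np.array([4.0, 8.0]))
        assert np.all(np.abs(wt.coeffs) < 1e-12)

    def test_unit_tone_amplitude_and_offband(self):
        wt = spectral.morlet_transform(_tone(4.0), np.array([4.0, 8.0]))
        in_band = np.abs(wt.coeffs[0][wt.valid[0]])
        assert np.all(np.abs(in_band - 1.0) < 0.01)
        # off-band response follows the wavelet's Gaussian frequency response
        off = np.abs(wt.coeffs[1][wt.valid[1]])
        assert np.median(off) == pytest.approx(_gauss_response(8.0, 4.0), abs=0.02)

    def test_superposition(self):
        t = np.arange(0, 10, 1 / RATE)
        x = np.sin(2 * np.pi * 4 * t) + np.sin(2 * np.pi * 12 * t)
        wt = spectral.morlet_transform(LfpSignal(x, RATE), np.array([4.0, 12.0]))
        for i, (fc, other) in enumerate([(4.0, 12.0), (12.0, 4.0)]):
            leak = _gauss_response(fc, other)
            vals = np.abs(wt.coeffs[i][wt.valid[i]])
            assert np.all(vals > 1 - leak - 0.03) and np.all(vals < 1 + leak + 0.03)

    def test_amplitude_scaling_quadratic_power(self):
        p = []
        for amp in (1.0, 2.0):
            wt = spectral.morlet_transform(_tone(4.0, amp=amp), np.array([4.0]))
            p.append(np.mean(np.abs(wt.coeffs[0][wt.valid[0]]) ** 2))
        assert p[1] / p[0] == pytest.approx(4.0, rel=0.05)

    def test_duration_invariance(self):
        vals = []
        for dur in (5.0, 20.0):
            wt = spectral.morlet_transform(_tone(4.0, duration=dur), np.array([4.0]))
            vals.append(np.mean(np.abs(wt.coeffs[0][wt.valid[0]])))
        assert vals[0] == pytest.approx(vals[1], rel=1e-3)

    def test_nyquist_error(self):
        with pytest.raises(NyquistError):
            spectral.morlet_transform(_tone(4.0), np.array([300.0]))


class TestCoherence:
    def test_identical_signals_unity(self):
        wt = spectral.morlet_transform(_tone(4.0), np.array([3.0, 4.0, 5.0]))
        coh, defined = spectral.wavelet_coherence(wt, wt)
        assert defined.any()
        assert np.nanmax(np.abs(coh[defined] - 1.0)) < 1e-9

    def test_delayed_signal_phase(self):
        delay_cycles = 0.2
        a = _tone(4.0)
        b = _tone(4.0, phase=-2 * np.pi * delay_cycles)
        wa = spectral.morlet_transform(a, np.array([4.0]))
        wb = spectral.morlet_transform(b, np.array([4.0]))
        coh, defined = spectral.wavelet_coherence(wa, wb)
        assert np.nanmean(coh[defined]) > 0.999
        cross_phase = np.angle(wa.coeffs[0] * np.conj(wb.coeffs[0]))[defined[0]]
        assert np.median(np.abs(np.angle(
            np.exp(1j * (cross_phase - 2 * np.pi * delay_cycles))))) < 0.02

    def test_independent_noise_below_null_bound(self, rng):
        dur = 100.0
        a = LfpSignal(rng.standard_normal(int(dur * RATE)), RATE)
        b = LfpSignal(rng.standard_normal(int(dur * RATE)), RATE)
        freqs = np.arange(3.0, 6.0 + 1e-9, 0.5)
        wa = spectral.morlet_transform(a, freqs)
        wb = spectral.morlet_transform(b, freqs)
        coh, defined = spectral.wavelet_coherence(wa, wb)
        assert np.nanmean(coh[defined]) < 0.45

    def test_grid_mismatch(self):
        wa = spectral.morlet_transform(_tone(4.0), np.array([4.0]))
        wb = spectral.morlet_transform(_tone(4.0), np.array([5.0]))
        with pytest.raises(IncompatibleTransformError):
            spectral.wavelet_coherence(wa, wb)

    def test_noise_monotonically_degrades_coherence(self, rng):
        base, _ = synthetic.gen_lfp_pair(60.0, RATE, coupling=1.0, noise_sd=0.0, seed=2)
        freqs = np.arange(3.0, 6.0 + 1e-9, 0.5)
        wa = spectral.morlet_transform(base, freqs)
        vals = []
        for sd in (0.0, 5.0, 20.0, 80.0):
            noisy = LfpSignal(base.samples + sd * rng.standard_normal(base.n), RATE)
            wb = spectral.morlet_transform(noisy, freqs)
            coh, defined = spectral.wavelet_coherence(wa, wb)
            vals.append(np.nanmean(coh[defined]))
        assert np.all(np.diff(vals) < 0)


class TestBandAverage:
    def test_constant_field(self):
        freqs = np.arange(1.0, 10.0 + 1e-9, 0.5)
        times = np.arange(100) / 100
        field = np.full((freqs.size, times.size), 3.7)
        series = spectral.band_average(field, freqs, times, (3.0, 6.0))
        assert np.allclose(series.values, 3.7)

    def test_inclusive_endpoints_seven_rows(self):
        freqs = np.arange(1.0, 10.0 + 1e-9, 0.5)
        sel = (freqs >= 3.0) & (freqs <= 6.0)
        assert sel.sum() == 7
        times = np.arange(10) / 10.0
        field = np.zeros((freqs.size, times.size))
        field[sel] = 1.0  # mean over exactly those 7 rows must be 1
        series = spectral.band_average(field, freqs, times, (3.0, 6.0))
        assert np.allclose(series.values, 1.0)

    def test_empty_band(self):
        with pytest.raises(InvalidParameterError):
            spectral.band_average(np.zeros((3, 4)), np.array([1.0, 2.0, 10.0]),
                                  np.arange(4.0), (3.0, 6.0))


class TestPositionMap:
    def test_constant_series(self, behavior_session, linearized):
        track, _, _ = behavior_session
        times = np.arange(0, track.timestamps[-1] + 1, 0.01)
        series = BandSeries(times, np.full(times.size, 2.5), (3, 6), 100.0)
        pm = spectral.position_resolved(series, linearized, "choice")
        assert np.allclose(pm.mean[pm.count > 0], 2.5)
        assert pm.center_arm_mean() == pytest.approx(2.5)

    def test_identity_ramp(self, behavior_session, linearized):
        # series value equal to the linear position by construction
        track, _, _ = behavior_session
        run = linearized[0]
        series = BandSeries(run.times, run.linear_pos, (3, 6), 25.0)
        pm = spectral.position_resolved(series, [run], run.phase)
        sel = pm.count > 0
        assert np.allclose(pm.mean[sel], pm.positions[sel], atol=0.5)

    def test_choice_amplitude_doubling_gives_power_ratio_4(self):
        track, trials, _ = synthetic.gen_behavior_session(8, seed=21)
        dur = float(track.timestamps[-1]) + 0.1
        amp = {"sample": 20.0, "choice": 40.0}
        lfp, _ = synthetic.gen_lfp_pair(dur, RATE, amp_by_phase=amp, coupling=1.0,
                                        noise_sd=1.0, trials=trials, seed=22)
        runs = behavior.linearize_session(track, trials)
        series = spectral.band_power(lfp, freqs=np.arange(3.0, 6.0 + 1e-9, 0.5))
        series.values = series.values**2  # amplitude -> power
        ps = spectral.position_resolved(series, runs, "sample").center_arm_mean()
        pc = spectral.position_resolved(series, runs, "choice").center_arm_mean()
        assert 3.0 <= pc / ps <= 5.0


class TestPowerCrossCorrelation:
    def _band(self, values, rate=200.0):
        return BandSeries(np.arange(len(values)) / rate, np.asarray(values, float),
                          (3, 6), rate)

    def test_self_peak_at_zero(self, rng):
        a = self._band(rng.standard_normal(4000).cumsum())
        lags, r = spectral.power_crosscorrelation(a, a)
        assert lags[np.argmax(r)] == pytest.approx(0.0)
        assert np.max(r) == pytest.approx(1.0)

    def test_50ms_shift_recovered(self, rng):
        rate = 200.0
        x = rng.standard_normal(6000).cumsum()
        a = self._band(x, rate)
        shift = int(0.05 * rate)
        b = self._band(np.concatenate([np.full(shift, np.nan), x[:-shift]]), rate)
        lags, r = spectral.power_crosscorrelation(a, b)
        assert abs(lags[np.nanargmax(r)] - 0.05) <= 0.005

    def test_independent_series_low_correlation(self, rng):
        a = self._band(rng.standard_normal(20000))
        b = self._band(rng.standard_normal(20000))
        _, r = spectral.power_crosscorrelation(a, b)
        assert np.max(np.abs(r)) < 0.3

    def test_constant_series_rejected(self):
        a = self._band(np.ones(4000))
        with pytest.raises(InvalidParameterError):
            spectral.power_crosscorrelation(a, a)
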