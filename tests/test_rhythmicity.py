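"""Correlograms, exp+sin fitting, circular-linear r, and the jitter
surrogate test."""

import numpy as np
import pytest

from fourhz import rhythmicity, synthetic
from fourhz.core import Correlogram, InsufficientDataError, SpikeTrain, UndefinedStatsError


class TestAutocorrelogram:
    def test_periodic_train_peaks(self):
        t = np.arange(600) * 0.196  # 196 ms period (mid-bin, avoids edge ties)
        cg = rhythmicity.autocorrelogram(SpikeTrain(t))
        peak_bins = np.nonzero(cg.counts > 0)[0]
        peak_lags = cg.lags_ms[peak_bins]
        assert set(np.round(peak_lags)) == {195.0, 395.0}  # the 196 & 392 ms lags
        assert np.all(cg.counts[~np.isin(np.arange(cg.counts.size), peak_bins)] == 0)

    def test_poisson_expectation(self, rng):
        lam, T = 10.0, 600.0
        t = np.sort(rng.uniform(0, T, rng.poisson(lam * T)))
        cg = rhythmicity.autocorrelogram(SpikeTrain(t))
        expect = cg.n_ref * lam * 0.01
        assert np.all(np.abs(cg.counts - expect) < 4 * np.sqrt(expect))

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            rhythmicity.autocorrelogram(SpikeTrain(np.arange(10.0)))

    def test_windows_restrict_pairs(self, rng):
        t = np.sort(rng.uniform(0, 100, 2000))
        full = rhythmicity.autocorrelogram(SpikeTrain(t))
        windowed = rhythmicity.autocorrelogram(SpikeTrain(t), windows=[(0, 50), (60, 100)])
        assert windowed.n_ref < full.n_ref
        assert windowed.counts.sum() < full.counts.sum()


class TestCrosscorrelogram:
    def test_self_pair_mirrors_autocorrelogram(self, rng):
        t = np.sort(rng.uniform(0, 300, 2000))
        a = rhythmicity.autocorrelogram(SpikeTrain(t))
        x = rhythmicity.crosscorrelogram(SpikeTrain(t), SpikeTrain(t))
        pos = x.counts[x.lags_ms > 10]
        neg = x.counts[x.lags_ms < -10][::-1]
        np.testing.assert_array_equal(pos, neg)  # symmetry about 0
        np.testing.assert_array_equal(pos[: a.counts.size], a.counts)

    def test_shifted_copy_peak(self):
        t = np.arange(0, 120, 0.4)
        shifted = SpikeTrain(t + 0.030)
        cg = rhythmicity.crosscorrelogram(SpikeTrain(t), shifted)
        assert cg.lags_ms[np.argmax(cg.counts)] == pytest.approx(35.0)  # 30-40 ms bin

    def test_independent_trains_flat(self, rng):
        a = np.sort(rng.uniform(0, 600, 3000))
        b = np.sort(rng.uniform(0, 600, 3000))
        cg = rhythmicity.crosscorrelogram(SpikeTrain(a), SpikeTrain(b))
        expect = cg.n_ref * (3000 / 600) * 0.01
        assert np.all(np.abs(cg.counts - expect) < 4 * np.sqrt(expect))


class TestFit:
    def _model_cg(self, freq_hz, a=50.0, b=1e-5, c=10.0, e=1.0, noise=0.0, rng=None):
        t = np.arange(15, 500, 10.0)
        d = 2 * np.pi * freq_hz / 1000.0
        y = a * np.exp(-b * t**2) + c * np.sin(d * t + e)
        if noise:
            y = y + rng.normal(0, noise, t.size)
        return Correlogram(t, y, 10.0, "auto", 1000)

    def test_exact_model_recovery(self):
        fit = rhythmicity.fit_correlogram(self._model_cg(4.5))
        assert fit.freq_hz == pytest.approx(4.5, abs=0.01)
        assert fit.sse < 1e-10

    def test_flat_correlogram_small_sinusoid(self, rng):
        t = np.arange(15, 500, 10.0)
        y = 40.0 + rng.normal(0, 0.5, t.size)
        fit = rhythmicity.fit_correlogram(Correlogram(t, y, 10.0, "auto", 1000))
        assert fit.c / y.mean() < 0.1

    def test_end_to_end_frequency_recovery(self):
        train = synthetic.gen_rhythmic_train(4.5, 0.8, 5.0, 600.0, seed=5)
        cg = rhythmicity.autocorrelogram(train)
        fit = rhythmicity.fit_correlogram(cg)
        assert fit.freq_hz == pytest.approx(4.5, abs=0.3)

    def test_too_few_bins(self):
        cg = Correlogram(np.arange(15, 100, 10.0), np.ones(9), 10.0, "auto", 500)
        from fourhz.core import InvalidParameterError

        with pytest.raises(InvalidParameterError):
            rhythmicity.fit_correlogram(cg)


class TestCircLinearCorr:
    def test_perfect_association(self):
        t = np.arange(15, 500, 10.0)
        d = 2 * np.pi * 4.0 / 1000
        counts = 5.0 + np.sin(d * t + 0.3)
        r = rhythmicity.circ_linear_corr(counts, d, 0.3, t)
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_offset_invariance(self, rng):
        t = np.arange(15, 500, 10.0)
        d = 2 * np.pi * 4.0 / 1000
        counts = rng.poisson(20, t.size).astype(float)
        r1 = rhythmicity.circ_linear_corr(counts, d, 0.0, t)
        r2 = rhythmicity.circ_linear_corr(counts + 100.0, d, 0.0, t)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_shuffled_counts_near_null(self, rng):
        t = np.arange(15, 500, 10.0)
        d = 2 * np.pi * 4.0 / 1000
        counts = 5.0 + np.sin(d * t + 0.3)
        r_obs = rhythmicity.circ_linear_corr(counts, d, 0.3, t)
        null = [rhythmicity.circ_linear_corr(rng.permutation(counts), d, 0.3, t)
                for _ in range(200)]
        assert r_obs > np.quantile(null, 0.99)

    def test_constant_counts_undefined(self):
        t = np.arange(15, 500, 10.0)
        with pytest.raises(UndefinedStatsError):
            rhythmicity.circ_linear_corr(np.full(t.size, 3.0), 0.03, 0.0, t)


class TestJitterSurrogates:
    def test_modulated_train_detected_full_null(self):
        train = synthetic.gen_rhythmic_train(4.5, 0.8, 5.0, 600.0, seed=6)
        fit = rhythmicity.jitter_surrogate_test(train, n_surr=1000, seed=7)
        assert fit.is_rhythmic and fit.is_4hz
        assert fit.freq_hz == pytest.approx(4.5, abs=0.3)
        assert fit.p_frac < 0.05

    def test_homogeneous_train_not_detected(self):
        train = synthetic.gen_rhythmic_train(4.5, 0.0, 5.0, 600.0, seed=8)
        fit = rhythmicity.jitter_surrogate_test(train, n_surr=200, seed=9)
        assert not fit.is_rhythmic

    def test_jitter_preserves_count_without_windows(self, rng):
        t = np.sort(rng.uniform(0, 100, 500))
        jittered = np.sort(t + rng.uniform(-1, 1, t.size))
        assert jittered.size == t.size  # the unwindowed surrogate keeps every spike

    def test_pair_flag_symmetric(self):
        a = synthetic.gen_rhythmic_train(4.5, 0.8, 5.0, 300.0, seed=10)
        b = synthetic.gen_rhythmic_train(4.5, 0.8, 5.0, 300.0, seed=11)
        f_ab = rhythmicity.jitter_surrogate_test(a, spikes_b=b, n_surr=200, seed=12)
        f_ba = rhythmicity.jitter_surrogate_test(b, spikes_b=a, n_surr=200, seed=12)
        assert f_ab.is_4hz == f_ba.is_4hz

    def test_surrogate_distribution_shift_invariant(self):
        train = synthetic.gen_rhythmic_train(4.5, 0.5, 5.0, 300.0, seed=13)
        shifted = SpikeTrain(train.timestamps + 1000.0)
        f1 = rhythmicity.jitter_surrogate_test(train, n_surr=200, seed=14)
        f2 = rhythmicity.jitter_surrogate_test(shifted, n_surr=200, seed=14)
        # same jitter stream, same relative spike structure -> same surrogate r
        np.testing.assert_allclose(f1.surrogate_r, f2.surrogate_r, atol=1e-9)

    def test_detection_monotone_in_depth(self):
        rates = []
        for depth in (0.0, 0.2, 0.5, 0.8):
            hits = 0
            for s in range(8):
                train = synthetic.gen_rhythmic_train(4.5, depth, 5.0, 300.0,
                                                     seed=100 + s)
                fit = rhythmicity.jitter_surrogate_test(train, n_surr=100,
                                                        seed=200 + s)
                hits += fit.is_rhythmic
            rates.append(hits / 8)
        assert rates[-1] >= 0.9
        assert all(b >= a - 0.2 for a, b in zip(rates, rates[1:]))
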