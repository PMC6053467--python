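"""Ground-truth recovery and contracts of the synthetic-session generator."""

import numpy as np
import pytest
from scipy.special import i0, i1

from fourhz import spike_phase, synthetic
from fourhz.core import InconsistentSessionError, InvalidParameterError


class TestLfpPair:
    def test_full_coupling_no_noise_identical(self):
        a, b = synthetic.gen_lfp_pair(10.0, 500.0, coupling=1.0, noise_sd=0.0, seed=0)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_zero_coupling_uncorrelated(self):
        a, b = synthetic.gen_lfp_pair(100.0, 500.0, coupling=0.0, noise_sd=0.0, seed=1)
        r = np.corrcoef(a.samples, b.samples)[0, 1]
        assert abs(r) < 0.1

    def test_determinism(self):
        a1, b1 = synthetic.gen_lfp_pair(5.0, 500.0, seed=42)
        a2, b2 = synthetic.gen_lfp_pair(5.0, 500.0, seed=42)
        np.testing.assert_array_equal(a1.samples, a2.samples)
        np.testing.assert_array_equal(b1.samples, b2.samples)

    def test_band_limited(self):
        a, _ = synthetic.gen_lfp_pair(60.0, 500.0, band=(3.0, 6.0), coupling=1.0,
                                      noise_sd=0.0, seed=5)
        from scipy.signal import welch

        f, p = welch(a.samples, fs=500.0, nperseg=4096)
        in_band = p[(f >= 2.5) & (f <= 6.5)].sum()
        assert in_band / p.sum() > 0.95

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            synthetic.gen_lfp_pair(10.0, 500.0, coupling=np.nan)
        with pytest.raises(InvalidParameterError):
            synthetic.gen_lfp_pair(10.0, 20.0)  # rate < 4x band top

    def test_trials_past_duration(self, behavior_session):
        _, trials, _ = behavior_session
        with pytest.raises(InconsistentSessionError):
            synthetic.gen_lfp_pair(10.0, 500.0, trials=trials,
                                   amp_by_phase={"sample": 1, "choice": 2})


@pytest.fixture(scope="module")
def lfp():
    return synthetic.gen_lfp_pair(400.0, 500.0, coupling=1.0, noise_sd=2.0, seed=3)[0]


class TestPhaseLockedTrain:
    @pytest.mark.parametrize("kappa", [0.0, 1.0, 2.0])
    def test_mrl_matches_bessel_ratio(self, lfp, kappa):
        # empirical MRL converges to I1(k)/I0(k) (n ~ 5000 spikes)
        train = synthetic.gen_phase_locked_train(lfp, kappa=kappa, mu=np.pi / 2,
                                                 base_rate=14.0, seed=int(kappa))
        phases = spike_phase.spike_phases_for_lfp(train, lfp)
        stats = spike_phase.phase_lock_stats(phases)
        assert stats.n_spikes > 4500
        assert stats.mrl == pytest.approx(i1(kappa) / i0(kappa), abs=0.03)

    def test_kappa0_uniform(self, lfp):
        train = synthetic.gen_phase_locked_train(lfp, kappa=0.0, base_rate=6.0, seed=8)
        phases = spike_phase.spike_phases_for_lfp(train, lfp)
        n = len(phases)
        assert spike_phase.phase_lock_stats(phases).mrl < np.sqrt(-np.log(0.01) / n) + 0.01

    def test_high_kappa_concentrates_at_mu(self, lfp):
        mu = -2.0
        train = synthetic.gen_phase_locked_train(lfp, kappa=50.0, mu=mu,
                                                 base_rate=6.0, seed=9)
        phases = spike_phase.spike_phases_for_lfp(train, lfp)
        rel = np.angle(np.exp(1j * (phases - mu)))
        circ_sd = np.sqrt(-2 * np.log(np.abs(np.exp(1j * rel).mean())))
        assert circ_sd < 0.2
        assert abs(np.angle(np.exp(1j * phases).mean()) - mu) < 0.1

    def test_rate_conservation(self, lfp):
        train = synthetic.gen_phase_locked_train(lfp, kappa=2.0, base_rate=5.0, seed=10)
        expect = 5.0 * lfp.duration
        assert abs(train.n - expect) < 4 * np.sqrt(expect)

    def test_negative_kappa_rejected(self, lfp):
        with pytest.raises(InvalidParameterError):
            synthetic.gen_phase_locked_train(lfp, kappa=-1.0)


class TestRhythmicTrain:
    def test_expected_count(self):
        train = synthetic.gen_rhythmic_train(4.5, 0.8, 5.0, 600.0, seed=0)
        assert abs(train.n - 3000) < 4 * np.sqrt(3000)

    def test_depth_zero_flat_autocorrelogram(self):
        from fourhz.rhythmicity import autocorrelogram

        train = synthetic.gen_rhythmic_train(4.5, 0.0, 10.0, 600.0, seed=1)
        cg = autocorrelogram(train)
        assert cg.counts.max() / cg.counts.min() < 1.5

    def test_depth_above_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            synthetic.gen_rhythmic_train(4.5, 1.2, 5.0, 60.0)

    def test_determinism(self):
        t1 = synthetic.gen_rhythmic_train(4.5, 0.5, 5.0, 60.0, seed=3)
        t2 = synthetic.gen_rhythmic_train(4.5, 0.5, 5.0, 60.0, seed=3)
        np.testing.assert_array_equal(t1.timestamps, t2.timestamps)


class TestBehaviorSession:
    def test_sampling_interval_40ms_exact(self, behavior_session):
        track, _, _ = behavior_session
        np.testing.assert_allclose(np.diff(track.timestamps), 0.04, rtol=0, atol=1e-12)

    def test_nonmatch_rule_all_correct(self, behavior_session):
        _, trials, _ = behavior_session
        assert trials["correct"].all()
        for _, grp in trials.groupby("trial"):
            arms = grp.sort_values("t_start")["goal_arm"].tolist()
            assert arms[0] != arms[1]

    def test_error_trials_marked_incorrect(self):
        _, trials, _ = synthetic.gen_behavior_session(40, seed=2, p_error=0.5)
        wrong = ~trials["correct"]
        assert wrong.any()
        for _, grp in trials[trials["trial"].isin(trials[wrong]["trial"])].groupby("trial"):
            arms = grp.sort_values("t_start")["goal_arm"].tolist()
            assert arms[0] == arms[1]


class TestTaskModulatedPopulation:
    def test_rates_by_phase(self, behavior_session):
        _, trials, _ = behavior_session
        from fourhz.core import run_windows

        units = synthetic.gen_task_modulated_population(2, [3.0, 1.0], trials,
                                                        seed=4, base_rate=4.0)
        for ratio, u in zip([3.0, 1.0], units):
            for phase, target in (("sample", 4.0), ("choice", 4.0 * ratio)):
                wins = run_windows(trials, phase)
                dur = sum(b - a for a, b in wins)
                n = len(u.in_windows(wins))
                assert abs(n - target * dur) < 4 * np.sqrt(target * dur) + 1

    def test_ratio_validation_and_determinism(self, behavior_session):
        _, trials, _ = behavior_session
        with pytest.raises(InvalidParameterError):
            synthetic.gen_task_modulated_population(1, [0.0], trials)
        u1 = synthetic.gen_task_modulated_population(1, [2.0], trials, seed=5)[0]
        u2 = synthetic.gen_task_modulated_population(1, [2.0], trials, seed=5)[0]
        np.testing.assert_array_equal(u1.timestamps, u2.timestamps)


class TestSession:
    def test_session_consistent(self):
        s = synthetic.gen_session(n_trials=4, n_units=2, seed=6)
        dur = s.lfp_vta.duration
        for u in s.units:
            assert u.timestamps.min() >= 0 and u.timestamps.max() <= dur
        assert s.trials["t_end"].max() <= dur
        assert len(s.pharmacology) == len(s.units)

    def test_adding_units_does_not_change_lfp(self):
        s2 = synthetic.gen_session(n_trials=3, n_units=2, seed=7)
        s4 = synthetic.gen_session(n_trials=3, n_units=4, seed=7)
        np.testing.assert_array_equal(s2.lfp_vta.samples, s4.lfp_vta.samples)
        np.testing.assert_array_equal(s2.units[0].timestamps, s4.units[0].timestamps)
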