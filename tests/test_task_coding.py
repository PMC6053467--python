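"""Per-unit task-variable tests, the LDA decoder, and proportion/overlap
statistics."""

import numpy as np
import pandas as pd
import pytest

from fourhz import behavior, synthetic, task_coding
from fourhz.core import SpikeTrain


class TestPhaseSelectivity:
    def test_modulated_unit_flagged(self, behavior_session, linearized):
        _, trials, _ = behavior_session
        unit = synthetic.gen_task_modulated_population(1, [3.0], trials, seed=1,
                                                       base_rate=4.0)[0]
        res = task_coding.phase_selectivity(unit, trials, linearized)
        assert res.selective and res.direction == "choice-preferring"

    def test_silent_unit_excluded(self, behavior_session, linearized):
        _, trials, _ = behavior_session
        res = task_coding.phase_selectivity(SpikeTrain(np.empty(0), unit_id="mute"),
                                            trials, linearized)
        assert res.excluded and "zero-variance" in res.reason

    def test_translation_invariance(self, behavior_session, linearized):
        track, trials, _ = behavior_session
        unit = synthetic.gen_task_modulated_population(1, [2.0], trials, seed=2)[0]
        r1 = task_coding.phase_selectivity(unit, trials, linearized)
        dt = 500.0
        trials2 = trials.copy()
        trials2[["t_start", "t_end"]] += dt
        runs2 = [type(r)(r.trial, r.phase, r.arm, r.times + dt, r.linear_pos)
                 for r in linearized]
        r2 = task_coding.phase_selectivity(
            SpikeTrain(unit.timestamps + dt), trials2, runs2)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)
        assert r1.selective == r2.selective


class TestDecoder:
    def test_disjoint_supports_perfect(self):
        X = np.vstack([np.full((10, 2), 1.0) + np.random.default_rng(0).normal(0, 0.05, (10, 2)),
                       np.full((10, 2), 9.0) + np.random.default_rng(1).normal(0, 0.05, (10, 2))])
        y = np.array([0] * 10 + [1] * 10)
        assert task_coding.decode_task_phase(X, y).accuracy == 100.0

    def test_single_neuron_excluded(self):
        X = np.random.default_rng(0).normal(size=(10, 1))
        res = task_coding.decode_task_phase(X, np.array([0, 1] * 5))
        assert res.excluded

    def test_shuffled_labels_chance(self, rng):
        X = rng.normal(4, 1, size=(40, 3))
        accs = []
        for _ in range(100):
            y = rng.permutation([0, 1] * 20)
            accs.append(task_coding.decode_task_phase(X, y).accuracy)
        assert 45.0 <= np.mean(accs) <= 55.0

    def test_matches_sklearn_lda_predictions(self, rng):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from sklearn.model_selection import LeaveOneOut, cross_val_score

        X = rng.normal(0, 1, size=(30, 3))
        X[15:] += 0.8
        y = np.array([0] * 15 + [1] * 15)
        mine = task_coding._lda_loo_accuracy(X, y)
        ref = cross_val_score(
            LinearDiscriminantAnalysis(priors=[0.5, 0.5]), X, y,
            cv=LeaveOneOut()).mean() * 100
        assert mine == pytest.approx(ref, abs=1e-9)


class TestTurnSelectivity:
    def _turns(self, n_per_side, spacing=20.0):
        events = []
        for i in range(2 * n_per_side):
            events.append((100.0 + i * spacing, "L" if i % 2 == 0 else "R"))
        return events

    def test_direction_tuned_unit_flagged(self, rng):
        events = self._turns(20)
        spikes = []
        for onset, d in events:
            rate = 2.0 if d == "L" else 8.0
            spikes.append(rng.uniform(onset - 0.5, onset + 0.5, rng.poisson(rate)))
        unit = SpikeTrain(np.sort(np.concatenate(spikes)), unit_id="turn")
        res = task_coding.turn_selectivity(unit, events)
        assert res.selective and res.direction == "R-preferring"

    def test_label_flip_symmetric(self, rng):
        events = self._turns(10)
        unit = SpikeTrain(np.sort(rng.uniform(0, 900, 2000)), unit_id="u")
        r1 = task_coding.turn_selectivity(unit, events)
        flipped = [(t, "L" if d == "R" else "R") for t, d in events]
        r2 = task_coding.turn_selectivity(unit, flipped)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_too_few_turns_excluded(self, rng):
        events = self._turns(3)
        unit = SpikeTrain(np.sort(rng.uniform(0, 300, 500)))
        assert task_coding.turn_selectivity(unit, events).excluded

    def test_anova_matches_statsmodels(self, rng):
        statsmodels = pytest.importorskip("statsmodels")
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        n_l, n_r, n_bins = 7, 12, 10
        y = rng.normal(5, 2, size=(n_l + n_r, n_bins))
        dirs = np.array(["L"] * n_l + ["R"] * n_r)
        p_dir, p_int, F_dir, F_int = task_coding.two_way_anova_rates(y, dirs)

        df = pd.DataFrame({
            "rate": y.ravel(),
            "direction": np.repeat(dirs, n_bins),
            "time": np.tile(np.arange(n_bins), n_l + n_r),
        })
        fit = ols("rate ~ C(time) * C(direction)", df).fit()
        tbl = sm.stats.anova_lm(fit, typ=2)
        assert p_dir == pytest.approx(tbl.loc["C(direction)", "PR(>F)"], rel=1e-6)
        assert p_int == pytest.approx(tbl.loc["C(time):C(direction)", "PR(>F)"], rel=1e-6)


class TestRewardResponsiveness:
    def test_rate_step_flagged(self, rng):
        arrivals = 100.0 + np.arange(20) * 30.0
        base = np.sort(rng.uniform(0, 800, rng.poisson(2.0 * 800)))
        extra = np.concatenate([rng.uniform(a - 0.5, a + 0.5, rng.poisson(6.0))
                                for a in arrivals])
        unit = SpikeTrain(np.sort(np.concatenate([base, extra])))
        assert task_coding.reward_responsiveness(unit, arrivals).selective

    def test_rate_decrease_not_flagged(self, rng):
        arrivals = 100.0 + np.arange(20) * 30.0
        base = np.sort(rng.uniform(0, 800, rng.poisson(8.0 * 800)))
        keep = np.ones(base.size, dtype=bool)
        for a in arrivals:  # silence the response window
            keep &= ~((base >= a - 0.5) & (base <= a + 0.5))
        unit = SpikeTrain(base[keep])
        assert not task_coding.reward_responsiveness(unit, arrivals).selective

    def test_too_few_arrivals_excluded(self, rng):
        unit = SpikeTrain(np.sort(rng.uniform(0, 100, 300)))
        assert task_coding.reward_responsiveness(unit, [10.0, 20.0]).excluded


class TestProportionsAndOverlap:
    def test_identical_tables_fisher_p1(self):
        res = task_coding.proportion_tests((10, 100), (10, 100))
        assert res["fisher_p"] == 1.0

    def test_binomial_closed_form(self):
        res = task_coding.proportion_tests((0, 50), (0, 50),
                                           binomial_alternative="less")
        assert res["binomial_p_a"] == pytest.approx(0.95**50, rel=1e-9)

    def test_large_difference_tiny_p(self):
        res = task_coding.proportion_tests((50, 100), (5, 100))
        assert res["fisher_p"] < 1e-6

    def test_overlap_independent_labels(self, rng):
        n = 1000
        lab = pd.DataFrame({
            "task_phase": rng.uniform(size=n) < 0.2,
            "turn": rng.uniform(size=n) < 0.2,
            "reward": rng.uniform(size=n) < 0.2,
        })
        out = task_coding.category_overlap(lab)
        for row in out.itertuples(index=False):
            sd = np.sqrt(max(row.expected, 1.0))
            assert abs(row.observed - row.expected) < 4 * sd

    def test_overlap_degenerate_cases(self):
        all_sel = pd.DataFrame({"a": [True] * 10, "b": [True] * 10})
        out = task_coding.category_overlap(all_sel)
        full = out[(out["a"]) & (out["b"])].iloc[0]
        assert full["observed"] == 10 and full["expected"] == pytest.approx(10.0)
        none_sel = pd.DataFrame({"a": [False] * 10, "b": [False] * 10})
        out = task_coding.category_overlap(none_sel)
        assert out[(out["a"]) | (out["b"])]["observed"].sum() == 0
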