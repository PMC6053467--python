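"""Task-variable coding of single units and population decoding.

Per-unit tests (all at alpha = .05, no multiplicity correction, matching the
per-unit convention of the analyses this package implements):

* task-phase selectivity — per-run firing rate from run start to the
  decision point (linear position 50), sample vs choice, Wilcoxon rank-sum;
* turn selectivity — rates in 100 ms bins from -500 to +500 ms around turn
  onset, two-way ANOVA (Time x Direction), selective on a Direction main
  effect or interaction;
* reward responsiveness — rate -500..+500 ms around reward-well arrival vs
  the -1000..-500 ms baseline, one-sided (higher) sign-rank.

Population decoding uses a Gaussian linear discriminant with pooled
covariance (diagonal shrinkage 1e-6) and leave-one-out cross-validation over
individual task phases; sessions contribute only if they hold at least two
neurons of the class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DecodingFailedError,
    DecodingResult,
    InvalidParameterError,
    SelectivityResult,
    SpikeTrain,
)

ALPHA = 0.05
DECISION_POS = 50.0
TURN_BINS = np.arange(-0.5, 0.5 + 1e-9, 0.1)  # 10 bins of 100 ms
REWARD_WINDOW = (-0.5, 0.5)
REWARD_BASELINE = (-1.0, -0.5)


# --------------------------------------------------------------------------- #
# task-phase selectivity & decoding


def _count(spikes: np.ndarray, a: float, b: float) -> int:
    return int(np.searchsorted(spikes, b) - np.searchsorted(spikes, a))


def run_epochs(trials: pd.DataFrame, linruns) -> pd.DataFrame:
    """Per-run analysis epoch: run start until the decision point.

    The epoch ends at the first behavioral sample with linear position
    >= 50 (or at run end if the run never reaches it).
    """
    lin = {(r.trial, r.phase): r for r in linruns}
    rows = []
    for _, row in trials.iterrows():
        key = (int(row["trial"]), row["phase"])
        t_stop = row["t_end"]
        r = lin.get(key)
        if r is not None:
            hit = np.nonzero(r.linear_pos >= DECISION_POS)[0]
            if hit.size:
                t_stop = float(r.times[hit[0]])
        rows.append(dict(trial=row["trial"], phase=row["phase"],
                         t_start=row["t_start"], t_stop=t_stop))
    return pd.DataFrame(rows)


def epoch_rates(spikes: SpikeTrain, epochs: pd.DataFrame) -> np.ndarray:
    """Firing rate of one unit in every run epoch (Hz)."""
    t = spikes.timestamps
    rates = np.empty(len(epochs))
    for i, row in enumerate(epochs.itertuples(index=False)):
        dur = row.t_stop - row.t_start
        rates[i] = _count(t, row.t_start, row.t_stop) / dur if dur > 0 else np.nan
    return rates


def phase_selectivity(
    spikes: SpikeTrain, trials: pd.DataFrame, linruns, alpha: float = ALPHA
) -> SelectivityResult:
    """Sample-vs-choice rank-sum test of center-arm firing rates."""
    epochs = run_epochs(trials, linruns)
    rates = epoch_rates(spikes, epochs)
    ok = np.isfinite(rates)
    is_choice = (epochs["phase"] == "choice").to_numpy()
    rs = rates[ok & ~is_choice]
    rc = rates[ok & is_choice]
    if rs.size < 5 or rc.size < 5:
        return SelectivityResult(spikes.unit_id, "task_phase", np.nan, np.nan, False,
                                 excluded=True, reason="fewer than 5 trials per phase")
    if np.std(np.concatenate([rs, rc])) == 0:
        return SelectivityResult(spikes.unit_id, "task_phase", np.nan, np.nan, False,
                                 excluded=True, reason="zero-variance rates")
    stat, p = stats.mannwhitneyu(rs, rc, alternative="two-sided", method="asymptotic")
    direction = "choice-preferring" if rc.mean() > rs.mean() else "sample-preferring"
    return SelectivityResult(spikes.unit_id, "task_phase", float(stat), float(p),
                             bool(p < alpha), direction=direction)


def build_rate_matrix(units, trials: pd.DataFrame, linruns):
    """(n_runs x n_units) rate matrix and run-phase labels for decoding."""
    epochs = run_epochs(trials, linruns)
    X = np.column_stack([epoch_rates(u, epochs) for u in units])
    y = (epochs["phase"] == "choice").to_numpy().astype(int)
    return X, y


def _lda_loo_accuracy(X: np.ndarray, y: np.ndarray, shrink: float = 1e-6) -> float:
    """Leave-one-out accuracy of a two-class Gaussian LDA (pooled covariance).

    Uniform class priors: the task design is balanced, and empirical priors
    would bias every held-out run toward the opposite class (the training
    fold always has one fewer member of the held-out class).
    """
    n, p = X.shape
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xt, yt = X[mask], y[mask]
        classes = np.unique(yt)
        if classes.size < 2:
            continue
        mus = []
        Sw = np.zeros((p, p))
        for c in classes:
            xc = Xt[yt == c]
            mu = xc.mean(axis=0)
            mus.append(mu)
            Sw += (xc - mu).T @ (xc - mu)
        Sw /= max(Xt.shape[0] - classes.size, 1)
        Sw += shrink * np.eye(p)
        try:
            Sinv = np.linalg.inv(Sw)
        except np.linalg.LinAlgError as exc:
            raise DecodingFailedError("pooled covariance singular after shrinkage") from exc
        scores = [X[i] @ Sinv @ mu - 0.5 * mu @ Sinv @ mu for mu in mus]
        if classes[int(np.argmax(scores))] == y[i]:
            correct += 1
    return 100.0 * correct / n


def decode_task_phase(
    X: np.ndarray,
    labels: np.ndarray,
    session_id: str = "",
    cell_class: str = "",
    min_neurons: int = 2,
    shrink: float = 1e-6,
) -> DecodingResult:
    """Leave-one-out linear-discriminant decoding of task phase.

    ``X`` is runs x neurons firing rates, ``labels`` the run phases (any two
    labels).  Sessions with fewer than ``min_neurons`` neurons or fewer than
    4 labeled runs are excluded (flag, not exception).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise InvalidParameterError("X must be (n_runs, n_neurons) matching labels")
    if X.shape[1] < min_neurons:
        return DecodingResult(session_id, cell_class, X.shape[1], X.shape[0], np.nan,
                              excluded=True,
                              reason=f"fewer than {min_neurons} neurons of the class")
    if y.size < 4 or np.unique(y).size < 2:
        return DecodingResult(session_id, cell_class, X.shape[1], X.shape[0], np.nan,
                              excluded=True, reason="fewer than 4 labeled phases")
    _, yc = np.unique(y, return_inverse=True)
    acc = _lda_loo_accuracy(X, yc, shrink)
    return DecodingResult(session_id, cell_class, X.shape[1], X.shape[0], float(acc))


# --------------------------------------------------------------------------- #
# turn selectivity


def two_way_anova_rates(y: np.ndarray, direction: np.ndarray):
    """Two-way ANOVA (Time x Direction) for turn-aligned binned rates.

    ``y`` is (n_turns, n_bins); ``direction`` the per-turn label.  Every turn
    contributes every time bin, so cell frequencies are proportional, the
    factors are orthogonal, and the closed-form sums of squares are exact.
    Returns (p_direction, p_interaction, F_direction, F_interaction).
    """
    y = np.asarray(y, dtype=float)
    dirs = np.asarray(direction)
    n_turns, n_bins = y.shape
    levels = np.unique(dirs)
    if levels.size != 2:
        raise InvalidParameterError("need exactly two turn directions")
    N = y.size
    grand = y.mean()
    ss_dir = 0.0
    ss_cells = 0.0
    ss_err = 0.0
    for lv in levels:
        block = y[dirs == lv]  # (n_d, n_bins)
        n_d = block.shape[0]
        ss_dir += n_d * n_bins * (block.mean() - grand) ** 2
        cm = block.mean(axis=0)  # cell means over turns
        ss_cells += n_d * np.sum((cm - grand) ** 2)
        ss_err += np.sum((block - cm) ** 2)
    tmeans = y.mean(axis=0)
    # proportional frequencies: the time marginal weights are equal per bin
    ss_time = n_turns * np.sum((tmeans - grand) ** 2)
    ss_int = ss_cells - ss_dir - ss_time
    df_dir, df_time = 1, n_bins - 1
    df_int = df_dir * df_time
    df_err = N - 2 * n_bins
    if df_err <= 0 or ss_err <= 0:
        return np.nan, np.nan, np.nan, np.nan
    mse = ss_err / df_err
    F_dir = (ss_dir / df_dir) / mse
    F_int = (max(ss_int, 0.0) / df_int) / mse
    p_dir = float(stats.f.sf(F_dir, df_dir, df_err))
    p_int = float(stats.f.sf(F_int, df_int, df_err))
    return p_dir, p_int, float(F_dir), float(F_int)


def turn_aligned_rates(spikes: SpikeTrain, turn_events) -> tuple[np.ndarray, np.ndarray]:
    """Rates in 100 ms bins -500..+500 ms around each turn onset."""
    t = spikes.timestamps
    onsets = np.asarray([ev[0] for ev in turn_events], dtype=float)
    dirs = np.asarray([ev[1] for ev in turn_events])
    rates = np.empty((onsets.size, TURN_BINS.size - 1))
    width = TURN_BINS[1] - TURN_BINS[0]
    for i, t0 in enumerate(onsets):
        counts = np.histogram(t, bins=t0 + TURN_BINS)[0]
        rates[i] = counts / width
    return rates, dirs


def turn_selectivity(
    spikes: SpikeTrain, turn_events, alpha: float = ALPHA
) -> SelectivityResult:
    """Left-vs-right ANOVA on turn-aligned binned rates (sample and choice
    runs combined); selective on a Direction main effect or Time x Direction
    interaction."""
    rates, dirs = turn_aligned_rates(spikes, turn_events)
    n_l = int(np.sum(dirs == "L"))
    n_r = int(np.sum(dirs == "R"))
    if n_l < 5 or n_r < 5:
        return SelectivityResult(spikes.unit_id, "turn", np.nan, np.nan, False,
                                 excluded=True, reason="fewer than 5 turns per direction")
    if np.std(rates) == 0:
        return SelectivityResult(spikes.unit_id, "turn", np.nan, np.nan, False,
                                 excluded=True, reason="zero-variance rates")
    p_dir, p_int, F_dir, _ = two_way_anova_rates(rates, dirs)
    if not np.isfinite(p_dir):
        return SelectivityResult(spikes.unit_id, "turn", np.nan, np.nan, False,
                                 excluded=True, reason="degenerate ANOVA design")
    p = min(p_dir, p_int)
    mean_l = rates[dirs == "L"].mean()
    mean_r = rates[dirs == "R"].mean()
    direction = "R-preferring" if mean_r > mean_l else "L-preferring"
    return SelectivityResult(spikes.unit_id, "turn", float(F_dir), float(p),
                             bool(p_dir < alpha or p_int < alpha), direction=direction)


# --------------------------------------------------------------------------- #
# reward responsiveness


def reward_responsiveness(
    spikes: SpikeTrain, reward_arrivals, alpha: float = ALPHA
) -> SelectivityResult:
    """One-sided sign-rank test of the rate -500..+500 ms around arrival
    against the rate 500-1000 ms before arrival."""
    arrivals = np.asarray(reward_arrivals, dtype=float)
    if arrivals.size < 5:
        return SelectivityResult(spikes.unit_id, "reward", np.nan, np.nan, False,
                                 excluded=True, reason="fewer than 5 rewarded arrivals")
    t = spikes.timestamps
    w_dur = REWARD_WINDOW[1] - REWARD_WINDOW[0]
    b_dur = REWARD_BASELINE[1] - REWARD_BASELINE[0]
    resp = np.array([_count(t, a + REWARD_WINDOW[0], a + REWARD_WINDOW[1]) / w_dur
                     for a in arrivals])
    base = np.array([_count(t, a + REWARD_BASELINE[0], a + REWARD_BASELINE[1]) / b_dur
                     for a in arrivals])
    diffs = resp - base
    if np.all(diffs == 0):
        return SelectivityResult(spikes.unit_id, "reward", 0.0, 1.0, False)
    stat, p = stats.wilcoxon(resp, base, alternative="greater",
                             zero_method="zsplit", method="approx")
    return SelectivityResult(spikes.unit_id, "reward", float(stat), float(p),
                             bool(p < alpha), direction="reward-excited")


# --------------------------------------------------------------------------- #
# proportions & overlap


def proportion_tests(
    counts_a: tuple, counts_b: tuple, chance: float = ALPHA,
    binomial_alternative: str = "two-sided",
) -> dict:
    """Fisher's exact test between two selective-cell proportions plus exact
    binomial tests of each against the chance rate.

    ``counts_a``/``counts_b`` are (k_selective, n_units).
    """
    (ka, na), (kb, nb) = counts_a, counts_b
    if na <= 0 or nb <= 0:
        raise InvalidParameterError("n must be > 0")
    table = [[ka, na - ka], [kb, nb - kb]]
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    binom_a = stats.binomtest(ka, na, chance, alternative=binomial_alternative).pvalue
    binom_b = stats.binomtest(kb, nb, chance, alternative=binomial_alternative).pvalue
    return {
        "fisher_p": float(fisher_p),
        "binomial_p_a": float(binom_a),
        "binomial_p_b": float(binom_b),
    }


def category_overlap(labels: pd.DataFrame) -> pd.DataFrame:
    """Observed vs independence-expected counts over the 8 membership cells.

    ``labels`` has one boolean column per response category (e.g.
    task_phase, turn, reward) and one row per unit.  Expected counts are
    products of the marginal proportions times n; a chi-square-style
    statistic is reported descriptively.
    """
    if len(labels) < 1:
        raise InvalidParameterError("need at least one unit")
    cols = list(labels.columns)
    n = len(labels)
    marg = labels.mean(axis=0)
    rows = []
    for bits in np.ndindex(*([2] * len(cols))):
        member = {c: bool(b) for c, b in zip(cols, bits)}
        obs = int(np.sum(np.all(
            [labels[c].to_numpy() == member[c] for c in cols], axis=0)))
        exp = n * float(np.prod([marg[c] if member[c] else 1 - marg[c] for c in cols]))
        rows.append({**member, "observed": obs, "expected": exp})
    out = pd.DataFrame(rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum(
            np.where(out["expected"] > 0,
                     (out["observed"] - out["expected"]) ** 2 / out["expected"], 0.0)
        )
    out.attrs["chi2"] = float(chi2)
    return out
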