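"""Per-session orchestration: behavior -> spectral -> phase locking ->
rhythmicity -> classification -> task coding.

Every stage writes its intermediates as delimited text under the output
directory and a manifest records package version, config hash, seeds, and
per-stage status.  All stochastic steps draw from seeds derived from the
config seed, so re-running with the same inputs reproduces every output
bitwise.  A stage failure is recorded and later independent stages still
run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from . import __version__, behavior, classify, rhythmicity, spectral, spike_phase, task_coding
from .core import InvalidParameterError, LfpSignal, SyntheticSession, run_windows
from .io import FLOAT_FMT, read_session

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Analysis constants of the pipeline (defaults follow the method)."""

    freq_lo: float = 1.0
    freq_hi: float = 25.0
    freq_step: float = 0.5
    band: tuple = (3.0, 6.0)
    filter_order_s: float = 2.0
    n_surrogates: int = 1000
    jitter_s: float = 1.0
    n_subsamples: int = 1000
    min_spikes_phase: int = 50
    min_spikes_rhythm: int = 100
    alpha: float = 0.05
    seed: int = 0
    spectral_rate: float = 200.0  # LFP is decimated to this for wavelets
    include_pairs: bool = True
    center_arm: tuple = (1.0, 50.0)
    goal_arm: tuple = (51.0, 100.0)

    def __post_init__(self) -> None:
        if self.band[0] >= self.band[1]:
            raise InvalidParameterError(f"band {self.band} must be increasing")
        if not (self.freq_lo <= self.band[0] and self.band[1] <= self.freq_hi):
            raise InvalidParameterError("band must lie within the frequency grid")
        for name in ("n_surrogates", "n_subsamples", "min_spikes_phase",
                     "min_spikes_rhythm"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")
        if not (0 < self.alpha < 1):
            raise InvalidParameterError("alpha must lie in (0, 1)")

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.freq_lo, self.freq_hi + 1e-9, self.freq_step)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["center_arm"] = list(self.center_arm)
        d["goal_arm"] = list(self.goal_arm)
        return d

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Read a ``key = value`` structured text config."""
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            val = val.strip()
            if key in ("band", "center_arm", "goal_arm"):
                kwargs[key] = tuple(float(v) for v in val.split(","))
            elif key in ("include_pairs",):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif key in ("n_surrogates", "n_subsamples", "min_spikes_phase",
                         "min_spikes_rhythm", "seed"):
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def _decimate(lfp: LfpSignal, target_rate: float) -> LfpSignal:
    factor = int(round(lfp.rate / target_rate))
    if factor <= 1:
        return lfp
    out = resample_poly(lfp.samples, 1, factor)
    return LfpSignal(out, rate=lfp.rate / factor, region=lfp.region, t0=lfp.t0)


# --------------------------------------------------------------------------- #
# stages


def _stage_behavior(session, config, out):
    runs = behavior.linearize_session(session.track, session.trials)
    rows = []
    for r in runs:
        for t, p in zip(r.times, r.linear_pos):
            rows.append(dict(trial=r.trial, phase=r.phase, arm=r.arm,
                             timestamp_s=round(t, 6), linear_pos=round(p, 4)))
    _write_tsv(out / "linearized.tsv", pd.DataFrame(rows))

    events = []
    for _, row in session.trials.iterrows():
        win = (row["t_start"], row["t_end"])
        rec = dict(trial=int(row["trial"]), phase=row["phase"])
        try:
            t_turn, direction = behavior.detect_turn_onset(session.track, win)
            rec.update(turn_onset_s=round(t_turn, 6), turn_direction=direction)
        except behavior.NoTurnDetectedError:
            rec.update(turn_onset_s=np.nan, turn_direction="none")
        lin = next(r for r in runs if r.trial == row["trial"] and r.phase == row["phase"])
        try:
            rec["reward_arrival_s"] = round(behavior.detect_reward_arrival(lin), 6)
        except behavior.NoArrivalError:
            rec["reward_arrival_s"] = np.nan
        _, sp = behavior.compute_speed(session.track, win)
        rec["mean_speed"] = round(float(np.mean(sp)), 4)
        events.append(rec)
    ev = pd.DataFrame(events)
    _write_tsv(out / "run_events.tsv", ev)
    return {"runs": runs, "events": ev}


def _stage_spectral(session, config, out, beh):
    lv = _decimate(session.lfp_vta, config.spectral_rate)
    lp = _decimate(session.lfp_pfc, config.spectral_rate)
    freqs = config.freqs
    wa = spectral.morlet_transform(lv, freqs)
    wb = spectral.morlet_transform(lp, freqs)
    res = {}
    for name, wt in (("VTA", wa), ("PFC", wb)):
        power = wt.power()
        power[~wt.valid] = np.nan
        series = spectral.band_average(power, wt.freqs, wt.times, config.band,
                                       rate=lv.rate, kind="power")
        res[f"power_{name}"] = series
    coh, defined = spectral.wavelet_coherence(wa, wb)
    coh_masked = np.where(defined, coh, np.nan)
    coh_series = spectral.band_average(coh_masked, wa.freqs, wa.times, config.band,
                                       rate=lv.rate, kind="coherence")
    res["coherence"] = coh_series

    summary = []
    for phase in ("sample", "choice"):
        for key in ("power_VTA", "power_PFC", "coherence"):
            pm = spectral.position_resolved(res[key], beh["runs"], phase)
            summary.append(dict(measure=key, phase=phase,
                                center_arm_mean=round(pm.center_arm_mean(), 6)))
            dfm = pd.DataFrame(dict(linear_pos=pm.positions,
                                    mean=np.round(pm.mean, 6), count=pm.count))
            _write_tsv(out / f"positionmap_{key}_{phase}.tsv", dfm)
    _write_tsv(out / "band_summary.tsv", pd.DataFrame(summary))

    lags, r = spectral.power_crosscorrelation(res["power_VTA"], res["power_PFC"])
    _write_tsv(out / "power_lag_correlation.tsv",
               pd.DataFrame(dict(lag_s=np.round(lags, 4), r=np.round(r, 6))))
    return res


def _stage_phaselock(session, config, out, beh):
    rows = []
    for k, unit in enumerate(session.units):
        local = session.lfp_vta if unit.region == "VTA" else session.lfp_pfc
        for lfp in (local,):
            ps = spike_phase.spike_phases_for_lfp(
                unit, lfp, config.band, windows=run_windows(session.trials, "sample"))
            pc = spike_phase.spike_phases_for_lfp(
                unit, lfp, config.band, windows=run_windows(session.trials, "choice"))
            comp = spike_phase.matched_subsample_comparison(
                ps, pc, n_subsamples=config.n_subsamples,
                min_spikes=config.min_spikes_phase,
                seed=config.seed * 1009 + k,
            )
            row = dict(unit_id=unit.unit_id, lfp_region=lfp.region,
                       excluded=int(comp.excluded), reason=comp.reason,
                       seed=comp.seed)
            for side, st in (("sample", comp.stats_sample), ("choice", comp.stats_choice)):
                if st is None:
                    row.update({f"mrl_{side}": np.nan, f"pref_phase_{side}": np.nan,
                                f"rayleigh_p_{side}": np.nan, f"n_{side}": 0})
                else:
                    row.update({f"mrl_{side}": round(st.mrl, 6),
                                f"pref_phase_{side}": round(st.preferred_phase, 6),
                                f"rayleigh_p_{side}": round(st.rayleigh_p, 8),
                                f"n_{side}": st.n_spikes})
            rows.append(row)
    df = pd.DataFrame(rows)
    _write_tsv(out / "phaselock.tsv", df)
    return df


def _stage_rhythmicity(session, config, out):
    windows = run_windows(session.trials)
    rows = []
    for k, unit in enumerate(session.units):
        try:
            fit = rhythmicity.jitter_surrogate_test(
                unit, windows=windows, n_surr=config.n_surrogates,
                jitter_s=config.jitter_s, seed=config.seed * 2003 + k,
                min_spikes=config.min_spikes_rhythm, band=config.band)
            rows.append(dict(unit_a=unit.unit_id, unit_b="", n_spikes=fit.n_spikes,
                             a=round(fit.a, 5), b=round(fit.b, 8), c=round(fit.c, 5),
                             d=round(fit.d, 6), e=round(fit.e, 5),
                             r_obs=round(fit.r_obs, 6),
                             surrogate_q95=round(fit.surrogate_q95, 6),
                             freq_hz=round(fit.freq_hz, 4),
                             is_rhythmic=int(fit.is_rhythmic), is_4hz=int(fit.is_4hz),
                             seed=fit.seed, status="ok"))
        except rhythmicity.InsufficientDataError as exc:
            log.warning("rhythmicity: %s", exc)
            rows.append(dict(unit_a=unit.unit_id, unit_b="", n_spikes=0,
                             a=np.nan, b=np.nan, c=np.nan, d=np.nan, e=np.nan,
                             r_obs=np.nan, surrogate_q95=np.nan, freq_hz=np.nan,
                             is_rhythmic=0, is_4hz=0, seed=-1, status="insufficient-data"))
    if config.include_pairs and len(session.units) >= 2:
        pairs = [(i, j) for i in range(len(session.units))
                 for j in range(i + 1, len(session.units))][:15]
        for i, j in pairs:
            ua, ub = session.units[i], session.units[j]
            try:
                fit = rhythmicity.jitter_surrogate_test(
                    ua, windows=windows, spikes_b=ub, n_surr=config.n_surrogates,
                    jitter_s=config.jitter_s, seed=config.seed * 4001 + i * 97 + j,
                    min_spikes=config.min_spikes_rhythm, band=config.band)
                rows.append(dict(unit_a=ua.unit_id, unit_b=ub.unit_id,
                                 n_spikes=fit.n_spikes, a=round(fit.a, 5),
                                 b=round(fit.b, 8), c=round(fit.c, 5),
                                 d=round(fit.d, 6), e=round(fit.e, 5),
                                 r_obs=round(fit.r_obs, 6),
                                 surrogate_q95=round(fit.surrogate_q95, 6),
                                 freq_hz=round(fit.freq_hz, 4),
                                 is_rhythmic=int(fit.is_rhythmic),
                                 is_4hz=int(fit.is_4hz), seed=fit.seed, status="ok"))
            except rhythmicity.InsufficientDataError as exc:
                log.warning("rhythmicity pair: %s", exc)
    df = pd.DataFrame(rows)
    _write_tsv(out / "rhythmicity.tsv", df)
    return df


def _stage_classification(session, config, out):
    labels = classify.classify_population(session.pharmacology, session.units)
    rows = [dict(unit_id=uid, cell_class=cls) for uid, cls in sorted(labels.items())]
    df = pd.DataFrame(rows)
    da = [p.baseline_rate for p in session.pharmacology if labels[p.unit_id] == "DA"]
    ga = [p.baseline_rate for p in session.pharmacology if labels[p.unit_id] == "GABA"]
    perm_p = np.nan
    if len(da) >= 2 and len(ga) >= 2:
        perm_p = classify.permutation_rate_test(da, ga, n_perm=2000, seed=config.seed)
    _write_tsv(out / "classification.tsv", df)
    (out / "classification_summary.json").write_text(json.dumps(
        dict(n_da=len(da), n_gaba=len(ga),
             rate_permutation_p=None if np.isnan(perm_p) else round(perm_p, 6)),
        indent=1, sort_keys=True))
    return labels


def _stage_task_coding(session, config, out, beh, labels):
    runs = beh["runs"]
    events = beh["events"]
    turn_events = [(row.turn_onset_s, row.turn_direction)
                   for row in events.itertuples(index=False)
                   if np.isfinite(row.turn_onset_s)]
    arrivals = [row.reward_arrival_s for row in events.itertuples(index=False)
                if np.isfinite(row.reward_arrival_s)]
    rows = []
    for unit in session.units:
        for res in (
            task_coding.phase_selectivity(unit, session.trials, runs, config.alpha),
            task_coding.turn_selectivity(unit, turn_events, config.alpha),
            task_coding.reward_responsiveness(unit, arrivals, config.alpha),
        ):
            rows.append(dict(unit_id=res.unit_id, variable=res.variable,
                             statistic=np.round(res.statistic, 6),
                             p=np.round(res.p, 8), selective=int(res.selective),
                             direction=res.direction, excluded=int(res.excluded),
                             reason=res.reason))
    sel = pd.DataFrame(rows)
    _write_tsv(out / "selectivity.tsv", sel)

    dec_rows = []
    for cls in ("DA", "GABA", None):
        members = [u for u in session.units
                   if (labels.get(u.unit_id) == cls if cls else True)]
        name = cls or "all"
        if len(members) == 0:
            continue
        X, y = task_coding.build_rate_matrix(members, session.trials, runs)
        res = task_coding.decode_task_phase(X, y, session_id=session.session_id,
                                            cell_class=name)
        dec_rows.append(dict(session=res.session_id, cell_class=name,
                             n_neurons=res.n_neurons, n_obs=res.n_obs,
                             accuracy_pct=np.round(res.accuracy, 4),
                             excluded=int(res.excluded), reason=res.reason))
    _write_tsv(out / "decoding.tsv", pd.DataFrame(dec_rows))

    by_var = {}
    for var in ("task_phase", "turn", "reward"):
        sub = sel[(sel["variable"] == var) & (sel["excluded"] == 0)]
        by_var[var] = sub.set_index("unit_id")["selective"].astype(bool)
    lab = pd.DataFrame(by_var).dropna().astype(bool)
    if len(lab):
        overlap = task_coding.category_overlap(lab)
        _write_tsv(out / "category_overlap.tsv", overlap)
    return sel


STAGES = ("behavior", "spectral", "phaselock", "rhythmicity", "classification",
          "task_coding")


def run_session(
    session: SyntheticSession | str | Path,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> dict:
    """Run the full per-session analysis; returns the manifest dict.

    ``session`` may be an in-memory session or a directory of session files.
    """
    config = config or PipelineConfig()
    if not isinstance(session, SyntheticSession):
        session = read_session(session)
    out = Path(out_dir or "fourhz_results")
    out.mkdir(parents=True, exist_ok=True)
    manifest = dict(package="fourhz", version=__version__,
                    session=session.session_id, config=config.to_dict(),
                    config_hash=config.config_hash(), stages={})
    beh = labels = None
    for stage in STAGES:
        try:
            if stage == "behavior":
                beh = _stage_behavior(session, config, out)
            elif stage == "spectral":
                _stage_spectral(session, config, out, beh)
            elif stage == "phaselock":
                _stage_phaselock(session, config, out, beh)
            elif stage == "rhythmicity":
                _stage_rhythmicity(session, config, out)
            elif stage == "classification":
                labels = _stage_classification(session, config, out)
            elif stage == "task_coding":
                if labels is None:
                    labels = {}
                _stage_task_coding(session, config, out, beh, labels)
            manifest["stages"][stage] = "ok"
        except Exception as exc:  # a failed stage must not stop independent ones
            log.exception("stage %s failed", stage)
            manifest["stages"][stage] = f"failed: {type(exc).__name__}: {exc}"
            if stage == "behavior":
                break  # everything downstream needs the linearized runs
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
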