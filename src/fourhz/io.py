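"""Session file formats.

Spikes, behavior, trials, and pharmacology are tab-separated text with
``#``-prefixed header lines carrying a schema version and the shared time
origin; the LFP is a NumPy ``.npz`` array container (header keys: rate,
region, t0, units).  All timestamps are seconds from a single session
origin.  Loading is forgiving where the contract allows: unsorted spike
files are sorted with a warning, and behavior gaps above 2x the nominal
sampling interval are flagged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BehaviorTrack,
    LfpSignal,
    PharmacologySummary,
    SpikeTrain,
    SyntheticSession,
    validate_trials,
)

SCHEMA_VERSION = "1"
FLOAT_FMT = "%.17g"  # lossless float64 round-trip


class ParseError(ValueError):
    """A session file does not match its documented schema."""


class BehaviorGapWarning(UserWarning):
    """Gap in the behavior track exceeding 2x the nominal interval."""


@dataclass
class SessionBundle:
    """Paths of one session's files."""

    spikes: Path
    lfp_vta: Path
    lfp_pfc: Path
    behavior: Path
    trials: Path
    pharmacology: Path | None = None
    ground_truth: Path | None = None
    session_id: str = ""
    genotype: str = ""

    @classmethod
    def from_dir(cls, directory, session_id: str = "", genotype: str = "") -> "SessionBundle":
        d = Path(directory)
        pharm = d / "pharmacology.tsv"
        truth = d / "ground_truth.json"
        return cls(
            spikes=d / "spikes.tsv",
            lfp_vta=d / "lfp_vta.npz",
            lfp_pfc=d / "lfp_pfc.npz",
            behavior=d / "behavior.tsv",
            trials=d / "trials.tsv",
            pharmacology=pharm if pharm.exists() else None,
            ground_truth=truth if truth.exists() else None,
            session_id=session_id or d.name,
            genotype=genotype,
        )


def _header(kind: str, t0: float = 0.0) -> str:
    return (f"# fourhz {kind} v{SCHEMA_VERSION}\n"
            f"# t0_s={FLOAT_FMT % t0}\n"
            "# phase_convention=0_at_peak\n")


def _read_table(path, columns) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


# --------------------------------------------------------------------------- #
# spikes


def write_spikes(path, units, t0: float = 0.0) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header("spikes", t0))
        fh.write("unit_id\tregion\tcell_class\ttimestamp_s\n")
        for u in units:
            cls = u.cell_class or "none"
            for t in u.timestamps:
                fh.write(f"{u.unit_id}\t{u.region}\t{cls}\t{FLOAT_FMT % t}\n")


def read_spikes(path) -> list[SpikeTrain]:
    df = _read_table(path, ["unit_id", "region", "cell_class", "timestamp_s"])
    units = []
    for uid, grp in df.groupby("unit_id", sort=True):
        t = grp["timestamp_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            warnings.warn(f"{path}: spikes of unit {uid} unsorted; sorting on load")
            t = np.sort(t)
        cls = grp["cell_class"].iloc[0]
        units.append(
            SpikeTrain(t, unit_id=str(uid), region=str(grp["region"].iloc[0]),
                       cell_class=None if cls == "none" else str(cls))
        )
    return units


# --------------------------------------------------------------------------- #
# LFP


def write_lfp(path, lfp: LfpSignal) -> None:
    np.savez(
        path, samples=lfp.samples.astype(np.float64), rate=float(lfp.rate),
        region=np.str_(lfp.region), t0=float(lfp.t0), units=np.str_("uV"),
        schema=np.str_(f"fourhz lfp v{SCHEMA_VERSION}"),
    )


def read_lfp(path) -> LfpSignal:
    with np.load(path, allow_pickle=False) as z:
        required = {"samples", "rate", "region", "t0"}
        if not required.issubset(z.files):
            raise ParseError(f"{path}: missing keys {required - set(z.files)}")
        return LfpSignal(z["samples"], rate=float(z["rate"]),
                         region=str(z["region"]), t0=float(z["t0"]))


# --------------------------------------------------------------------------- #
# behavior / trials / pharmacology


def write_behavior(path, track: BehaviorTrack) -> None:
    with Path(path).open("w") as fh:
        fh.write(_header("behavior"))
        fh.write("timestamp_s\tx\ty\n")
        for t, x, y in zip(track.timestamps, track.x, track.y):
            fh.write(f"{FLOAT_FMT % t}\t{FLOAT_FMT % x}\t{FLOAT_FMT % y}\n")


def read_behavior(path, nominal_dt: float = 0.04) -> BehaviorTrack:
    df = _read_table(path, ["timestamp_s", "x", "y"])
    t = df["timestamp_s"].to_numpy(dtype=float)
    gaps = np.diff(t)
    if np.any(gaps > 2 * nominal_dt):
        warnings.warn(
            f"{path}: behavior gap of {gaps.max() * 1e3:.0f} ms "
            f"(nominal {nominal_dt * 1e3:.0f} ms); nearest-sample analyses will warn",
            BehaviorGapWarning,
        )
    return BehaviorTrack(t, df["x"].to_numpy(dtype=float), df["y"].to_numpy(dtype=float))


def write_trials(path, trials: pd.DataFrame) -> None:
    with Path(path).open("w") as fh:
        fh.write(_header("trials"))
        fh.write("trial\tphase\tt_start\tt_end\tgoal_arm\tcorrect\n")
        for row in trials.itertuples(index=False):
            fh.write(
                f"{int(row.trial)}\t{row.phase}\t{FLOAT_FMT % row.t_start}\t"
                f"{FLOAT_FMT % row.t_end}\t{row.goal_arm}\t{int(bool(row.correct))}\n"
            )


def read_trials(path) -> pd.DataFrame:
    df = _read_table(path, ["trial", "phase", "t_start", "t_end", "goal_arm", "correct"])
    df["correct"] = df["correct"].astype(bool)
    return validate_trials(df)


def write_pharmacology(path, summaries) -> None:
    with Path(path).open("w") as fh:
        fh.write(_header("pharmacology"))
        fh.write("unit_id\tbaseline_rate_hz\tpost_rate_hz\n")
        for p in summaries:
            post = "nan" if p.post_rate is None else FLOAT_FMT % p.post_rate
            fh.write(f"{p.unit_id}\t{FLOAT_FMT % p.baseline_rate}\t{post}\n")


def read_pharmacology(path) -> list[PharmacologySummary]:
    df = _read_table(path, ["unit_id", "baseline_rate_hz", "post_rate_hz"])
    out = []
    for row in df.itertuples(index=False):
        post = None if np.isnan(row.post_rate_hz) else float(row.post_rate_hz)
        out.append(PharmacologySummary(str(row.unit_id), float(row.baseline_rate_hz), post))
    return out


# --------------------------------------------------------------------------- #
# whole sessions


def write_session(session: SyntheticSession, directory) -> Path:
    """Write a session in the pipeline's native formats; ground truth goes to
    a JSON sidecar for recovery tests."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_spikes(d / "spikes.tsv", session.units)
    write_lfp(d / "lfp_vta.npz", session.lfp_vta)
    write_lfp(d / "lfp_pfc.npz", session.lfp_pfc)
    write_behavior(d / "behavior.tsv", session.track)
    write_trials(d / "trials.tsv", session.trials)
    write_pharmacology(d / "pharmacology.tsv", session.pharmacology)
    truth = {}
    for k, v in session.ground_truth.items():
        if isinstance(v, np.ndarray):
            truth[k] = v.tolist()
        elif hasattr(v, "__dict__") and not np.isscalar(v):
            continue  # geometry objects stay out of the sidecar
        else:
            truth[k] = v
    truth["unit_truth"] = [gt.to_dict() for gt in session.unit_truth]
    truth["session_id"] = session.session_id
    (d / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return d


def read_session(directory) -> SyntheticSession:
    from .core import GroundTruth

    bundle = SessionBundle.from_dir(directory)
    truth = {}
    if bundle.ground_truth is not None:
        truth = json.loads(Path(bundle.ground_truth).read_text())
    unit_truth = [
        GroundTruth(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in gt.items()})
        for gt in truth.pop("unit_truth", [])
    ]
    session_id = truth.pop("session_id", bundle.session_id)
    pharm = read_pharmacology(bundle.pharmacology) if bundle.pharmacology else []
    return SyntheticSession(
        lfp_vta=read_lfp(bundle.lfp_vta),
        lfp_pfc=read_lfp(bundle.lfp_pfc),
        units=read_spikes(bundle.spikes),
        unit_truth=unit_truth,
        track=read_behavior(bundle.behavior),
        trials=read_trials(bundle.trials),
        pharmacology=pharm,
        ground_truth=truth,
        session_id=session_id,
    )
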