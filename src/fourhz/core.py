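"""Shared containers and errors for the VTA-PFC 4 Hz analysis pipeline.

Conventions used throughout the package:

* time is in seconds from a single per-session origin (``t0``),
* LFP voltages are in microvolts, firing rates in Hz,
* linearized maze positions run from 1 (bottom of the center arm) to 100
  (end of the goal arm); the decision point sits at position 50,
* phases are radians in ``[-pi, pi)`` with 0 at the oscillation peak.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------- #
# errors / signals


class InvalidParameterError(ValueError):
    """A numeric parameter is outside its documented domain."""


class InconsistentSessionError(ValueError):
    """Session components disagree (e.g. trials extend past the recording)."""


class RecordTooShortError(ValueError):
    """Signal shorter than the analysis (filter/wavelet) requires."""


class NyquistError(ValueError):
    """Requested frequency outside (0, rate/2)."""


class IncompatibleTransformError(ValueError):
    """Wavelet transforms on different frequency/time grids."""


class EmptyRunError(ValueError):
    """A run window containing no behavioral samples."""


class NoTurnDetectedError(RuntimeError):
    """No 15-sample stretch of consistent horizontal motion in the run."""


class NoArrivalError(RuntimeError):
    """Linearized run never reaches the reward threshold (position 99)."""


class UndefinedStatsError(ValueError):
    """Circular statistics requested on an empty phase list."""


class InsufficientDataError(RuntimeError):
    """Too few spikes for a correlogram; the unit is skipped, not failed."""


class FitFailedError(RuntimeError):
    """Nonlinear correlogram fit did not converge from any start."""


class DecodingFailedError(RuntimeError):
    """Pooled covariance singular even after shrinkage."""


# --------------------------------------------------------------------------- #
# signals & spikes


@dataclass
class LfpSignal:
    """Uniformly sampled extracellular voltage trace.

    Parameters
    ----------
    samples : array of float
        Voltage in microvolts.
    rate : float
        Sampling rate in samples/s (nominally 2000).
    region : str
        Recording site label, ``"VTA"`` or ``"PFC"``.
    t0 : float
        Session time of the first sample, in seconds.
    """

    samples: np.ndarray
    rate: float
    region: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise InvalidParameterError(f"sampling rate must be > 0, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("LFP samples must be finite")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate


@dataclass
class SpikeTrain:
    """Sorted spike timestamps of one unit."""

    timestamps: np.ndarray
    unit_id: str = ""
    region: str = ""
    cell_class: str | None = None  # "DA" | "GABA" | "unclassified" | None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.ndim != 1:
            raise InvalidParameterError("spike timestamps must be a 1-D array")
        if self.timestamps.size and np.any(np.diff(self.timestamps) < 0):
            raise InvalidParameterError(
                "spike timestamps must be sorted (loaders sort with a warning)"
            )

    @property
    def n(self) -> int:
        return self.timestamps.size

    def in_windows(self, windows) -> np.ndarray:
        """Timestamps falling inside any of the (start, end) windows."""
        t = self.timestamps
        keep = np.zeros(t.size, dtype=bool)
        for a, b in windows:
            keep |= (t >= a) & (t <= b)
        return t[keep]


# --------------------------------------------------------------------------- #
# behavior


@dataclass
class BehaviorTrack:
    """Head-tracking samples, nominally 25 Hz (40 ms spacing)."""

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.timestamps.size == self.x.size == self.y.size):
            raise InvalidParameterError("track arrays must have equal length")
        if self.timestamps.size > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise InvalidParameterError("track timestamps must be strictly increasing")

    @property
    def n(self) -> int:
        return self.timestamps.size


TRIAL_COLUMNS = ("trial", "phase", "t_start", "t_end", "goal_arm", "correct")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the TrialTable contract.

    One row per run; each trial has exactly one ``sample`` and one ``choice``
    run, the sample precedes the choice, and run windows are time-ordered and
    non-overlapping.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise InvalidParameterError(f"trial table missing columns {missing}")
    if not set(trials["phase"]).issubset({"sample", "choice"}):
        raise InvalidParameterError("trial phase must be 'sample' or 'choice'")
    if not set(trials["goal_arm"]).issubset({"L", "R"}):
        raise InvalidParameterError("goal_arm must be 'L' or 'R'")
    t = trials.sort_values("t_start").reset_index(drop=True)
    if np.any(t["t_end"].to_numpy() <= t["t_start"].to_numpy()):
        raise InvalidParameterError("run windows must have t_end > t_start")
    if np.any(t["t_start"].to_numpy()[1:] < t["t_end"].to_numpy()[:-1]):
        raise InvalidParameterError("run windows must be non-overlapping")
    for idx, grp in t.groupby("trial"):
        phases = list(grp.sort_values("t_start")["phase"])
        if phases != ["sample", "choice"]:
            raise InvalidParameterError(
                f"trial {idx} must have one sample run followed by one choice run"
            )
    return t


def run_windows(trials: pd.DataFrame, phase: str | None = None):
    """(t_start, t_end) pairs, optionally restricted to one task phase."""
    sel = trials if phase is None else trials[trials["phase"] == phase]
    return list(zip(sel["t_start"].to_numpy(), sel["t_end"].to_numpy()))


@dataclass
class MazeGeometry:
    """T-maze arm endpoints in tracking coordinates (arms 40 units long)."""

    center_start: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0]))
    junction: np.ndarray = field(default_factory=lambda: np.array([0.0, 40.0]))
    goal_ends: dict = field(
        default_factory=lambda: {
            "L": np.array([-40.0, 40.0]),
            "R": np.array([40.0, 40.0]),
        }
    )

    def __post_init__(self) -> None:
        self.center_start = np.asarray(self.center_start, dtype=float)
        self.junction = np.asarray(self.junction, dtype=float)
        self.goal_ends = {k: np.asarray(v, dtype=float) for k, v in self.goal_ends.items()}

    def translated(self, offset) -> "MazeGeometry":
        off = np.asarray(offset, dtype=float)
        return MazeGeometry(
            self.center_start + off,
            self.junction + off,
            {k: v + off for k, v in self.goal_ends.items()},
        )


@dataclass
class LinearizedRun:
    """Per-sample normalized linear position (1-100) for one run."""

    trial: int
    phase: str
    arm: str
    times: np.ndarray
    linear_pos: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.linear_pos = np.asarray(self.linear_pos, dtype=float)


# --------------------------------------------------------------------------- #
# spectral


@dataclass
class WaveletResult:
    """Complex Morlet coefficients WT(f, t) with a cone-of-influence mask."""

    freqs: np.ndarray
    times: np.ndarray
    coeffs: np.ndarray  # (n_freqs, n_times) complex
    valid: np.ndarray  # (n_freqs, n_times) bool; False inside the edge cone
    n_cycles: float = 3.0

    def power(self) -> np.ndarray:
        """Spectrogram |WT(f, t)| (amplitude units)."""
        return np.abs(self.coeffs)


@dataclass
class BandSeries:
    """Band-averaged power or coherence as a function of time."""

    times: np.ndarray
    values: np.ndarray
    band: tuple
    rate: float
    kind: str = "power"  # "power" | "coherence"


@dataclass
class PositionMap:
    """Per-linear-position (1-100) mean of a band series, split by phase."""

    positions: np.ndarray  # 1..100
    mean: np.ndarray  # NaN where count == 0
    count: np.ndarray
    phase: str

    def center_arm_mean(self) -> float:
        """Mean over positions 1-50 (the center arm)."""
        sel = (self.positions <= 50) & (self.count > 0)
        return float(np.nanmean(self.mean[sel]))


# --------------------------------------------------------------------------- #
# phase locking


@dataclass
class PhaseSeries:
    """Instantaneous band phase/amplitude from the Hilbert transform.

    Phase convention: 0 = oscillation peak, +/-pi = trough.
    """

    times: np.ndarray
    phase: np.ndarray
    amplitude: np.ndarray
    band: tuple
    rate: float
    edge: np.ndarray = None  # bool, True where the estimate is edge-contaminated

    def __post_init__(self) -> None:
        if self.edge is None:
            self.edge = np.zeros(len(self.times), dtype=bool)


@dataclass
class PhaseLockStats:
    n_spikes: int
    mrl: float
    preferred_phase: float
    rayleigh_p: float
    subsampled: bool = False


@dataclass
class SubsampleComparison:
    """Bias-matched sample-vs-choice phase-locking comparison for one unit."""

    stats_sample: PhaseLockStats | None
    stats_choice: PhaseLockStats | None
    excluded: bool
    reason: str = ""
    seed: int | None = None


# --------------------------------------------------------------------------- #
# rhythmicity


@dataclass
class Correlogram:
    """Spike-time lag histogram (auto: 10-500 ms, cross: +/-500 ms; 10 ms bins)."""

    lags_ms: np.ndarray  # bin centers
    counts: np.ndarray
    bin_ms: float
    kind: str  # "auto" | "cross"
    n_ref: int  # number of reference spikes


@dataclass
class CorrelogramFit:
    """Parameters of a*exp(-b*t^2) + c*sin(d*t + e) and the surrogate test."""

    a: float
    b: float
    c: float
    d: float  # rad/ms
    e: float
    sse: float
    freq_hz: float  # d / (2*pi) * 1000
    r_obs: float = np.nan
    surrogate_r: np.ndarray | None = None
    surrogate_q95: float = np.nan
    p_frac: float = np.nan
    is_rhythmic: bool = False
    is_4hz: bool = False
    n_spikes: int = 0
    seed: int | None = None


# --------------------------------------------------------------------------- #
# classification & task coding


@dataclass
class PharmacologySummary:
    """Home-cage baseline rate and post-apomorphine rate for one VTA unit."""

    unit_id: str
    baseline_rate: float
    post_rate: float | None = None

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or (self.post_rate is not None and self.post_rate < 0):
            raise InvalidParameterError("firing rates must be >= 0")


@dataclass
class SelectivityResult:
    unit_id: str
    variable: str  # "task_phase" | "turn" | "reward"
    statistic: float
    p: float
    selective: bool
    direction: str = ""
    excluded: bool = False
    reason: str = ""


@dataclass
class DecodingResult:
    session_id: str
    cell_class: str
    n_neurons: int
    n_obs: int
    accuracy: float  # percent correct
    excluded: bool = False
    reason: str = ""


# --------------------------------------------------------------------------- #
# synthetic sessions


@dataclass
class GroundTruth:
    """Generator parameters recorded alongside a synthetic session."""

    lfp_band_hz: tuple = (3.0, 6.0)
    osc_amp_sample: float = 40.0
    osc_amp_choice: float = 40.0
    coupling: float = 1.0
    kappa: float = 0.0
    mu: float = 0.0
    mod_freq: float = 4.5
    mod_depth: float = 0.0
    base_rate: float = 5.0
    phase_rate_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coupling <= 1.0):
            raise InvalidParameterError("coupling must lie in [0, 1]")
        if self.kappa < 0:
            raise InvalidParameterError("kappa must be >= 0")
        if not (0.0 <= self.mod_depth <= 1.0):
            raise InvalidParameterError("mod_depth must lie in [0, 1]")
        if self.phase_rate_ratio <= 0:
            raise InvalidParameterError("phase_rate_ratio must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticSession:
    """A complete generated session plus its ground truth."""

    lfp_vta: LfpSignal
    lfp_pfc: LfpSignal
    units: list  # list[SpikeTrain]
    unit_truth: list  # list[GroundTruth], parallel to units
    track: BehaviorTrack
    trials: pd.DataFrame
    pharmacology: list  # list[PharmacologySummary]
    ground_truth: dict = field(default_factory=dict)
    session_id: str = "synthetic"
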