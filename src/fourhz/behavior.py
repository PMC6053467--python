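"""Trajectory linearization, turn/reward event detection, running speed,
and the learning criterion.

Linearization projects each 25 Hz tracking sample onto a two-segment ideal
path (center-arm axis, then the chosen goal-arm axis) and maps it affinely so
that position 1 is the bottom of the center arm, 50 the junction, and 100
the end of the goal arm; the center arm occupies positions 1-50, the goal
arm 51-100.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import (
    BehaviorTrack,
    EmptyRunError,
    InvalidParameterError,
    LinearizedRun,
    MazeGeometry,
    NoArrivalError,
    NoTurnDetectedError,
)

REWARD_POS = 99.0  # linear-position threshold for arrival at the reward well
TURN_RUN_LENGTH = 15  # consecutive samples of consistent horizontal motion


class IncompleteRunWarning(UserWarning):
    """Trajectory never reached a goal arm; positions capped at the maximum."""


class ClockMisalignmentWarning(UserWarning):
    """Nearest-sample gap between clocks exceeded the tolerance."""


def _project_param(p, seg_start, seg_vec, seg_len):
    """Clamped projection parameter (0..seg_len) and distance to segment."""
    t = np.clip((p - seg_start) @ seg_vec / seg_len, 0.0, seg_len)
    foot = seg_start[None, :] + np.outer(t, seg_vec / seg_len)
    d = np.linalg.norm(p - foot, axis=1)
    return t, d


def linearize_run(
    track: BehaviorTrack,
    run_window: tuple,
    geometry: MazeGeometry | None = None,
    arm: str | None = None,
    trial: int = -1,
    phase: str = "",
) -> LinearizedRun:
    """Linearize one run to normalized positions in [1, 100].

    Each sample inside ``run_window`` is orthogonally projected onto the
    center-arm and goal-arm axes and attached to the nearer segment; the
    projection parameter is mapped affinely, center arm to [1, 50] and goal
    arm to [51, 100].  If ``arm`` is not given, the goal arm whose end lies
    closest to the final sample is used.  Runs that never reach the goal arm
    trigger an :class:`IncompleteRunWarning` with positions capped at the
    maximum reached.
    """
    geo = geometry or MazeGeometry()
    t0, t1 = run_window
    sel = (track.timestamps >= t0) & (track.timestamps <= t1)
    if sel.sum() < 2:
        raise EmptyRunError(f"run window ({t0}, {t1}) contains < 2 behavioral samples")
    ts = track.timestamps[sel]
    pts = np.column_stack([track.x[sel], track.y[sel]])

    if arm is None:
        dists = {k: np.linalg.norm(pts[-1] - v) for k, v in geo.goal_ends.items()}
        arm = min(dists, key=dists.get)
    if arm not in geo.goal_ends:
        raise InvalidParameterError(f"unknown goal arm {arm!r}")

    c_vec = geo.junction - geo.center_start
    c_len = float(np.linalg.norm(c_vec))
    g_vec = geo.goal_ends[arm] - geo.junction
    g_len = float(np.linalg.norm(g_vec))
    tc, dc = _project_param(pts, geo.center_start, c_vec, c_len)
    tg, dg = _project_param(pts, geo.junction, g_vec, g_len)

    on_center = dc <= dg  # ties resolved toward the center arm
    pos = np.where(
        on_center,
        1.0 + 49.0 * tc / c_len,
        51.0 + 49.0 * tg / g_len,
    )
    if not np.any(~on_center):
        warnings.warn(
            "trajectory never reached a goal arm; positions capped",
            IncompleteRunWarning,
        )
    return LinearizedRun(trial=trial, phase=phase, arm=arm, times=ts, linear_pos=pos)


def linearize_session(track, trials, geometry=None):
    """Linearize every run in a trial table."""
    runs = []
    for _, row in trials.iterrows():
        runs.append(
            linearize_run(
                track,
                (row["t_start"], row["t_end"]),
                geometry,
                arm=row["goal_arm"],
                trial=int(row["trial"]),
                phase=row["phase"],
            )
        )
    return runs


def detect_turn_onset(track: BehaviorTrack, run_window: tuple) -> tuple[float, str]:
    """Timestamp and direction of turn onset within a run.

    The onset is the first sample of the first stretch of
    ``TURN_RUN_LENGTH`` consecutive samples whose forward horizontal
    displacement ``dx[i] = x[i+1] - x[i]`` is nonzero with constant sign;
    zero-displacement samples break a streak.  Direction 'R' for positive
    dx, 'L' for negative.
    """
    t0, t1 = run_window
    sel = (track.timestamps >= t0) & (track.timestamps <= t1)
    if sel.sum() < TURN_RUN_LENGTH + 1:
        raise NoTurnDetectedError("run contains too few samples for the 15-sample rule")
    ts = track.timestamps[sel]
    x = track.x[sel]
    dx = np.diff(x)
    sign = np.sign(dx)
    streak = 0
    cur = 0.0
    for i, s in enumerate(sign):
        if s != 0 and s == cur:
            streak += 1
        elif s != 0:
            cur = s
            streak = 1
        else:
            cur = 0.0
            streak = 0
        if streak >= TURN_RUN_LENGTH:
            start = i - TURN_RUN_LENGTH + 1
            return float(ts[start]), ("R" if cur > 0 else "L")
    raise NoTurnDetectedError("no 15-sample stretch of consistent horizontal motion")


def detect_reward_arrival(linrun: LinearizedRun) -> float:
    """Timestamp of the first sample with linear position >= 99."""
    hit = np.nonzero(linrun.linear_pos >= REWARD_POS)[0]
    if hit.size == 0:
        raise NoArrivalError(
            f"run never reached linear position {REWARD_POS} "
            f"(max {linrun.linear_pos.max():.1f})"
        )
    return float(linrun.times[hit[0]])


def compute_speed(
    track: BehaviorTrack, window: tuple | None = None, smooth_samples: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Running speed (maze units/s): centered finite differences smoothed by
    a moving average (default 5 samples = 200 ms at 25 Hz)."""
    if window is not None:
        sel = (track.timestamps >= window[0]) & (track.timestamps <= window[1])
        ts, x, y = track.timestamps[sel], track.x[sel], track.y[sel]
    else:
        ts, x, y = track.timestamps, track.x, track.y
    if ts.size < 2:
        raise EmptyRunError("speed requires >= 2 samples")
    vx = np.gradient(x, ts)
    vy = np.gradient(y, ts)
    speed = np.hypot(vx, vy)
    if smooth_samples > 1 and ts.size >= smooth_samples:
        kernel = np.ones(smooth_samples) / smooth_samples
        pad = smooth_samples // 2
        padded = np.pad(speed, pad, mode="edge")
        speed = np.convolve(padded, kernel, mode="valid")[: ts.size]
    return ts, speed


NOT_REACHED = -1


def days_to_criterion(daily_correct) -> int:
    """Last day of the first stretch of three consecutive days with >= 7
    correct trials (out of the daily 10).

    ``daily_correct`` is a sequence of ``n_correct`` or ``(n_correct,
    n_trials)`` pairs.  Returns the 1-based day index, or ``NOT_REACHED``
    (-1) if the criterion is never met.
    """
    streak = 0
    for day, item in enumerate(daily_correct, start=1):
        n_correct = item[0] if np.iterable(item) else item
        streak = streak + 1 if n_correct >= 7 else 0
        if streak >= 3:
            return day
    return NOT_REACHED
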