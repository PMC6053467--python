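"""Spike-LFP phase locking in the 3-6 Hz band.

The LFP is bandpass filtered with a linear-phase FIR filter, the
instantaneous phase extracted with the Hilbert transform, each spike assigned
the phase of the nearest LFP sample, and phase locking quantified by the mean
resultant length (MRL) with Rayleigh's test for circular uniformity.  The
sample-vs-choice comparison equalizes spike counts by repeated subsampling of
the larger side, because the MRL estimator has a strong n-dependent positive
bias.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .core import (
    InvalidParameterError,
    LfpSignal,
    PhaseLockStats,
    PhaseSeries,
    RecordTooShortError,
    SpikeTrain,
    SubsampleComparison,
    UndefinedStatsError,
)

log = logging.getLogger(__name__)

DEFAULT_BAND = (3.0, 6.0)
#: spikes this close (s) to the record edge are excluded from phase assignment
EDGE_MARGIN_S = 0.5


def bandpass_filter(
    lfp: LfpSignal, band: tuple = DEFAULT_BAND, order_s: float = 2.0
) -> LfpSignal:
    """Zero-lag FIR bandpass of an LFP trace.

    A windowed-sinc (Hamming) linear-phase filter whose impulse response
    spans ``order_s`` seconds (default 2 s, i.e. >= 6 cycles at 3 Hz) is
    applied via ``fftconvolve(mode="same")``; centering the kernel
    compensates the group delay exactly, so filtered features align with the
    raw trace.
    """
    lo, hi = band
    if not (0 < lo < hi < lfp.rate / 2):
        raise InvalidParameterError(f"band {band} invalid for rate {lfp.rate}")
    numtaps = int(round(order_s * lfp.rate)) | 1  # odd -> integer group delay
    if lfp.n <= numtaps:
        raise RecordTooShortError(
            f"record of {lfp.n} samples shorter than the {numtaps}-tap filter"
        )
    taps = signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=lfp.rate, window="hamming")
    out = signal.fftconvolve(lfp.samples, taps, mode="same")
    return LfpSignal(out, rate=lfp.rate, region=lfp.region, t0=lfp.t0)


def instantaneous_phase(filtered: LfpSignal, band: tuple = DEFAULT_BAND) -> PhaseSeries:
    """Hilbert phase and amplitude of a band-limited trace.

    Phase 0 marks the oscillation peak and +/-pi the trough (the analytic
    signal of ``cos`` has argument 0 at the peak).  Samples within
    ``EDGE_MARGIN_S`` of the record ends are flagged as edge-contaminated.
    """
    analytic = signal.hilbert(filtered.samples)
    phase = np.angle(analytic)
    amplitude = np.abs(analytic)
    times = filtered.times
    edge = np.zeros(filtered.n, dtype=bool)
    margin = int(round(EDGE_MARGIN_S * filtered.rate))
    if margin > 0:
        edge[:margin] = True
        if margin < filtered.n:
            edge[-margin:] = True
        else:
            edge[:] = True
    return PhaseSeries(
        times=times, phase=phase, amplitude=amplitude, band=tuple(band),
        rate=filtered.rate, edge=edge,
    )


def assign_spike_phases(spikes: SpikeTrain, phases: PhaseSeries) -> np.ndarray:
    """Phase of the nearest-in-time LFP sample for each spike.

    Spikes outside the phase-series span or landing on edge-flagged samples
    are dropped (count reported at warning level).
    """
    t = spikes.timestamps
    if t.size == 0:
        return np.empty(0)
    times = phases.times
    idx = np.searchsorted(times, t)
    idx = np.clip(idx, 1, times.size - 1)
    left = times[idx - 1]
    right = times[idx]
    nearest = np.where(t - left <= right - t, idx - 1, idx)
    in_span = (t >= times[0]) & (t <= times[-1])
    keep = in_span & ~phases.edge[nearest]
    dropped = int(t.size - keep.sum())
    if dropped:
        log.warning("%d/%d spikes dropped (out of span or edge-flagged)", dropped, t.size)
    return phases.phase[nearest[keep]]


def resultant(phases: np.ndarray) -> tuple[float, float]:
    """(MRL, mean direction) of a list of phase angles."""
    z = np.exp(1j * np.asarray(phases, dtype=float)).mean()
    return float(np.abs(z)), float(np.angle(z))


def rayleigh_p(n: int, mrl: float) -> float:
    """Rayleigh test p-value with the standard finite-n correction.

    p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n)), with R = n * MRL.
    """
    R = n * mrl
    z = R * R / n
    p = np.exp(np.sqrt(1.0 + 4 * n + 4.0 * (n * n - R * R)) - (1.0 + 2 * n))
    # the correction can marginally exceed 1 for tiny n
    return float(min(1.0, p)) if np.isfinite(p) else float(np.exp(-z))


def phase_lock_stats(phases: np.ndarray) -> PhaseLockStats:
    """MRL, preferred phase, and Rayleigh p for a list of spike phases."""
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n == 0:
        raise UndefinedStatsError("phase-locking statistics undefined for 0 spikes")
    mrl, mu = resultant(phases)
    return PhaseLockStats(n_spikes=n, mrl=mrl, preferred_phase=mu, rayleigh_p=rayleigh_p(n, mrl))


def matched_subsample_comparison(
    phases_sample: np.ndarray,
    phases_choice: np.ndarray,
    n_subsamples: int = 1000,
    min_spikes: int = 50,
    seed: int | None = None,
) -> SubsampleComparison:
    """Sample-vs-choice MRL with the spike-count bias equalized.

    From the task phase with more spikes, subsets equal in size to the
    smaller side are drawn without replacement ``n_subsamples`` times and the
    MRL averaged across draws; the smaller side keeps its plain MRL.  Units
    with fewer than ``min_spikes`` spikes in either phase are excluded (a
    signal, not an exception).
    """
    ps = np.asarray(phases_sample, dtype=float)
    pc = np.asarray(phases_choice, dtype=float)
    if ps.size < min_spikes or pc.size < min_spikes:
        return SubsampleComparison(
            None, None, excluded=True,
            reason=f"fewer than {min_spikes} spikes in one task phase "
                   f"(sample={ps.size}, choice={pc.size})",
            seed=seed,
        )

    def _plain(p):
        st = phase_lock_stats(p)
        return st

    def _subsampled(big, k, rng):
        mrls = np.empty(n_subsamples)
        mus = np.empty(n_subsamples)
        for i in range(n_subsamples):
            sub = rng.choice(big, size=k, replace=False)
            mrls[i], mus[i] = resultant(sub)
        mean_mrl = float(mrls.mean())
        mu = float(np.angle(np.exp(1j * mus).mean()))
        return PhaseLockStats(
            n_spikes=k, mrl=mean_mrl, preferred_phase=mu,
            rayleigh_p=rayleigh_p(k, mean_mrl), subsampled=True,
        )

    rng = np.random.default_rng(seed)
    if ps.size == pc.size:
        return SubsampleComparison(_plain(ps), _plain(pc), excluded=False, seed=seed)
    if ps.size > pc.size:
        return SubsampleComparison(
            _subsampled(ps, pc.size, rng), _plain(pc), excluded=False, seed=seed
        )
    return SubsampleComparison(
        _plain(ps), _subsampled(pc, ps.size, rng), excluded=False, seed=seed
    )


def spike_phases_for_lfp(
    spikes: SpikeTrain, lfp: LfpSignal, band: tuple = DEFAULT_BAND,
    windows=None,
) -> np.ndarray:
    """Convenience: filter, extract phase, and assign spike phases.

    ``windows`` optionally restricts spikes to task windows first.
    """
    train = spikes
    if windows is not None:
        train = SpikeTrain(spikes.in_windows(windows), spikes.unit_id, spikes.region,
                           spikes.cell_class)
    filt = bandpass_filter(lfp, band)
    ph = instantaneous_phase(filt, band)
    return assign_spike_phases(train, ph)
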