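"""Morlet-wavelet power, cycle-spaced coherence, band averaging,
position-resolved maps, and lagged band-power cross-correlation.

The transform convolves the LFP with 3-cycle complex Morlet wavelets
(Gaussian envelope with sigma_t = n_cycles / (2*pi*f), truncated at
+/-3 sigma) on a 1-25 Hz grid.  Wavelets are amplitude-normalized: a
unit-amplitude sinusoid at a grid frequency yields |WT| = 1 in the record
interior, so band power is directly an oscillation amplitude.  Coherence at
(f, t) sums the cross-spectrum over six timepoints spaced one cycle (1/f)
apart around t and normalizes by the autospectra summed over the same
points, measuring how consistent the inter-regional phase relationship is
over ~6 cycles.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from scipy.fft import fft, ifft, next_fast_len

from .core import (
    BandSeries,
    IncompatibleTransformError,
    InvalidParameterError,
    LfpSignal,
    NyquistError,
    PositionMap,
    RecordTooShortError,
    WaveletResult,
)

DEFAULT_FREQS = np.arange(1.0, 25.0 + 1e-9, 0.5)
DEFAULT_BAND = (3.0, 6.0)
N_CYCLES = 3.0
#: symmetric cycle offsets of the 6-point coherence estimator
COHERENCE_OFFSETS = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)


def _morlet_kernel(freq: float, rate: float) -> np.ndarray:
    """Truncated, amplitude-normalized complex Morlet wavelet."""
    sigma_t = N_CYCLES / (2 * np.pi * freq)
    half = int(np.ceil(3 * sigma_t * rate))
    t = np.arange(-half, half + 1) / rate
    gauss = np.exp(-(t**2) / (2 * sigma_t**2))
    kernel = gauss * np.exp(2j * np.pi * freq * t)
    # response of the convolution to cos(2*pi*f*t) has magnitude sum(gauss)/2
    return kernel * (2.0 / gauss.sum())


def morlet_transform(
    lfp: LfpSignal, freqs: np.ndarray = DEFAULT_FREQS
) -> WaveletResult:
    """Complex wavelet coefficients WT(f, t) for every grid frequency.

    Implemented as one FFT of the signal multiplied by the FFT of each
    kernel.  Samples within 1.5 cycles (the wavelet half-length) of either
    edge are flagged invalid (cone of influence).
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= lfp.rate / 2):
        raise NyquistError(f"frequencies must lie in (0, {lfp.rate / 2}) Hz")
    if np.any(np.diff(freqs) <= 0):
        raise InvalidParameterError("frequency grid must be strictly increasing")
    n = lfp.n
    if n < N_CYCLES * lfp.rate / freqs.min():
        raise RecordTooShortError(
            f"record of {n} samples shorter than {N_CYCLES} cycles of {freqs.min()} Hz"
        )
    coeffs = np.empty((freqs.size, n), dtype=complex)
    valid = np.ones((freqs.size, n), dtype=bool)
    # shared zero-padded FFT of the signal
    max_half = int(np.ceil(3 * (N_CYCLES / (2 * np.pi * freqs.min())) * lfp.rate))
    nfft = next_fast_len(n + 2 * max_half + 1)
    X = fft(lfp.samples, nfft)
    for i, f in enumerate(freqs):
        kern = _morlet_kernel(f, lfp.rate)
        half = kern.size // 2
        K = fft(kern, nfft)
        conv = ifft(X * K)[half : half + n]  # centered ("same") convolution
        coeffs[i] = conv
        margin = int(np.ceil(1.5 / f * lfp.rate))
        valid[i, :margin] = False
        valid[i, n - margin :] = False
    return WaveletResult(freqs=freqs, times=lfp.times, coeffs=coeffs, valid=valid,
                         n_cycles=N_CYCLES)


def wavelet_coherence(wt_a: WaveletResult, wt_b: WaveletResult) -> tuple[np.ndarray, np.ndarray]:
    """6-point cycle-spaced wavelet coherence over the (f, t) grid.

    Returns ``(coherence, defined)``: coherence in [0, 1] where defined,
    NaN elsewhere; a point is undefined when any of the six cycle-spaced
    timepoints falls outside the record or inside the edge cone.
    """
    if wt_a.coeffs.shape != wt_b.coeffs.shape or not np.allclose(wt_a.freqs, wt_b.freqs):
        raise IncompatibleTransformError("wavelet transforms on different grids")
    nf, nt = wt_a.coeffs.shape
    rate = 1.0 / float(np.mean(np.diff(wt_a.times)))
    coh = np.full((nf, nt), np.nan)
    defined = np.zeros((nf, nt), dtype=bool)
    for i, f in enumerate(wt_a.freqs):
        offs = np.round(np.asarray(COHERENCE_OFFSETS) / f * rate).astype(int)
        a = wt_a.coeffs[i]
        b = wt_b.coeffs[i]
        cross = np.zeros(nt, dtype=complex)
        pa = np.zeros(nt)
        pb = np.zeros(nt)
        ok = np.ones(nt, dtype=bool)
        base_valid = wt_a.valid[i] & wt_b.valid[i]
        for o in offs:
            idx = np.arange(nt) + o
            inside = (idx >= 0) & (idx < nt)
            idx_c = np.clip(idx, 0, nt - 1)
            ok &= inside & base_valid[idx_c]
            cross += np.where(inside, a[idx_c] * np.conj(b[idx_c]), 0.0)
            pa += np.where(inside, np.abs(a[idx_c]) ** 2, 0.0)
            pb += np.where(inside, np.abs(b[idx_c]) ** 2, 0.0)
        denom = np.sqrt(pa * pb)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.abs(cross) / denom
        ok &= denom > 0
        coh[i, ok] = np.clip(c[ok], 0.0, 1.0)
        defined[i] = ok
    return coh, defined


def band_average(
    field: np.ndarray,
    freqs: np.ndarray,
    times: np.ndarray,
    band: tuple = DEFAULT_BAND,
    rate: float | None = None,
    kind: str = "power",
) -> BandSeries:
    """Unweighted mean over grid frequencies in ``band`` (inclusive)."""
    freqs = np.asarray(freqs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise InvalidParameterError(f"no grid frequencies inside band {band}")
    if rate is None:
        rate = 1.0 / float(np.mean(np.diff(times)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(field[sel], axis=0)
    return BandSeries(times=times, values=values, band=tuple(band), rate=rate, kind=kind)


def band_power(lfp: LfpSignal, band: tuple = DEFAULT_BAND,
               freqs: np.ndarray | None = None) -> BandSeries:
    """Convenience: 3-6 Hz amplitude series |WT| averaged over the band."""
    if freqs is None:
        freqs = DEFAULT_FREQS
    wt = morlet_transform(lfp, freqs)
    power = wt.power()
    power[~wt.valid] = np.nan
    return band_average(power, wt.freqs, wt.times, band, rate=lfp.rate, kind="power")


def position_resolved(
    series: BandSeries,
    linruns,
    phase_filter: str,
    gap_tolerance_s: float = 0.05,
) -> PositionMap:
    """Per-linear-position (1-100) mean of a band series for one task phase.

    Each behavioral sample takes the value of the nearest-in-time series
    sample; values are averaged within integer position bins over all runs
    of the given phase.  A nearest-sample gap above ``gap_tolerance_s``
    raises a :class:`ClockMisalignmentWarning`.
    """
    from .behavior import ClockMisalignmentWarning

    sums = np.zeros(100)
    counts = np.zeros(100)
    st = series.times
    for run in linruns:
        if run.phase != phase_filter:
            continue
        idx = np.searchsorted(st, run.times)
        idx = np.clip(idx, 1, st.size - 1)
        nearer_left = (run.times - st[idx - 1]) <= (st[idx] - run.times)
        idx = np.where(nearer_left, idx - 1, idx)
        gap = np.abs(st[idx] - run.times)
        if np.any(gap > gap_tolerance_s):
            warnings.warn(
                f"nearest LFP sample {gap.max() * 1e3:.0f} ms away from a "
                "behavioral sample; check the shared time origin",
                ClockMisalignmentWarning,
            )
        vals = series.values[idx]
        bins = np.clip(np.round(run.linear_pos).astype(int), 1, 100) - 1
        good = np.isfinite(vals)
        np.add.at(sums, bins[good], vals[good])
        np.add.at(counts, bins[good], 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PositionMap(positions=np.arange(1, 101), mean=mean, count=counts,
                       phase=phase_filter)


def power_crosscorrelation(
    band_a: BandSeries,
    band_b: BandSeries,
    max_lag_s: float = 0.25,
    step_s: float = 0.005,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of two band-power series at lags of
    +/-``max_lag_s`` in ``step_s`` steps.

    Sign convention: at positive lag, ``band_a`` leads ``band_b`` — the
    correlation at lag L compares ``a(t)`` with ``b(t + L)``.  Returns
    ``(lags_s, r)``.
    """
    if band_a.rate != band_b.rate or band_a.times.size != band_b.times.size:
        raise IncompatibleTransformError("band series on different grids")
    a = np.asarray(band_a.values, dtype=float)
    b = np.asarray(band_b.values, dtype=float)
    good = np.isfinite(a) & np.isfinite(b)
    first, last = np.argmax(good), len(good) - np.argmax(good[::-1])
    a, b = a[first:last], b[first:last]
    if a.size / band_a.rate < 10.0:
        raise RecordTooShortError("need >= 10 s of overlapping band series")
    if np.nanstd(a) == 0 or np.nanstd(b) == 0:
        raise InvalidParameterError("undefined correlation for a constant series")
    step = max(1, int(round(step_s * band_a.rate)))
    max_shift = int(round(max_lag_s * band_a.rate))
    shifts = np.arange(-max_shift, max_shift + 1, step)
    r = np.empty(shifts.size)
    for i, s in enumerate(shifts):
        if s >= 0:
            x, y = a[: a.size - s], b[s:]
        else:
            x, y = a[-s:], b[: b.size + s]
        m = np.isfinite(x) & np.isfinite(y)
        r[i] = stats.pearsonr(x[m], y[m])[0]
    return shifts / band_a.rate, r
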