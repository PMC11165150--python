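"""Per-trial high-gamma (70-80 Hz) power from EEG epoch matrices.

Pipeline: cut the -300..+800 ms analysis window out of each +-1500 ms
epoch, estimate the power spectral density with Welch's method (periodic
367 ms Hamming windows, 25% overlap), report the spectrum on a 2,560-point
linear frequency grid over 0-256 Hz, sum power over the 70-80 Hz band and
log-transform.  Per-trial band powers aggregate into 2-minute time bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .model_core import ParameterError, _check

__all__ = [
    "EpochMatrix",
    "PSDResult",
    "extract_analysis_window",
    "welch_psd",
    "band_power_log",
    "bin_aggregate",
    "epochs_to_gamma",
]

GRID_POINTS = 2560
GRID_MAX_HZ = 256.0


@dataclass
class EpochMatrix:
    """Trials x samples of voltage (uV) around stimulus onset.

    ``span_ms`` is (start, end) relative to onset; the sample count must
    match span x rate within rounding, and the rate must satisfy Nyquist
    for the 70-80 Hz band with margin (> 200 Hz).
    """

    data: np.ndarray
    rate: float = 512.0
    span_ms: tuple[float, float] = (-1500.0, 1500.0)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        _check(self.rate > 200.0, "sampling rate must exceed 200 Hz for the 70-80 Hz band")
        lo, hi = self.span_ms
        _check(hi > lo, "epoch span must be increasing")
        expected = int(np.floor((hi - lo) * self.rate / 1000.0))
        if abs(self.data.shape[1] - expected) > 1:
            raise ParameterError(
                f"sample count {self.data.shape[1]} does not match span "
                f"{self.span_ms} ms at {self.rate} Hz (expected ~{expected})"
            )

    @property
    def n_trials(self) -> int:
        return int(self.data.shape[0])


@dataclass
class PSDResult:
    """One-sided PSD on a linear frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    window_ms: float
    overlap: float


def extract_analysis_window(
    epochs: EpochMatrix, start_ms: float = -300.0, end_ms: float = 800.0
) -> EpochMatrix:
    """Cut [start_ms, end_ms) out of the epoch span (half-open, floor indices)."""
    if start_ms >= end_ms:
        raise ParameterError("window start must precede its end")
    lo, hi = epochs.span_ms
    if start_ms < lo or end_ms > hi:
        raise ParameterError(f"requested window {start_ms}..{end_ms} ms outside span {epochs.span_ms}")
    i0 = int(np.floor((start_ms - lo) * epochs.rate / 1000.0))
    i1 = int(np.floor((end_ms - lo) * epochs.rate / 1000.0))
    return EpochMatrix(epochs.data[:, i0:i1], rate=epochs.rate, span_ms=(start_ms, end_ms))


def welch_psd(
    trial_signal: np.ndarray,
    rate: float = 512.0,
    window_ms: float = 367.0,
    overlap: float = 0.25,
) -> PSDResult:
    """Welch PSD of one trial's signal with periodic Hamming windows.

    Segments of ``window_ms`` overlap by ``overlap`` of their length; each
    segment is zero-padded so the raw spectrum is at least as dense as the
    reporting grid, then interpolated onto ``GRID_POINTS`` linearly spaced
    frequencies over 0 to min(256, Nyquist) Hz.
    """
    x = np.asarray(trial_signal, dtype=float)
    nperseg = int(np.floor(window_ms * rate / 1000.0))
    if x.size < nperseg:
        raise ParameterError(f"signal length {x.size} is shorter than one {window_ms} ms window")
    noverlap = int(np.floor(overlap * nperseg))
    f_max = min(GRID_MAX_HZ, rate / 2.0)
    nfft = nperseg
    while (rate / nfft) > f_max / (GRID_POINTS - 1):
        nfft *= 2
    freqs_raw, p_raw = sps.welch(
        x,
        fs=rate,
        window=sps.get_window("hamming", nperseg, fftbins=True),
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=nfft,
        detrend=False,
        scaling="density",
    )
    grid = np.linspace(0.0, f_max, GRID_POINTS)
    power = np.interp(grid, freqs_raw, p_raw)
    return PSDResult(freqs=grid, power=power, window_ms=window_ms, overlap=overlap)


def band_power_log(psd: PSDResult, lo: float = 70.0, hi: float = 80.0) -> tuple[float, float]:
    """Sum PSD over grid points in [lo, hi] (inclusive) and natural-log it.

    Returns (band_power, log_band_power); a non-positive band sum (all-zero
    input) yields NaN for the log with a warning.
    """
    if lo >= hi:
        raise ParameterError("band edges must satisfy lo < hi")
    if lo < psd.freqs[0] or hi > psd.freqs[-1]:
        raise ParameterError(f"band [{lo}, {hi}] Hz outside the PSD grid")
    mask = (psd.freqs >= lo) & (psd.freqs <= hi)
    band = float(psd.power[mask].sum())
    if band <= 0.0:
        warnings.warn("non-positive band power; log is undefined", stacklevel=2)
        return band, float("nan")
    return band, float(np.log(band))


def bin_aggregate(powers: np.ndarray, labels: np.ndarray, mode: str = "sum") -> dict[int, float]:
    """Aggregate per-trial powers into labelled bins by sum or mean."""
    _check(mode in ("sum", "mean"), f"mode must be 'sum' or 'mean', got {mode!r}")
    p = np.asarray(powers, dtype=float)
    lab = np.asarray(labels, dtype=int)
    _check(p.size == lab.size, "powers and labels must be aligned")
    out: dict[int, float] = {}
    for b in sorted(set(lab.tolist())):
        vals = p[lab == b]
        if vals.size == 0:
            raise ParameterError(f"bin {b} is empty")
        out[b] = float(vals.sum() if mode == "sum" else vals.mean())
    return out


def epochs_to_gamma(
    epochs: EpochMatrix,
    start_ms: float = -300.0,
    end_ms: float = 800.0,
    band: tuple[float, float] = (70.0, 80.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Full pipeline: per-trial (band_power, log_band_power) arrays."""
    win = extract_analysis_window(epochs, start_ms, end_ms)
    lin = np.empty(win.n_trials)
    logp = np.empty(win.n_trials)
    for i in range(win.n_trials):
        psd = welch_psd(win.data[i], rate=win.rate)
        lin[i], logp[i] = band_power_log(psd, *band)
    return lin, logp
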