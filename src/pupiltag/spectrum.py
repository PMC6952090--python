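"""Periodogram power-spectral-density estimation on a fine frequency grid.

The PSD of a conditioned pupil trace x(n) of length L sampled at Fs is the
classical periodogram

    Pxx(f) = |sum_n x(n) exp(-j 2 pi f n / Fs)|^2 / (L * Fs),

evaluated by a zero-padded DFT.  The trace itself is only a few seconds long
(natural resolution ~0.1 Hz), so the signal is zero-padded to
N = ceil(Fs / grid_step) points, which interpolates the spectrum onto a grid
of spacing Fs / N <= grid_step (0.01 Hz by default at 333 Hz, N = 33300).
A rectangular window is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import PupilTrace

__all__ = ["Spectrum", "periodogram", "psd_at", "peak_frequency", "write_spectrum"]


@dataclass(frozen=True)
class Spectrum:
    """Uniform frequency grid with periodogram PSD values.

    ``source_length`` is the number of time-domain samples L that entered the
    DFT (before zero-padding); it fixes the PSD normalization 1/(L*Fs).
    """

    frequencies: np.ndarray
    psd: np.ndarray
    source_length: int
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.frequencies.shape != self.psd.shape:
            raise ValueError("frequencies and psd must have equal length")
        if np.any(self.psd < 0):
            raise ValueError("psd values must be non-negative")

    @property
    def grid_step(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


def periodogram(
    trace: PupilTrace, grid_step: float = 0.01, one_sided: bool = True
) -> Spectrum:
    """Zero-padded periodogram of a pupil trace.

    Parameters
    ----------
    trace : PupilTrace
        Conditioned trace of length >= 2.
    grid_step : float
        Upper bound on the frequency-grid spacing in Hz.  The DFT length is
        N = ceil(Fs / grid_step) (never shorter than the trace), giving an
        actual spacing Fs / N.
    one_sided : bool
        If True (default) return the grid [0, Fs/2]; otherwise the full
        two-sided grid [0, Fs), useful for energy bookkeeping.
    """
    if not grid_step > 0:
        raise ValueError("grid_step must be positive")
    x = trace.samples
    L = x.size
    if L < 2:
        raise ValueError("trace must contain at least two samples")
    fs = trace.sampling_rate
    n_pad = max(int(np.ceil(fs / grid_step)), L)
    if one_sided:
        X = np.fft.rfft(x, n=n_pad)
        freqs = np.fft.rfftfreq(n_pad, d=1.0 / fs)
    else:
        X = np.fft.fft(x, n=n_pad)
        freqs = np.arange(n_pad) * (fs / n_pad)
    psd = (X.real**2 + X.imag**2) / (L * fs)
    return Spectrum(freqs, psd, source_length=L, sampling_rate=fs)


def _bin_index(spec: Spectrum, f: float) -> int:
    # nearest grid bin; exact midpoints resolve to the lower bin
    step = spec.grid_step
    idx = int(np.ceil(f / step - 0.5))
    return idx


def psd_at(spec: Spectrum, f: float, neighborhood: int = 0) -> float:
    """PSD at the grid bin nearest to ``f`` (ties toward the lower bin).

    With ``neighborhood`` > 0 the maximum PSD over that many bins on either
    side of the nearest bin is returned instead, guarding against sub-bin
    misalignment of a spectral peak.
    """
    if f < spec.frequencies[0] or f > spec.frequencies[-1]:
        raise ValueError(
            f"frequency {f} Hz outside grid [{spec.frequencies[0]}, {spec.frequencies[-1]}]"
        )
    idx = _bin_index(spec, f)
    if neighborhood <= 0:
        return float(spec.psd[idx])
    lo = max(0, idx - neighborhood)
    hi = min(spec.psd.size, idx + neighborhood + 1)
    return float(spec.psd[lo:hi].max())


def peak_frequency(spec: Spectrum, band: tuple[float, float]) -> float:
    """Grid frequency of maximal PSD within [band_low, band_high].

    Ties break toward the lower frequency.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("band_low must be below band_high")
    mask = (spec.frequencies >= lo) & (spec.frequencies <= hi)
    if not mask.any():
        raise ValueError(f"band ({lo}, {hi}) Hz contains no grid points")
    sub = spec.psd[mask]
    return float(spec.frequencies[mask][int(np.argmax(sub))])


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    """Export as two-column delimited text (frequency_hz, psd)."""
    arr = np.column_stack([spec.frequencies, spec.psd])
    np.savetxt(path, arr, fmt="%.6f\t%.10e", header="frequency_hz\tpsd", comments="")
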