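"""Pupil-trace container and the fixed preprocessing pipeline.

Raw pupil-diameter recordings (nominally 333 Hz) are conditioned in a fixed
order before spectral analysis:

1. ``trim_onset`` — drop the first second, which is dominated by the
   stimulus-onset constriction rather than steady-state entrainment;
2. ``repair_invalid`` — optionally interpolate over samples the tracker
   flagged invalid (off by default);
3. ``smooth`` — 120 ms moving average (40 samples at 333 Hz);
4. ``normalize`` — z-score to zero mean and unit standard deviation so that
   power spectra are comparable across trials and recording units.

The same pipeline is exposed as the scikit-learn transformer
:class:`PupilPreprocessor` operating on a (n_trials, n_samples) array.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "PupilTrace",
    "read_trace",
    "write_trace",
    "trim_onset",
    "window_length",
    "smooth",
    "demean",
    "normalize",
    "repair_invalid",
    "preprocess",
    "PupilPreprocessor",
]

DEFAULT_SAMPLING_RATE = 333.0


@dataclass(frozen=True)
class PupilTrace:
    """Uniformly sampled pupil-diameter series.

    Parameters
    ----------
    samples : ndarray
        Diameter values in arbitrary units (recorders typically report
        pixels).
    sampling_rate : float
        Samples per second (default 333).
    start_time : float
        Time of the first sample in seconds.
    validity : ndarray of bool, optional
        Per-sample validity mask from the eye tracker; ``None`` means all
        samples are trusted.
    """

    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    start_time: float = 0.0
    validity: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.validity is not None:
            mask = np.asarray(self.validity, dtype=bool)
            if mask.shape != self.samples.shape:
                raise ValueError("validity mask must match samples in length")
            object.__setattr__(self, "validity", mask)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate


def read_trace(path: str | Path, sampling_rate: float | None = None) -> PupilTrace:
    """Read a trace from delimited text with columns time_s, diameter[, valid].

    Lines starting with '#' are comments.  The sampling rate is inferred from
    the median time step unless given explicitly.
    """
    df = pd.read_csv(path, sep=r"\s+|,|;", comment="#", engine="python")
    if "time_s" not in df.columns or "diameter" not in df.columns:
        raise ValueError("trace file needs columns time_s and diameter")
    t = df["time_s"].to_numpy(float)
    if sampling_rate is None:
        if len(t) < 2:
            raise ValueError("cannot infer sampling rate from a single sample")
        sampling_rate = 1.0 / float(np.median(np.diff(t)))
    validity = None
    if "valid" in df.columns:
        validity = df["valid"].to_numpy(int).astype(bool)
    return PupilTrace(
        df["diameter"].to_numpy(float),
        sampling_rate=sampling_rate,
        start_time=float(t[0]),
        validity=validity,
    )


def write_trace(trace: PupilTrace, path: str | Path) -> None:
    """Write a trace as delimited text readable by :func:`read_trace`."""
    cols = {"time_s": trace.times, "diameter": trace.samples}
    if trace.validity is not None:
        cols["valid"] = trace.validity.astype(int)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6f")


def trim_onset(trace: PupilTrace, exclude: float = 1.0) -> PupilTrace:
    """Drop the first ``exclude`` seconds of a trace.

    The retained suffix has ``round(n - exclude * Fs)`` samples, so an 8 s
    trace trimmed by 1 s yields exactly 7 s of data.
    """
    if exclude < 0:
        raise ValueError("exclude must be non-negative")
    n = len(trace)
    n_keep = int(round(n - exclude * trace.sampling_rate))
    if n_keep <= 0:
        raise ValueError(
            f"exclusion of {exclude} s leaves no data in a {trace.duration:.3f} s trace"
        )
    start = n - n_keep
    return replace(
        trace,
        samples=trace.samples[start:],
        start_time=trace.start_time + start / trace.sampling_rate,
        validity=None if trace.validity is None else trace.validity[start:],
    )


def window_length(duration_ms: float, sampling_rate: float) -> int:
    """Moving-average window length in samples for a duration in ms.

    120 ms at 333 Hz gives 40 samples.  Never less than one sample.
    """
    if not duration_ms > 0:
        raise ValueError("duration_ms must be positive")
    return max(1, int(np.floor(duration_ms / 1000.0 * sampling_rate + 0.5)))


def smooth(trace: PupilTrace, duration_ms: float = 120.0) -> PupilTrace:
    """Moving-average filter of the given duration.

    Output length equals input length; near the edges the mean is taken over
    the samples actually available (shrinking window).
    """
    w = window_length(duration_ms, trace.sampling_rate)
    if w > len(trace):
        raise ValueError(f"window of {w} samples exceeds trace length {len(trace)}")
    kernel = np.ones(w)
    num = np.convolve(trace.samples, kernel, mode="same")
    den = np.convolve(np.ones(len(trace)), kernel, mode="same")
    return replace(trace, samples=num / den, validity=trace.validity)


def demean(trace: PupilTrace) -> PupilTrace:
    """Subtract the mean without rescaling the variance.

    Useful when absolute PSD magnitudes across trials must stay comparable
    (e.g. when pooling PSD peaks across frequencies for calibration) while
    still suppressing the DC leakage of the baseline diameter.
    """
    return replace(trace, samples=trace.samples - trace.samples.mean(),
                   validity=trace.validity)


def normalize(trace: PupilTrace) -> PupilTrace:
    """Z-score a trace to zero mean and unit standard deviation."""
    if len(trace) < 2:
        raise ValueError("normalization needs at least two samples")
    x = trace.samples
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot normalize a zero-variance trace")
    return replace(trace, samples=(x - x.mean()) / sd, validity=trace.validity)


def repair_invalid(trace: PupilTrace) -> PupilTrace:
    """Replace invalid samples by linear interpolation between valid ones.

    Leading or trailing invalid runs are filled with the nearest valid value.
    Requires a validity mask with at least one valid sample.
    """
    if trace.validity is None:
        raise ValueError("repair_invalid requires a validity mask")
    mask = trace.validity
    if not mask.any():
        raise ValueError("trace has no valid samples to interpolate from")
    if mask.all():
        return trace
    idx = np.arange(len(trace))
    repaired = np.interp(idx, idx[mask], trace.samples[mask])
    return replace(trace, samples=repaired, validity=np.ones(len(trace), dtype=bool))


def preprocess(
    trace: PupilTrace,
    trim_s: float = 1.0,
    smooth_ms: float = 120.0,
    do_normalize: bool = True,
    repair: bool = False,
) -> PupilTrace:
    """Full conditioning pipeline: trim -> (repair) -> smooth -> normalize."""
    out = trim_onset(trace, trim_s) if trim_s > 0 else trace
    if repair and out.validity is not None:
        out = repair_invalid(out)
    if smooth_ms > 0:
        out = smooth(out, smooth_ms)
    if do_normalize:
        out = normalize(out)
    return out


class PupilPreprocessor(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer applying the trace-conditioning pipeline.

    Operates on a 2-D array of shape (n_trials, n_samples) of equally long
    raw traces sharing one sampling rate; ``transform`` returns the
    preprocessed trials (shorter by the trimmed onset).

    Parameters
    ----------
    sampling_rate : float
        Sampling rate of every row, Hz.
    trim_s : float
        Seconds removed from the start of each trial.
    smooth_ms : float
        Moving-average duration in ms (0 disables smoothing).
    normalize : bool
        Whether to z-score each trial after smoothing.
    """

    def __init__(
        self,
        sampling_rate: float = DEFAULT_SAMPLING_RATE,
        trim_s: float = 1.0,
        smooth_ms: float = 120.0,
        normalize: bool = True,
    ):
        self.sampling_rate = sampling_rate
        self.trim_s = trim_s
        self.smooth_ms = smooth_ms
        self.normalize = normalize

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_trials, n_samples)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_trials, n_samples)")
        rows = [
            preprocess(
                PupilTrace(row, sampling_rate=self.sampling_rate),
                trim_s=self.trim_s,
                smooth_ms=self.smooth_ms,
                do_normalize=self.normalize,
            ).samples
            for row in X
        ]
        return np.vstack(rows)
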