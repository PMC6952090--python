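"""Gaze-target decoding from the pupil-diameter spectrum.

Three decision rules, one per interface size:

- :func:`estimate_single` — read the PSD at each candidate tag frequency,
  apply the exponential gain correction, and return the argmax candidate
  (single-stimulus frequency estimation);
- :func:`decide_two` — compare the raw PSD at the two discs' frequencies
  and pick the larger (no correction: with tag frequencies only fractions
  of a hertz apart the gain roll-off is negligible);
- :func:`decode_keypad` — corrected argmax over a 12-key layout's tag
  frequencies, returning the chosen key.

All rules are deterministic; exact score ties resolve to the lowest
frequency (left disc for the two-choice rule).  The scikit-learn classifier
:class:`FrequencyTagDecoder` wraps the same scoring for batches of
equally long, already-preprocessed trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .calibration import DEFAULT_CALIBRATION, CalibrationModel
from .preprocess import PupilTrace
from .spectrum import periodogram, psd_at
from .stimulus import Layout

__all__ = ["DecodeResult", "estimate_single", "decide_two", "decode_keypad",
           "FrequencyTagDecoder"]


@dataclass(frozen=True)
class DecodeResult:
    """Outcome of one decoding decision.

    ``scores`` holds one (frequency, raw_psd, corrected) row per candidate;
    ``corrected`` equals ``raw_psd`` when no correction was applied.  The
    chosen candidate always carries the maximal corrected score.
    """

    estimated_frequency: float
    chosen_item: str | None
    scores: tuple[tuple[float, float, float], ...]
    used_correction: bool

    def score_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.scores), columns=["frequency_hz", "raw_psd", "corrected"]
        )


def _score_candidates(
    trace: PupilTrace,
    freqs: np.ndarray,
    model: CalibrationModel | None,
    use_correction: bool,
    grid_step: float,
    neighborhood: int,
):
    spec = periodogram(trace, grid_step=grid_step)
    raw = np.array([psd_at(spec, f, neighborhood=neighborhood) for f in freqs])
    if use_correction:
        mdl = model if model is not None else DEFAULT_CALIBRATION
        corrected = raw * mdl.weight(freqs)
    else:
        corrected = raw.copy()
    return raw, corrected


def estimate_single(
    trace: PupilTrace,
    candidates,
    model: CalibrationModel | None = None,
    use_correction: bool = True,
    grid_step: float = 0.01,
    neighborhood: int = 0,
) -> DecodeResult:
    """Estimate which candidate tag frequency drives a preprocessed trace.

    The periodogram is read at the grid bin nearest each candidate, the
    values are multiplied by the correction weight omega(f) (unless
    ``use_correction`` is off), and the candidate with the largest corrected
    PSD wins; ties go to the lowest frequency.
    """
    freqs = np.asarray(candidates, dtype=float)
    if freqs.size == 0:
        raise ValueError("candidate set must be non-empty")
    if np.unique(freqs).size != freqs.size:
        raise ValueError("candidate frequencies must be distinct")
    order = np.argsort(freqs)
    freqs = freqs[order]
    raw, corrected = _score_candidates(
        trace, freqs, model, use_correction, grid_step, neighborhood
    )
    best = int(np.argmax(corrected))  # first max = lowest frequency
    return DecodeResult(
        estimated_frequency=float(freqs[best]),
        chosen_item=None,
        scores=tuple(zip(freqs.tolist(), raw.tolist(), corrected.tolist())),
        used_correction=use_correction,
    )


def decide_two(
    trace: PupilTrace,
    f_left: float,
    f_right: float,
    model: CalibrationModel | None = None,
    use_correction: bool = False,
    grid_step: float = 0.01,
    neighborhood: int = 0,
) -> DecodeResult:
    """Two-choice decision: which of two tag frequencies has the larger PSD.

    Raw (uncorrected) PSD values are compared by default.  An exact tie
    resolves to the left item.
    """
    if f_left == f_right:
        raise ValueError("the two frequencies must differ")
    freqs = np.array([f_left, f_right], dtype=float)
    raw, corrected = _score_candidates(
        trace, freqs, model, use_correction, grid_step, neighborhood
    )
    side = "R" if corrected[1] > corrected[0] else "L"
    best = 1 if side == "R" else 0
    return DecodeResult(
        estimated_frequency=float(freqs[best]),
        chosen_item=side,
        scores=tuple(zip(freqs.tolist(), raw.tolist(), corrected.tolist())),
        used_correction=use_correction,
    )


def decode_keypad(
    trace: PupilTrace,
    layout: Layout,
    model: CalibrationModel | None = None,
    use_correction: bool = True,
    grid_step: float = 0.01,
    neighborhood: int = 0,
) -> DecodeResult:
    """Corrected argmax over a layout's tag frequencies; returns the item.

    The layout must contain at least two items with distinct frequencies
    (the Layout type already enforces distinctness).  Ties resolve to the
    lowest-frequency item.
    """
    if len(layout) < 2:
        raise ValueError("keypad decoding needs a layout with at least two items")
    items = sorted(layout.items, key=lambda it: it.frequency)
    freqs = np.array([it.frequency for it in items])
    raw, corrected = _score_candidates(
        trace, freqs, model, use_correction, grid_step, neighborhood
    )
    best = int(np.argmax(corrected))
    return DecodeResult(
        estimated_frequency=float(freqs[best]),
        chosen_item=items[best].id,
        scores=tuple(zip(freqs.tolist(), raw.tolist(), corrected.tolist())),
        used_correction=use_correction,
    )


class FrequencyTagDecoder(BaseEstimator, ClassifierMixin):
    """Scikit-learn classifier assigning trials to candidate tag frequencies.

    Rows of X are equally long, already-preprocessed pupil traces sharing
    one sampling rate.  ``decision_function`` returns the (corrected) PSD
    score per candidate; ``predict`` returns the winning frequency.  Ties
    resolve to the lowest candidate frequency.

    Parameters
    ----------
    candidates : sequence of float
        Candidate tag frequencies in Hz.
    calibration : CalibrationModel, optional
        Gain model for the correction; the published group fit by default.
    use_correction : bool
        Multiply PSD values by omega(f) before the argmax.
    sampling_rate : float
        Sampling rate of the trace rows, Hz.
    grid_step : float
        Periodogram grid spacing bound, Hz.
    """

    def __init__(
        self,
        candidates=None,
        calibration: CalibrationModel | None = None,
        use_correction: bool = True,
        sampling_rate: float = 333.0,
        grid_step: float = 0.01,
    ):
        self.candidates = candidates
        self.calibration = calibration
        self.use_correction = use_correction
        self.sampling_rate = sampling_rate
        self.grid_step = grid_step

    def fit(self, X=None, y=None):
        if self.candidates is None or len(self.candidates) == 0:
            raise ValueError("candidates must be a non-empty frequency sequence")
        freqs = np.sort(np.asarray(self.candidates, dtype=float))
        if np.unique(freqs).size != freqs.size:
            raise ValueError("candidate frequencies must be distinct")
        self.classes_ = freqs
        self.calibration_ = (
            self.calibration if self.calibration is not None else DEFAULT_CALIBRATION
        )
        if X is not None:
            X = np.asarray(X, dtype=float)
            if X.ndim == 2:
                self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        if not hasattr(self, "classes_"):
            raise RuntimeError("decoder must be fitted before scoring")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_trials, n_samples)")
        out = np.empty((X.shape[0], self.classes_.size))
        for i, row in enumerate(X):
            trace = PupilTrace(row, sampling_rate=self.sampling_rate)
            _, corrected = _score_candidates(
                trace,
                self.classes_,
                self.calibration_,
                self.use_correction,
                self.grid_step,
                0,
            )
            out[i] = corrected
        return out

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]
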