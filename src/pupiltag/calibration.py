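"""Exponential gain calibration of the pupil frequency response.

The amplitude of pupil-size oscillation — and hence its PSD peak — falls off
steeply with the luminance-modulation frequency of the fixated stimulus.
Averaged over observers the mean PSD peak follows

    f(x) = a * exp(b * x),        a > 0, b < 0,

with the published group fit a = 3.545, b = -2.844 (R^2 = 0.97,
RMSE = 0.09).  Multiplying a measured PSD by the reciprocal weight

    omega(x) = 1 / (a * exp(b * x)) = exp(-b * x) / a

removes this physiological roll-off so that PSD values at different tag
frequencies become directly comparable.  This module fits the model to
(frequency, mean PSD) calibration data and provides the weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "CalibrationModel",
    "DEFAULT_CALIBRATION",
    "fit_exponential",
    "weight",
    "correct_scores",
    "save_model",
    "load_model",
    "ExponentialGainModel",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted parameters of the exponential PSD-decay model a*exp(b*x).

    Defaults are the published group fit, so decoding works out of the box
    without per-user calibration.
    """

    a: float = 3.545
    b: float = -2.844
    r_squared: float | None = None
    rmse: float | None = None

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("parameter a must be positive")

    def predict(self, f):
        """Model mean PSD at frequency ``f`` (Hz)."""
        return self.a * np.exp(self.b * np.asarray(f, dtype=float))

    def weight(self, f):
        """Correction weight omega(f) = 1 / (a * exp(b*f))."""
        return np.exp(-self.b * np.asarray(f, dtype=float)) / self.a


#: Published group calibration used when no per-user model is supplied.
DEFAULT_CALIBRATION = CalibrationModel()


def _exp_model(x, a, b):
    return a * np.exp(b * x)


def fit_exponential(freqs, mean_psd) -> CalibrationModel:
    """Nonlinear least-squares fit of a*exp(b*x) to mean-PSD data.

    Initial values come from an ordinary least-squares line through
    (f, log PSD) restricted to positive PSD points, which keeps the
    Levenberg-Marquardt iteration well away from divergence.

    Requires at least three points.
    """
    x = np.asarray(freqs, dtype=float)
    y = np.asarray(mean_psd, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("freqs and mean_psd must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("exponential fit needs at least three points")

    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
        p0 = (float(np.exp(intercept)), float(slope))
    else:
        p0 = (max(float(y.max()), 1e-6), -1.0)

    try:
        popt, _ = curve_fit(_exp_model, x, y, p0=p0, maxfev=20000)
    except RuntimeError as err:  # pragma: no cover - hard to trigger
        raise RuntimeError(
            f"exponential fit failed to converge (start {p0}): {err}"
        ) from err

    a_hat, b_hat = float(popt[0]), float(popt[1])
    resid = y - _exp_model(x, a_hat, b_hat)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    rmse = float(np.sqrt(ss_res / x.size))
    return CalibrationModel(a=a_hat, b=b_hat, r_squared=r2, rmse=rmse)


def weight(model: CalibrationModel, f):
    """Correction weight omega(f); see :meth:`CalibrationModel.weight`."""
    return model.weight(f)


def correct_scores(model: CalibrationModel, freqs, psd):
    """Elementwise corrected scores psd_i * omega(f_i).

    PSD values lying exactly on the calibration curve flatten to 1.
    """
    f = np.asarray(freqs, dtype=float)
    p = np.asarray(psd, dtype=float)
    if f.shape != p.shape:
        raise ValueError("freqs and psd must have matching shapes")
    return p * model.weight(f)


def save_model(model: CalibrationModel, path: str | Path) -> None:
    lines = [f"a\t{model.a!r}", f"b\t{model.b!r}"]
    if model.r_squared is not None:
        lines.append(f"r_squared\t{model.r_squared!r}")
    if model.rmse is not None:
        lines.append(f"rmse\t{model.rmse!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> CalibrationModel:
    fields: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, value = line.split()
        fields[key] = float(value)
    return CalibrationModel(
        a=fields["a"],
        b=fields["b"],
        r_squared=fields.get("r_squared"),
        rmse=fields.get("rmse"),
    )


class ExponentialGainModel(BaseEstimator, RegressorMixin):
    """Scikit-learn front end for the exponential PSD-decay model.

    Constructed with the published group parameters; ``fit`` re-estimates
    them from calibration data and stores the result in the fitted
    attributes ``a_``, ``b_``, ``r_squared_`` and ``rmse_``.

    Parameters
    ----------
    a, b : float
        Model parameters used before (or instead of) fitting.
    """

    def __init__(self, a: float = 3.545, b: float = -2.844):
        self.a = a
        self.b = b

    def _model(self) -> CalibrationModel:
        if hasattr(self, "a_"):
            return CalibrationModel(
                a=self.a_, b=self.b_, r_squared=self.r_squared_, rmse=self.rmse_
            )
        return CalibrationModel(a=self.a, b=self.b)

    def fit(self, X, y):
        """Fit to frequencies X (1-D or column vector, Hz) and mean PSD y."""
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("X must be a single column of frequencies")
            x = x.ravel()
        fitted = fit_exponential(x, np.asarray(y, dtype=float))
        self.a_ = fitted.a
        self.b_ = fitted.b
        self.r_squared_ = fitted.r_squared
        self.rmse_ = fitted.rmse
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        shape_1d = x.ndim == 2
        if shape_1d:
            x = x.ravel()
        return self._model().predict(x)

    def weight(self, f):
        """Correction weight omega(f) under the current parameters."""
        return self._model().weight(f)

    def to_calibration(self) -> CalibrationModel:
        """Export the current parameters as a plain :class:`CalibrationModel`."""
        return self._model()
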