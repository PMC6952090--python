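"""Synthetic pupil traces with the statistical structure the decoder assumes.

The simulated pupil diameter for a trial in which the observer fixates one
item of a frequency-tagged layout is

    p(t) = baseline
           - sum_i w_i * G(f_i) * sin(2 pi f_i (t - latency))
           + band-limited autonomic noise (0.15-0.40 Hz)
           + white sensor noise
           - optional onset constriction in the first second,

where w_i = 1 for the fixated item and ``leakage`` for every other item,
and the entrainment gain decays exponentially with tag frequency,

    G(f) = gain_at_1hz * exp(gain_decay * (f - 1)),

with a steep extra roll-off beyond the pupil tracking limit
(``tracking_cutoff``, 3.15 Hz).  Because PSD scales with amplitude squared,
``gain_decay`` defaults to half the calibration decay constant b, so the
published exponential PSD-vs-frequency curve emerges from simulation.

The negative sign on the oscillation reflects that the pupil constricts to
brighter light; the decoder is phase-blind, so only the magnitude matters.

The defaults of :class:`PupilModelParams` constitute the *canonical noise
regime* used by the evaluation harness and all stochastic tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import PupilTrace, read_trace, write_trace
from .stimulus import (
    EXP1_FREQUENCIES,
    EXP2A_BASE_FREQUENCIES,
    EXP2A_DELTA_FS,
    Layout,
    make_exp1_layout,
    make_exp2a_layout,
    make_exp2b_layout,
)

__all__ = [
    "PupilModelParams",
    "Trial",
    "gain",
    "simulate_trial",
    "generate_dataset",
    "manifest",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class PupilModelParams:
    """Parameters of the synthetic pupil model (canonical regime by default).

    Parameters
    ----------
    gain_at_1hz : float
        Oscillation amplitude (trace units) for a fixated item tagged at
        1 Hz.
    gain_decay : float
        Exponential decay of amplitude with frequency, 1/Hz.  Default
        -1.422 = b/2 of the published PSD fit (PSD ~ amplitude squared).
    latency : float
        Pupillary response latency in seconds (typical light-reflex value).
    leakage : float
        Relative amplitude, in [0, 1), of entrainment to non-fixated items.
    white_noise_sd : float
        Standard deviation of per-sample white measurement noise.
    band_noise_amp : float
        Amplitude of autonomic (hippus) noise, realized as random-phase
        sinusoids inside ``band_noise_range``.
    band_noise_range : tuple
        Frequency band of the autonomic noise, Hz.
    baseline : float
        Mean pupil diameter in trace units.
    onset_dip : bool
        Include a decaying onset constriction in the first second.
    tracking_cutoff : float
        Frequency (Hz) above which pupil entrainment collapses.
    rolloff_rate : float
        Extra exponential decay rate, 1/Hz, applied beyond the cutoff.
    onset_dip_amp, onset_dip_tau : float
        Depth (trace units) and time constant (s) of the onset constriction.
    n_band_components : int
        Number of random sinusoids composing the autonomic noise.
    """

    gain_at_1hz: float = 1.0
    gain_decay: float = -1.422
    latency: float = 0.4
    leakage: float = 0.15
    white_noise_sd: float = 0.5
    band_noise_amp: float = 0.5
    band_noise_range: tuple[float, float] = (0.15, 0.40)
    baseline: float = 100.0
    onset_dip: bool = True
    tracking_cutoff: float = 3.15
    rolloff_rate: float = 8.0
    onset_dip_amp: float = 5.0
    onset_dip_tau: float = 0.25
    n_band_components: int = 8

    def __post_init__(self) -> None:
        if not 0 <= self.leakage < 1:
            raise ValueError("leakage must lie in [0, 1)")
        lo, hi = self.band_noise_range
        if not 0 < lo < hi:
            raise ValueError("band_noise_range must satisfy 0 < low < high")
        for name in ("gain_at_1hz", "white_noise_sd", "band_noise_amp",
                     "onset_dip_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class Trial:
    """One simulated trial: the raw trace plus its ground-truth metadata."""

    trace: PupilTrace
    meta: dict


def gain(params: PupilModelParams, f: float) -> float:
    """Entrainment amplitude G(f) for a fixated item tagged at ``f`` Hz."""
    if not f > 0:
        raise ValueError("frequency must be positive")
    g = params.gain_at_1hz * np.exp(params.gain_decay * (f - 1.0))
    if f > params.tracking_cutoff:
        g *= np.exp(-params.rolloff_rate * (f - params.tracking_cutoff))
    return float(g)


def simulate_trial(
    layout: Layout,
    gazed_id: str,
    duration: float,
    sampling_rate: float = 333.0,
    params: PupilModelParams | None = None,
    seed=None,
) -> PupilTrace:
    """Simulate one fixation trial on a layout.

    ``seed`` may be an int or a numpy Generator; the same seed always yields
    the identical trace.
    """
    if params is None:
        params = PupilModelParams()
    if not duration > 0:
        raise ValueError("duration must be positive")
    layout.item(gazed_id)  # raises KeyError for unknown ids
    rng = np.random.default_rng(seed)

    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    p = np.full(n, params.baseline, dtype=float)

    for it in layout:
        w = 1.0 if it.id == gazed_id else params.leakage
        p -= w * gain(params, it.frequency) * np.sin(
            2 * np.pi * it.frequency * (t - params.latency)
        )

    # hippus: random-phase sinusoids inside the autonomic band, scaled so the
    # summed process has the variance of one sinusoid of band_noise_amp
    k = params.n_band_components
    band_f = rng.uniform(*params.band_noise_range, size=k)
    band_phi = rng.uniform(0.0, 2 * np.pi, size=k)
    amp = params.band_noise_amp / np.sqrt(k)
    for fk, phik in zip(band_f, band_phi):
        p += amp * np.sin(2 * np.pi * fk * t + phik)

    p += rng.normal(0.0, params.white_noise_sd, size=n)

    if params.onset_dip:
        p -= params.onset_dip_amp * np.exp(-t / params.onset_dip_tau)

    return PupilTrace(p, sampling_rate=sampling_rate)


def _trial_seed(master: np.random.Generator) -> int:
    return int(master.integers(2**31))


def generate_dataset(
    protocol: str,
    n_reps: int,
    params: PupilModelParams | None = None,
    seed=None,
    sampling_rate: float = 333.0,
) -> list[Trial]:
    """Simulate a full labelled trial set for one experimental protocol.

    - ``exp1``: 12 tag frequencies x n_reps, 10 s single-stimulus trials;
    - ``exp2a``: 8 base frequencies x 3 frequency offsets x {L, R} x n_reps,
      8 s two-choice trials;
    - ``exp2b``: 12 keys x n_reps, 8 s keypad trials.

    Each trial records its own sub-seed in the metadata so datasets written
    to disk can be regenerated exactly.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if params is None:
        params = PupilModelParams()
    master = np.random.default_rng(seed)
    trials: list[Trial] = []

    if protocol == "exp1":
        duration = 10.0
        for rep in range(n_reps):
            for f in EXP1_FREQUENCIES:
                layout = make_exp1_layout(f)
                s = _trial_seed(master)
                trace = simulate_trial(layout, "stim", duration, sampling_rate,
                                       params, s)
                trials.append(Trial(trace, {
                    "trial_id": len(trials), "protocol": "exp1", "rep": rep,
                    "gazed_id": "stim", "gazed_frequency": f,
                    "duration_s": duration, "seed": s,
                }))
    elif protocol == "exp2a":
        duration = 8.0
        for rep in range(n_reps):
            for base in EXP2A_BASE_FREQUENCIES:
                for df in EXP2A_DELTA_FS:
                    for side in ("L", "R"):
                        layout = make_exp2a_layout(base, df)
                        s = _trial_seed(master)
                        trace = simulate_trial(layout, side, duration,
                                               sampling_rate, params, s)
                        trials.append(Trial(trace, {
                            "trial_id": len(trials), "protocol": "exp2a",
                            "rep": rep, "gazed_id": side,
                            "gazed_frequency": layout.item(side).frequency,
                            "base_frequency": base, "delta_f": df,
                            "duration_s": duration, "seed": s,
                        }))
    elif protocol == "exp2b":
        duration = 8.0
        layout = make_exp2b_layout()
        for rep in range(n_reps):
            for it in layout:
                s = _trial_seed(master)
                trace = simulate_trial(layout, it.id, duration, sampling_rate,
                                       params, s)
                trials.append(Trial(trace, {
                    "trial_id": len(trials), "protocol": "exp2b", "rep": rep,
                    "gazed_id": it.id, "gazed_label": it.label,
                    "gazed_frequency": it.frequency,
                    "duration_s": duration, "seed": s,
                }))
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    return trials


def manifest(trials: list[Trial]) -> pd.DataFrame:
    """Ground-truth manifest of a trial set as a DataFrame."""
    return pd.DataFrame([t.meta for t in trials])


def write_dataset(trials: list[Trial], directory: str | Path) -> None:
    """Write one trace file per trial plus a tab-delimited manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t in trials:
        write_trace(t.trace, directory / f"trial{t.meta['trial_id']:05d}.tsv")
    manifest(trials).to_csv(directory / "manifest.tsv", sep="\t", index=False)


def read_dataset(directory: str | Path) -> list[Trial]:
    """Read a trial set written by :func:`write_dataset`."""
    directory = Path(directory)
    man = pd.read_csv(directory / "manifest.tsv", sep="\t")
    trials = []
    for _, row in man.iterrows():
        trace = read_trace(directory / f"trial{int(row['trial_id']):05d}.tsv")
        trials.append(Trial(trace, row.to_dict()))
    return trials
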