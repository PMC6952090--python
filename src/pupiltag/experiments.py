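"""Evaluation harness: per-condition accuracy for the three interface sizes.

Each runner takes a labelled trial set (simulated or recorded), applies the
standard preprocessing (1 s onset trim, 120 ms moving average, z-score),
decodes every trial with the matching decision rule, and tabulates accuracy:

- :func:`run_exp1` — single-stimulus frequency estimation over the 12
  candidate frequencies with the gain correction; per-frequency accuracy
  and a 12x12 confusion matrix;
- :func:`run_exp2a` — two-choice decisions without correction; accuracy per
  (base frequency, frequency offset) cell and marginal per offset;
- :func:`run_exp2b` — corrected 12-key decoding; per-key accuracy, overall
  mean, and the mean excluding the lowest tag frequency.

Accuracies are reported in percent.  All runners are deterministic given the
trial set and decoder settings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationModel
from .decoder import decide_two, decode_keypad, estimate_single
from .preprocess import preprocess
from .simulate import Trial
from .stimulus import EXP1_FREQUENCIES, make_exp2b_layout

__all__ = ["Exp1Result", "Exp2aResult", "Exp2bResult",
           "run_exp1", "run_exp2a", "run_exp2b", "overall_accuracy"]


@dataclass(frozen=True)
class Exp1Result:
    accuracy: pd.DataFrame      # frequency_hz, n_trials, n_correct, accuracy_pct
    confusion: pd.DataFrame     # rows = actual frequency, cols = estimated


@dataclass(frozen=True)
class Exp2aResult:
    by_condition: pd.DataFrame  # base_frequency, delta_f, n, n_correct, accuracy_pct
    by_delta_f: pd.DataFrame    # delta_f marginals


@dataclass(frozen=True)
class Exp2bResult:
    by_key: pd.DataFrame        # key, label, frequency_hz, n, n_correct, accuracy_pct
    overall_pct: float
    overall_excluding_lowest_pct: float


def _acc_table(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    grouped = df.groupby(keys, as_index=False).agg(
        n_trials=("correct", "size"), n_correct=("correct", "sum")
    )
    grouped["accuracy_pct"] = 100.0 * grouped["n_correct"] / grouped["n_trials"]
    return grouped


def overall_accuracy(table: pd.DataFrame) -> float:
    """Trial-weighted overall accuracy (%) of an accuracy table."""
    return 100.0 * table["n_correct"].sum() / table["n_trials"].sum()


def _prep(trial: Trial, trim_s: float, smooth_ms: float):
    return preprocess(trial.trace, trim_s=trim_s, smooth_ms=smooth_ms)


def run_exp1(
    trials: list[Trial],
    model: CalibrationModel | None = None,
    candidates=EXP1_FREQUENCIES,
    trim_s: float = 1.0,
    smooth_ms: float = 120.0,
) -> Exp1Result:
    """Decode a single-stimulus trial set and tabulate per-frequency accuracy."""
    records = []
    for t in trials:
        if t.meta.get("protocol", "exp1") != "exp1":
            raise ValueError("run_exp1 expects exp1-protocol trials")
        est = estimate_single(_prep(t, trim_s, smooth_ms), candidates, model)
        actual = float(t.meta["gazed_frequency"])
        records.append({
            "actual": actual,
            "estimated": est.estimated_frequency,
            "correct": est.estimated_frequency == actual,
        })
    df = pd.DataFrame(records)
    acc = _acc_table(df.rename(columns={"actual": "frequency_hz"}),
                     ["frequency_hz"])
    freqs = sorted({r["actual"] for r in records} | set(candidates))
    confusion = pd.crosstab(df["actual"], df["estimated"]).reindex(
        index=freqs, columns=freqs, fill_value=0
    )
    confusion.index.name = "actual_hz"
    confusion.columns.name = "estimated_hz"
    return Exp1Result(accuracy=acc, confusion=confusion)


def run_exp2a(
    trials: list[Trial],
    trim_s: float = 1.0,
    smooth_ms: float = 120.0,
) -> Exp2aResult:
    """Decode a two-choice trial set; accuracy per condition and per offset."""
    records = []
    for t in trials:
        if t.meta.get("protocol", "exp2a") != "exp2a":
            raise ValueError("run_exp2a expects exp2a-protocol trials")
        base = float(t.meta["base_frequency"])
        df_ = float(t.meta["delta_f"])
        res = decide_two(_prep(t, trim_s, smooth_ms), base, base + df_)
        records.append({
            "base_frequency": base,
            "delta_f": df_,
            "side": t.meta["gazed_id"],
            "correct": res.chosen_item == t.meta["gazed_id"],
        })
    df = pd.DataFrame(records)
    return Exp2aResult(
        by_condition=_acc_table(df, ["base_frequency", "delta_f"]),
        by_delta_f=_acc_table(df, ["delta_f"]),
    )


def run_exp2b(
    trials: list[Trial],
    model: CalibrationModel | None = None,
    trim_s: float = 1.0,
    smooth_ms: float = 120.0,
) -> Exp2bResult:
    """Decode a keypad trial set; per-key accuracy and overall means."""
    layout = make_exp2b_layout()
    records = []
    for t in trials:
        if t.meta.get("protocol", "exp2b") != "exp2b":
            raise ValueError("run_exp2b expects exp2b-protocol trials")
        res = decode_keypad(_prep(t, trim_s, smooth_ms), layout, model)
        records.append({
            "key": t.meta["gazed_id"],
            "label": t.meta.get("gazed_label", t.meta["gazed_id"]),
            "frequency_hz": float(t.meta["gazed_frequency"]),
            "correct": res.chosen_item == t.meta["gazed_id"],
        })
    df = pd.DataFrame(records)
    by_key = _acc_table(df, ["key", "label", "frequency_hz"]).sort_values(
        "frequency_hz", ignore_index=True
    )
    overall = overall_accuracy(by_key)
    lowest = by_key["frequency_hz"].min()
    excl = by_key[by_key["frequency_hz"] > lowest]
    return Exp2bResult(
        by_key=by_key,
        overall_pct=overall,
        overall_excluding_lowest_pct=overall_accuracy(excl),
    )
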