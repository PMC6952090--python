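"""Luminance-modulated visual stimuli and frequency-tagged layouts.

Each selectable item on screen is a disc whose grayscale value is modulated
sinusoidally at a unique "tag" frequency,

    y_RGB(t) = A * sin(2*pi*f*t) + 127,

clipped to the displayable range [0, 255].  The pupillary light reflex
entrains to the luminance of the fixated disc, so the tag frequency of the
gazed item can be read back out of the pupil-diameter spectrum.  This module
builds the modulation waveforms, maps RGB values to physical luminance
through an offset-gamma display model, and constructs the three canonical
layouts: a single centered disc, a left/right pair, and a 12-key keypad.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ModulationSpec",
    "DisplayModel",
    "LayoutItem",
    "Layout",
    "rgb_waveform",
    "sample_waveform",
    "rgb_to_luminance",
    "make_exp1_layout",
    "make_exp2a_layout",
    "make_exp2b_layout",
    "save_layout",
    "load_layout",
    "write_waveform",
    "EXP1_FREQUENCIES",
    "EXP2A_BASE_FREQUENCIES",
    "EXP2A_DELTA_FS",
    "EXP2B_FREQUENCIES",
    "EXP2B_LABELS",
]

#: Tag frequencies probed in the single-stimulus experiment (Hz).
EXP1_FREQUENCIES = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0, 2.25, 2.5, 2.75, 3.0)

#: Left-disc base frequencies of the two-choice experiment (Hz).
EXP2A_BASE_FREQUENCIES = (0.75, 1.0, 1.25, 1.5, 1.75, 2.0, 2.25, 2.5)

#: Frequency offsets of the right disc relative to the left (Hz).
EXP2A_DELTA_FS = (0.06, 0.12, 0.25)

#: Keypad frequencies, ascending left-to-right then top-to-bottom (Hz).
EXP2B_FREQUENCIES = (0.58, 0.70, 0.82, 0.94, 1.06, 1.18,
                     1.30, 1.42, 1.54, 1.66, 1.78, 1.90)

#: Keypad key labels in the same order as ``EXP2B_FREQUENCIES``.
EXP2B_LABELS = ("1", "2", "3", "4", "5", "6", "7", "8", "9", "SPACE", "0", "<")


@dataclass(frozen=True)
class ModulationSpec:
    """Sinusoidal RGB modulation of one stimulus.

    Parameters
    ----------
    frequency : float
        Modulation frequency in Hz; must be positive.
    amplitude : float
        Peak RGB deviation from the offset (default 128, half the maximum
        RGB value).
    offset : float
        Mean RGB value (127).
    duration : float
        Stimulus duration in seconds.
    frame_rate : float
        Display refresh rate in Hz used when sampling the waveform.
    """

    frequency: float
    amplitude: float = 128.0
    offset: float = 127.0
    duration: float = 10.0
    frame_rate: float = 60.0

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ValueError(f"frequency must be positive, got {self.frequency}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be non-negative, got {self.amplitude}")
        if not self.duration > 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if not self.frame_rate > 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")


@dataclass(frozen=True)
class DisplayModel:
    """Offset-gamma model of the display: L(v) = Lb + (Lmax-Lb)*(v/255)**gamma.

    Anchored so that RGB 0 emits ``black_level`` and RGB 255 emits
    ``max_luminance`` exactly (cd/m^2).
    """

    gamma: float = 2.8
    black_level: float = 0.99
    max_luminance: float = 99.4

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if not (0 <= self.black_level < self.max_luminance):
            raise ValueError("require 0 <= black_level < max_luminance")


@dataclass(frozen=True)
class LayoutItem:
    """One frequency-tagged disc: identity, tag frequency, and geometry."""

    id: str
    label: str
    frequency: float
    x_deg: float = 0.0
    y_deg: float = 0.0
    diameter_deg: float = 3.0


@dataclass(frozen=True)
class Layout:
    """A set of frequency-tagged items forming one interface screen."""

    items: tuple[LayoutItem, ...]

    def __post_init__(self) -> None:
        freqs = [it.frequency for it in self.items]
        if any(f <= 0 for f in freqs):
            raise ValueError("all item frequencies must be positive")
        if len(set(freqs)) != len(freqs):
            raise ValueError("item frequencies must be distinct")

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([it.frequency for it in self.items])

    def item(self, item_id: str) -> LayoutItem:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(f"no item with id {item_id!r}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)


def rgb_waveform(spec: ModulationSpec, times: Sequence[float] | np.ndarray | float):
    """RGB value of the modulation at the given times (s).

    Evaluates ``A*sin(2*pi*f*t) + offset`` and clips to [0, 255]; with the
    default amplitude 128 the raw minimum is -1, which the clip maps to 0.
    Scalar input returns a scalar.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    raw = spec.amplitude * np.sin(2 * np.pi * spec.frequency * t) + spec.offset
    out = np.clip(raw, 0.0, 255.0)
    return float(out) if np.ndim(times) == 0 else out


def sample_waveform(spec: ModulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Waveform sampled at the display frame rate over the full duration."""
    n = int(round(spec.duration * spec.frame_rate))
    times = np.arange(n) / spec.frame_rate
    return times, rgb_waveform(spec, times)


def rgb_to_luminance(display: DisplayModel, rgb):
    """Physical luminance (cd/m^2) emitted for an RGB value in [0, 255]."""
    v = np.asarray(rgb, dtype=float)
    if np.any(v < 0) or np.any(v > 255):
        raise ValueError("rgb values must lie in [0, 255]")
    lum = display.black_level + (display.max_luminance - display.black_level) * (
        v / 255.0
    ) ** display.gamma
    return float(lum) if np.ndim(rgb) == 0 else lum


def make_exp1_layout(frequency: float) -> Layout:
    """Single 3-degree disc at screen center, tagged at ``frequency``."""
    if not frequency > 0:
        raise ValueError("frequency must be positive")
    return Layout((LayoutItem("stim", "stim", float(frequency), 0.0, 0.0, 3.0),))


def make_exp2a_layout(f_left: float, delta_f: float) -> Layout:
    """Two 3-degree discs side by side with a 1-degree edge gap.

    The right disc is tagged ``delta_f`` Hz above the left.  Centers sit at
    x = -2 and +2 degrees (radius 1.5 each plus the 1-degree separation).
    """
    if not f_left > 0:
        raise ValueError("f_left must be positive")
    if not delta_f > 0:
        raise ValueError("delta_f must be positive")
    return Layout(
        (
            LayoutItem("L", "L", float(f_left), -2.0, 0.0, 3.0),
            LayoutItem("R", "R", float(f_left + delta_f), 2.0, 0.0, 3.0),
        )
    )


def make_exp2b_layout() -> Layout:
    """Twelve-key keypad: 3 columns x 4 rows of 3-degree discs.

    Tag frequencies run 0.58 to 1.90 Hz in 0.12 Hz steps, increasing left to
    right and top to bottom.  Adjacent disc edges are separated by 1 degree
    (centers 4 degrees apart).
    """
    items = []
    for i, (f, label) in enumerate(zip(EXP2B_FREQUENCIES, EXP2B_LABELS)):
        row, col = divmod(i, 3)
        items.append(
            LayoutItem(f"key{i}", label, f, x_deg=4.0 * (col - 1), y_deg=6.0 - 4.0 * row)
        )
    return Layout(tuple(items))


def save_layout(layout: Layout, path: str | Path) -> None:
    """Write a layout as a YAML list of item mappings."""
    records = [
        {
            "id": it.id,
            "label": it.label,
            "frequency_hz": it.frequency,
            "x_deg": it.x_deg,
            "y_deg": it.y_deg,
            "diameter_deg": it.diameter_deg,
        }
        for it in layout.items
    ]
    Path(path).write_text(yaml.safe_dump(records, sort_keys=False))


def load_layout(path: str | Path) -> Layout:
    """Read a layout written by :func:`save_layout`."""
    records = yaml.safe_load(Path(path).read_text())
    items = tuple(
        LayoutItem(
            str(r["id"]),
            str(r["label"]),
            float(r["frequency_hz"]),
            float(r.get("x_deg", 0.0)),
            float(r.get("y_deg", 0.0)),
            float(r.get("diameter_deg", 3.0)),
        )
        for r in records
    )
    return Layout(items)


def write_waveform(path: str | Path, times: np.ndarray, values: np.ndarray) -> None:
    """Export a sampled waveform as two-column delimited text (time_s, rgb)."""
    arr = np.column_stack([np.asarray(times), np.asarray(values)])
    np.savetxt(path, arr, fmt="%.6f\t%.3f", header="time_s\trgb", comments="")
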