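"""Cochleagram front-end and the maturational blur schedule.

Waveforms are converted to 100 x 100 cochleagrams: a bank of gammatone
band-pass filters with center frequencies spaced on the ERB (equivalent
rectangular bandwidth) scale, half-wave rectification, envelope extraction by
temporal binning, and power-law compression (exponent 0.3), following standard
human-cochlea modelling practice.

The developmental manipulation is applied to the cochleagram image: a
normalized box filter of shape (1, y) oriented along the frequency axis
(frequency is the vertical axis of the image), whose height y shrinks over
training epochs according to a per-condition maturation schedule:

* ``control``: y = 1 throughout (full acuity from the outset),
* ``regular``: y falls from 25 to 1, reaching full resolution by epoch 7
  (of 10; proportionally for shorter runs),
* ``delay``:   y falls from 25 to only 16, never reaching full resolution.

The regular and delay conditions are identical at epoch 1 and the delay
kernel is at least as tall as the regular kernel at every epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import ceil

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import gammatone, lfilter

__all__ = [
    "Cochleagram",
    "CochleagramConfig",
    "MaturationSchedule",
    "CONDITIONS",
    "erb_space",
    "cochleagram",
    "blur",
    "make_schedule",
    "kernel_height",
]

CONDITIONS = ("control", "regular", "delay")


def erb_space(fmin: float, fmax: float, n: int) -> np.ndarray:
    """``n`` center frequencies uniformly spaced on the ERB-number scale.

    Uses the Glasberg & Moore ERB-number mapping
    ``E(f) = 21.4 log10(1 + 0.00437 f)``.
    """
    e = 21.4 * np.log10(1 + 0.00437 * np.array([fmin, fmax]))
    erbs = np.linspace(e[0], e[1], n)
    return (10 ** (erbs / 21.4) - 1) / 0.00437


def erb_bandwidth(f: float) -> float:
    """Equivalent rectangular bandwidth (Hz) at center frequency ``f``."""
    return 24.7 * (1 + 0.00437 * f)


@dataclass(frozen=True)
class CochleagramConfig:
    n_channels: int = 100
    n_frames: int = 100
    fmin: float = 50.0
    fmax: float = 7500.0
    compression_exponent: float = 0.3


@dataclass(frozen=True)
class Cochleagram:
    """Nonnegative [n_channels x n_frames] activation image.

    ``values[0]`` is the lowest-frequency channel; ``channel_cfs`` are ERB
    spaced and strictly increasing; ``frame_times`` are frame centers (s).
    """

    values: np.ndarray
    channel_cfs: np.ndarray
    frame_times: np.ndarray

    @property
    def shape(self):
        return self.values.shape


@lru_cache(maxsize=16)
def _filterbank(sample_rate: int, n_channels: int, fmin: float, fmax: float):
    cfs = erb_space(fmin, fmax, n_channels)
    coeffs = [gammatone(float(f), "iir", fs=sample_rate) for f in cfs]
    return cfs, coeffs


def cochleagram(
    waveform: np.ndarray,
    sample_rate: int,
    config: CochleagramConfig | None = None,
) -> Cochleagram:
    """ERB-spaced gammatone filterbank -> rectify -> bin -> compress.

    Raises on empty or non-finite input, or if the waveform is shorter than
    one output frame.
    """
    config = config or CochleagramConfig()
    waveform = np.asarray(waveform, dtype=np.float64)
    if waveform.ndim != 1 or waveform.size == 0:
        raise ValueError("waveform must be a nonempty 1-D array")
    if not np.all(np.isfinite(waveform)):
        raise ValueError("waveform contains non-finite samples")
    if not config.fmin < config.fmax < sample_rate / 2:
        raise ValueError("need fmin < fmax < Nyquist")
    if waveform.size < config.n_frames:
        raise ValueError("waveform shorter than one frame per output column")

    cfs, coeffs = _filterbank(sample_rate, config.n_channels, config.fmin, config.fmax)
    # temporal bin edges: n_frames equal bins over the waveform
    edges = np.linspace(0, waveform.size, config.n_frames + 1).astype(int)
    values = np.empty((config.n_channels, config.n_frames))
    for ch, (b, a) in enumerate(coeffs):
        rect = np.maximum(lfilter(b, a, waveform), 0.0)
        summed = np.concatenate([[0.0], np.cumsum(rect)])
        values[ch] = (summed[edges[1:]] - summed[edges[:-1]]) / np.diff(edges)
    values = np.maximum(values, 0.0) ** config.compression_exponent
    frame_times = (edges[:-1] + np.diff(edges) / 2) / sample_rate
    return Cochleagram(values=values, channel_cfs=np.asarray(cfs), frame_times=frame_times)


def blur(c: Cochleagram, y: int) -> Cochleagram:
    """Normalized box filter of height ``y`` along the frequency axis.

    Each output cell is the mean of a length-``y`` window of channels at the
    same time frame (reflective borders); the time axis is untouched and
    ``y = 1`` is the identity.
    """
    y = int(y)
    if y < 1:
        raise ValueError("kernel height y must be >= 1")
    n_channels = c.values.shape[0]
    if y > 2 * n_channels:
        raise ValueError(f"kernel height {y} degenerate for {n_channels} channels")
    if y == 1:
        return c
    smoothed = uniform_filter1d(c.values, size=y, axis=0, mode="reflect")
    return Cochleagram(values=smoothed, channel_cfs=c.channel_cfs, frame_times=c.frame_times)


@dataclass(frozen=True)
class MaturationSchedule:
    """Per-epoch box-kernel heights for one maturation condition."""

    condition: str
    y_by_epoch: tuple[int, ...]
    y_test: int

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        ys = self.y_by_epoch
        if any(y < 1 for y in ys) or self.y_test < 1:
            raise ValueError("kernel heights must be >= 1")
        if any(a < b for a, b in zip(ys, ys[1:])):
            raise ValueError("y_by_epoch must be non-increasing")

    @property
    def n_epochs(self) -> int:
        return len(self.y_by_epoch)


def _linear_integer_descent(y0: int, y1: int, n: int) -> list[int]:
    if n == 1:
        return [y1]
    return [int(round(y0 + (y1 - y0) * k / (n - 1))) for k in range(n)]


def make_schedule(condition: str, n_epochs: int = 10, y_start: int = 25, y_delay_end: int = 16) -> MaturationSchedule:
    """Build the default schedule for a condition.

    * control: y = 1 at every epoch and at test.
    * regular: linear integer descent from ``y_start`` to 1 over the first
      ``ceil(0.7 n_epochs)`` epochs (epoch 7 of 10), then 1; tested at 1.
    * delay: linear integer descent from ``y_start`` to ``y_delay_end`` over
      all epochs; tested at its final (still blurred) resolution.
    """
    if condition == "control":
        return MaturationSchedule("control", tuple([1] * n_epochs), y_test=1)
    if condition == "regular":
        reach = max(2, ceil(0.7 * n_epochs))
        ys = _linear_integer_descent(y_start, 1, reach) + [1] * (n_epochs - reach)
        return MaturationSchedule("regular", tuple(ys), y_test=1)
    if condition == "delay":
        ys = _linear_integer_descent(y_start, y_delay_end, n_epochs)
        return MaturationSchedule("delay", tuple(ys), y_test=y_delay_end)
    raise ValueError(f"unknown condition {condition!r}")


def kernel_height(schedule: MaturationSchedule, epoch: int) -> int:
    """Kernel height at a 1-based training epoch."""
    if not 1 <= epoch <= schedule.n_epochs:
        raise ValueError(f"epoch {epoch} out of range 1..{schedule.n_epochs}")
    return schedule.y_by_epoch[epoch - 1]
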