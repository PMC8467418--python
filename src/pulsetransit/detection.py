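"""Preprocessing chain: smoothing, differentiation, upstroke detection.

The processing follows the classic invasive-pressure recipe: a centred
moving-average filter on the raw pressure (default 1000 samples, 100 ms at
10 kHz), a central-difference first derivative, a second moving average on
the derivative (default 100 samples), then local-maxima picking on the
smoothed derivative to locate the instant of maximum systolic inclination
of every beat. Both channels of a recording are processed identically, so
any filter-induced group delay cancels in the transit-time difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

__all__ = [
    "moving_average",
    "differentiate",
    "FilteredSignal",
    "filter_signal",
    "UpstrokeEvent",
    "detect_upstrokes",
    "scaled_window",
]

#: default smoothing windows, tied to 10 kHz sampling (100 ms / 10 ms spans)
DEFAULT_PRESSURE_WINDOW = 1000
DEFAULT_DERIVATIVE_WINDOW = 100
REFERENCE_SAMPLING_RATE = 10_000.0

DEFAULT_MIN_BEAT_SEPARATION = 0.25  # s
DEFAULT_PROMINENCE_FRACTION = 0.3


def moving_average(signal: np.ndarray, window: int) -> np.ndarray:
    """Centred moving mean with reflect padding; length-preserving.

    Zero phase shift, so a feature at sample k in a symmetric input stays
    at sample k in the output.
    """
    signal = np.asarray(signal, dtype=float)
    window = int(window)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > signal.size:
        raise ValueError(f"window {window} exceeds signal length {signal.size}")
    if window == 1:
        return signal.copy()
    return uniform_filter1d(signal, size=window, mode="reflect")


def differentiate(signal: np.ndarray, sampling_rate: float) -> np.ndarray:
    """First derivative in mmHg/s: central differences, one-sided at edges."""
    signal = np.asarray(signal, dtype=float)
    if signal.size < 2:
        raise ValueError("need at least 2 samples to differentiate")
    return np.gradient(signal) * sampling_rate


def scaled_window(window: int, sampling_rate: float) -> int:
    """Scale a 10 kHz-referenced window to another sampling rate.

    Keeps the default 1000/100-sample windows meaning 100 ms / 10 ms spans
    on resampled input.
    """
    return max(1, int(round(window * sampling_rate / REFERENCE_SAMPLING_RATE)))


@dataclass
class FilteredSignal:
    """Smoothed pressure and smoothed first derivative of one channel."""

    smoothed_pressure: np.ndarray
    smoothed_derivative: np.ndarray
    pressure_window: int
    derivative_window: int
    sampling_rate: float


def filter_signal(
    pressure: np.ndarray,
    sampling_rate: float,
    pressure_window: int | None = None,
    derivative_window: int | None = None,
) -> FilteredSignal:
    """Apply the smoothing/derivative chain to one pressure channel.

    Windows default to 100 ms / 10 ms spans at the given sampling rate.
    """
    if pressure_window is None:
        pressure_window = scaled_window(DEFAULT_PRESSURE_WINDOW, sampling_rate)
    if derivative_window is None:
        derivative_window = scaled_window(DEFAULT_DERIVATIVE_WINDOW, sampling_rate)
    smoothed = moving_average(pressure, pressure_window)
    deriv = moving_average(differentiate(smoothed, sampling_rate), derivative_window)
    return FilteredSignal(
        smoothed_pressure=smoothed,
        smoothed_derivative=deriv,
        pressure_window=pressure_window,
        derivative_window=derivative_window,
        sampling_rate=sampling_rate,
    )


@dataclass
class UpstrokeEvent:
    """Instant of maximum systolic inclination of one beat."""

    sample_index: int
    time: float
    slope: float
    beat_index: int


def detect_upstrokes(
    filtered: FilteredSignal,
    min_beat_separation: float = DEFAULT_MIN_BEAT_SEPARATION,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
) -> list[UpstrokeEvent]:
    """Locate one maximum-inclination instant per cardiac cycle.

    Local maxima of the smoothed derivative, guarded by a minimum
    separation (default 0.25 s) and a height floor of
    ``prominence_fraction`` times the 95th percentile of the positive
    smoothed derivative. Returns an empty list when no pulsatile activity
    is present (e.g. constant pressure).
    """
    deriv = filtered.smoothed_derivative
    if deriv.size == 0:
        return []
    positive = deriv[deriv > 0]
    if positive.size == 0:
        return []
    height = prominence_fraction * np.percentile(positive, 95)
    if height <= 0:
        return []
    distance = max(1, int(round(min_beat_separation * filtered.sampling_rate)))
    peaks, _ = find_peaks(deriv, height=height, distance=distance)
    return [
        UpstrokeEvent(
            sample_index=int(k),
            time=k / filtered.sampling_rate,
            slope=float(deriv[k]),
            beat_index=i,
        )
        for i, k in enumerate(peaks)
    ]
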