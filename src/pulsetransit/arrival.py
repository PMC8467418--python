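"""Per-beat pulse arrival (intersecting-tangent foot) and beat pressures.

The pulse arrival of a beat is defined as the intersection of the tangent
at the maximum systolic upstroke with the horizontal line through the
preceding diastolic pressure. The tangent is constructed on the smoothed
pressure and smoothed derivative; per-beat systolic/mean/diastolic
pressures (sPAP/mPAP/dPAP) come from the raw, unsmoothed channel.

Exclusion rules: premature beats (short RR relative to the local median)
and artifact beats (pulse amplitude or upstroke slope far outside the
channel's median-absolute-deviation band) are marked invalid and excluded
from transit analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import FilteredSignal, UpstrokeEvent, detect_upstrokes, filter_signal

__all__ = [
    "BeatAnnotation",
    "find_diastolic_foot",
    "tangent_arrival",
    "beat_pressures",
    "flag_premature",
    "flag_artifacts",
    "annotate_channel",
    "beats_to_frame",
]

DEFAULT_FOOT_SEARCH_WINDOW = 0.3  # s before the upstroke
DEFAULT_PREMATURE_FRACTION = 0.8
DEFAULT_PREMATURE_WINDOW = 11  # beats
DEFAULT_ARTIFACT_MAD = 5.0


@dataclass
class BeatAnnotation:
    """One annotated beat on one channel."""

    beat_index: int
    arrival_time: float
    upstroke_time: float
    slope_at_upstroke: float
    diastolic_foot_time: float
    diastolic_foot_pressure: float
    spap: float
    mpap: float
    dpap: float
    rr_interval: float | None
    premature: bool = False
    valid: bool = True


def find_diastolic_foot(
    smoothed_pressure: np.ndarray,
    upstroke: UpstrokeEvent,
    sampling_rate: float,
    search_window: float = DEFAULT_FOOT_SEARCH_WINDOW,
) -> tuple[float, float]:
    """Locate the preceding diastolic minimum before an upstroke.

    Searches ``(upstroke_time - search_window, upstroke_time]`` for the
    minimum of the smoothed pressure; ties break toward the latest sample.

    Returns
    -------
    (time, pressure)

    Raises
    ------
    ValueError
        If the upstroke is closer to the recording start than the search
        window (the caller marks such beats invalid).
    """
    k_up = upstroke.sample_index
    k_lo = k_up - int(round(search_window * sampling_rate))
    if k_lo < 0:
        raise ValueError("upstroke too close to recording start for foot search")
    window = smoothed_pressure[k_lo + 1 : k_up + 1]
    if window.size == 0:
        raise ValueError("empty diastolic search window")
    rev = window[::-1]
    k_min = window.size - 1 - int(np.argmin(rev))  # latest minimum on ties
    k_abs = k_lo + 1 + k_min
    return k_abs / sampling_rate, float(smoothed_pressure[k_abs])


def tangent_arrival(
    upstroke: UpstrokeEvent,
    pressure_at_upstroke: float,
    diastolic_foot_pressure: float,
) -> float:
    """Intersect the maximum-upstroke tangent with the diastolic level.

    ``arrival = t_up - (p_up - p_foot) / slope``; continuous-valued, not
    snapped to the sample grid, so transit-time resolution is finer than
    the sample period.
    """
    if upstroke.slope <= 0:
        raise ValueError("upstroke slope must be positive")
    if pressure_at_upstroke < diastolic_foot_pressure:
        raise ValueError("pressure at upstroke below diastolic level")
    return upstroke.time - (pressure_at_upstroke - diastolic_foot_pressure) / upstroke.slope


def beat_pressures(
    raw_pressure: np.ndarray,
    beat_start: float,
    beat_end: float,
    sampling_rate: float,
) -> tuple[float, float, float]:
    """Systolic / mean / diastolic pressure over one beat window.

    Max, time average and min of the raw (unsmoothed) pressure over
    ``[beat_start, beat_end)``.
    """
    k0 = max(0, int(np.ceil(beat_start * sampling_rate)))
    k1 = min(raw_pressure.size, int(np.ceil(beat_end * sampling_rate)))
    if k1 <= k0:
        raise ValueError("empty beat window")
    seg = raw_pressure[k0:k1]
    return float(seg.max()), float(seg.mean()), float(seg.min())


def flag_premature(
    beats: list[BeatAnnotation],
    fraction: float = DEFAULT_PREMATURE_FRACTION,
    window: int = DEFAULT_PREMATURE_WINDOW,
) -> list[BeatAnnotation]:
    """Flag beats whose RR is short relative to the local median RR.

    A beat is premature when its RR interval is below ``fraction`` times
    the median RR of the surrounding ``window`` beats (itself excluded).
    The flagged beat and its successor are marked invalid — the successor's
    diastolic reference is corrupted by the ectopic beat. Mutates and
    returns the list.
    """
    rr = np.array(
        [b.rr_interval if b.rr_interval is not None else np.nan for b in beats]
    )
    half = window // 2
    n = len(beats)
    flagged = []
    for i, beat in enumerate(beats):
        if not np.isfinite(rr[i]):
            continue
        lo, hi = max(0, i - half), min(n, i + half + 1)
        neighbours = np.concatenate([rr[lo:i], rr[i + 1 : hi]])
        neighbours = neighbours[np.isfinite(neighbours)]
        if neighbours.size == 0:
            continue
        if rr[i] < fraction * np.median(neighbours):
            flagged.append(i)
    for i in flagged:
        beats[i].premature = True
        beats[i].valid = False
        if i + 1 < n:
            beats[i + 1].valid = False
    return beats


def flag_artifacts(
    beats: list[BeatAnnotation], n_mad: float = DEFAULT_ARTIFACT_MAD
) -> list[BeatAnnotation]:
    """Invalidate beats with outlying pulse amplitude or upstroke slope.

    Operationalises manual artifact screening: beats whose sPAP-dPAP range
    or maximum slope deviates from the channel median by more than
    ``n_mad`` median absolute deviations are marked invalid.
    """
    cand = [b for b in beats if b.valid]
    if len(cand) < 5:
        return beats
    for values in (
        np.array([b.spap - b.dpap for b in cand]),
        np.array([b.slope_at_upstroke for b in cand]),
    ):
        med = np.median(values)
        mad = np.median(np.abs(values - med))
        # floor the scale so numerically identical beats (noiseless input)
        # are not flagged on float-epsilon deviations
        scale = max(mad, 1e-3 * abs(med))
        if scale <= 0:
            continue
        for beat, v in zip(cand, values):
            if abs(v - med) > n_mad * scale:
                beat.valid = False
    return beats


def annotate_channel(
    pressure: np.ndarray,
    sampling_rate: float,
    pressure_window: int | None = None,
    derivative_window: int | None = None,
    min_beat_separation: float = 0.25,
    prominence_fraction: float = 0.3,
    foot_search_window: float = DEFAULT_FOOT_SEARCH_WINDOW,
    premature_fraction: float = DEFAULT_PREMATURE_FRACTION,
    premature_window: int = DEFAULT_PREMATURE_WINDOW,
    artifact_mad: float = DEFAULT_ARTIFACT_MAD,
    filtered: FilteredSignal | None = None,
) -> list[BeatAnnotation]:
    """Full single-channel annotation: detect, localise feet, measure.

    Pipeline: smooth + differentiate, pick upstrokes, find each beat's
    diastolic foot and tangent arrival, segment beats between consecutive
    arrivals for raw-pressure sPAP/mPAP/dPAP, then apply the premature and
    artifact exclusion rules. The last detected beat has no closing
    boundary and is dropped.
    """
    pressure = np.asarray(pressure, dtype=float)
    if filtered is None:
        filtered = filter_signal(pressure, sampling_rate, pressure_window, derivative_window)
    events = detect_upstrokes(filtered, min_beat_separation, prominence_fraction)
    if len(events) < 2:
        return []

    raw: list[BeatAnnotation] = []
    for ev in events:
        valid = True
        try:
            foot_t, foot_p = find_diastolic_foot(
                filtered.smoothed_pressure, ev, sampling_rate, foot_search_window
            )
            p_up = float(filtered.smoothed_pressure[ev.sample_index])
            arr = tangent_arrival(ev, p_up, foot_p)
        except ValueError:
            foot_t, foot_p, arr = np.nan, np.nan, np.nan
            valid = False
        raw.append(
            BeatAnnotation(
                beat_index=ev.beat_index,
                arrival_time=arr,
                upstroke_time=ev.time,
                slope_at_upstroke=ev.slope,
                diastolic_foot_time=foot_t,
                diastolic_foot_pressure=foot_p,
                spap=np.nan,
                mpap=np.nan,
                dpap=np.nan,
                rr_interval=None,
                valid=valid,
            )
        )

    # beat windows run arrival-to-arrival; the last beat has no right edge
    beats: list[BeatAnnotation] = []
    for i in range(len(raw) - 1):
        beat, nxt = raw[i], raw[i + 1]
        if beat.valid and nxt.valid and np.isfinite(beat.arrival_time):
            try:
                s, m, d = beat_pressures(
                    pressure, beat.arrival_time, nxt.arrival_time, sampling_rate
                )
                beat.spap, beat.mpap, beat.dpap = s, m, d
            except ValueError:
                beat.valid = False
        if i > 0 and np.isfinite(beat.arrival_time) and np.isfinite(raw[i - 1].arrival_time):
            beat.rr_interval = beat.arrival_time - raw[i - 1].arrival_time
        beats.append(beat)

    flag_premature(beats, premature_fraction, premature_window)
    flag_artifacts(beats, artifact_mad)
    return beats


def beats_to_frame(beats: list[BeatAnnotation], channel: str) -> pd.DataFrame:
    """Beat table in the on-disk dialect (one row per beat)."""
    return pd.DataFrame(
        {
            "channel": channel,
            "beat_idx": [b.beat_index for b in beats],
            "t_arrival_s": [b.arrival_time for b in beats],
            "spap": [b.spap for b in beats],
            "mpap": [b.mpap for b in beats],
            "dpap": [b.dpap for b in beats],
            "rr_s": [b.rr_interval if b.rr_interval is not None else np.nan for b in beats],
            "premature": [b.premature for b in beats],
            "valid": [b.valid for b in beats],
        }
    )
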