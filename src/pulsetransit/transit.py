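"""Beat matching across sites, transit time (PWTT) and wave velocity (PWV).

Transit time is the difference between the distal and proximal
tangent-foot arrival of the same pulse. Because both channels pass through
an identical filter chain, any waveform- or filter-induced arrival bias is
common to both sites and cancels in the difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arrival import BeatAnnotation

__all__ = [
    "BeatPair",
    "match_beats",
    "compute_pwtt",
    "compute_pwv",
    "build_pairs",
    "pairs_to_frame",
]

DEFAULT_MAX_LAG = 0.15  # s
#: physiological plausibility bounds on transit time, ms
DEFAULT_PWTT_BOUNDS = (2.0, 150.0)
#: plausibility band for pulmonary pulse wave velocity, m/s (logged, not fatal)
PWV_PLAUSIBLE = (0.5, 12.0)


@dataclass
class BeatPair:
    """A proximal/distal beat matched to the same pulse."""

    proximal: BeatAnnotation
    distal: BeatAnnotation
    pwtt: float  # ms
    pwv: float | None = None  # m/s, when sensor distance is known


def match_beats(
    proximal_beats: list[BeatAnnotation],
    distal_beats: list[BeatAnnotation],
    max_lag: float = DEFAULT_MAX_LAG,
) -> list[tuple[BeatAnnotation, BeatAnnotation]]:
    """Greedy matching: each distal beat takes the latest earlier proximal.

    Only valid beats participate. A distal arrival pairs with the latest
    proximal arrival strictly earlier than it and within ``max_lag``
    seconds; each proximal beat is used at most once; unmatched beats are
    dropped.
    """
    prox = [b for b in proximal_beats if b.valid and np.isfinite(b.arrival_time)]
    dist = [b for b in distal_beats if b.valid and np.isfinite(b.arrival_time)]
    pairs: list[tuple[BeatAnnotation, BeatAnnotation]] = []
    i = 0
    used = -1
    for d in dist:
        while i < len(prox) and prox[i].arrival_time < d.arrival_time:
            i += 1
        j = i - 1  # latest proximal strictly earlier
        if j > used and j >= 0 and d.arrival_time - prox[j].arrival_time <= max_lag:
            pairs.append((prox[j], d))
            used = j
    return pairs


def compute_pwtt(proximal: BeatAnnotation, distal: BeatAnnotation) -> float:
    """Transit time in ms: distal minus proximal arrival.

    A non-positive difference signals mis-matching and is rejected.
    """
    dt_ms = (distal.arrival_time - proximal.arrival_time) * 1000.0
    if dt_ms <= 0:
        raise ValueError("non-positive transit time: beats mis-matched")
    return dt_ms


def compute_pwv(pwtt_ms: float, sensor_distance: float | None) -> float | None:
    """Wave velocity in m/s: sensor distance over transit time.

    Returns ``None`` (not an error) when the distance is unknown.
    """
    if sensor_distance is None:
        return None
    if sensor_distance <= 0:
        raise ValueError("sensor_distance must be positive")
    if pwtt_ms <= 0:
        raise ValueError("pwtt must be positive")
    return sensor_distance / (pwtt_ms / 1000.0)


def build_pairs(
    proximal_beats: list[BeatAnnotation],
    distal_beats: list[BeatAnnotation],
    sensor_distance: float | None = None,
    max_lag: float = DEFAULT_MAX_LAG,
    pwtt_bounds: tuple[float, float] = DEFAULT_PWTT_BOUNDS,
) -> tuple[list[BeatPair], int]:
    """Match, compute transit times, apply plausibility bounds.

    Returns the accepted pairs and the count of matched pairs rejected for
    a transit time outside ``pwtt_bounds`` (mirrors manual exclusion of
    implausible beats).
    """
    lo, hi = pwtt_bounds
    pairs: list[BeatPair] = []
    rejected = 0
    for p, d in match_beats(proximal_beats, distal_beats, max_lag):
        try:
            pwtt = compute_pwtt(p, d)
        except ValueError:
            rejected += 1
            continue
        if not lo <= pwtt <= hi:
            rejected += 1
            continue
        pairs.append(BeatPair(p, d, pwtt, compute_pwv(pwtt, sensor_distance)))
    return pairs, rejected


def pairs_to_frame(pairs: list[BeatPair], pressure_source: str = "distal") -> pd.DataFrame:
    """Pair table: transit time, velocity and the per-beat pressures.

    ``pressure_source`` selects which channel's sPAP/mPAP/dPAP accompany
    each pair (default distal).
    """
    if pressure_source not in ("proximal", "distal"):
        raise ValueError("pressure_source must be 'proximal' or 'distal'")
    rows = []
    for pair in pairs:
        src = pair.distal if pressure_source == "distal" else pair.proximal
        rows.append(
            {
                "beat_idx": pair.proximal.beat_index,
                "t_prox_s": pair.proximal.arrival_time,
                "t_dist_s": pair.distal.arrival_time,
                "pwtt_ms": pair.pwtt,
                "pwv_mps": pair.pwv if pair.pwv is not None else np.nan,
                "spap": src.spap,
                "mpap": src.mpap,
                "dpap": src.dpap,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "beat_idx",
            "t_prox_s",
            "t_dist_s",
            "pwtt_ms",
            "pwv_mps",
            "spap",
            "mpap",
            "dpap",
        ],
    )
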