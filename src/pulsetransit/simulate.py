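"""Synthetic paired-site pulmonary artery pressure waveforms with ground truth.

The generator renders a train of stereotyped beats on two channels. Each
beat is a raised-cosine systolic upstroke followed by an exponential
diastolic decay whose time constant is chosen so the pressure lands exactly
on the next beat's diastolic level (C0-continuous train). The distal
channel renders the same beat foot-aligned at the proximal foot plus the
per-beat true transit time, with the pulse amplitude scaled by a
site-amplification factor. The true transit time follows a linear law in
systolic pressure, ``PWTT = a - b * sPAP`` (ms), plus Gaussian jitter,
clipped below at 5 ms.

Because the per-beat foot times, transit times and pressures are known
exactly, every downstream stage (filtering, foot detection, beat matching,
regression) can be validated against ground truth without any recorded
data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .recording import PressureRecording, write_recording_csv

__all__ = [
    "beat_waveform",
    "simulate_experiment",
    "SimulatedExperiment",
    "write_truth_csv",
]

#: floor on the true transit time, ms
MIN_TRUE_PWTT_MS = 5.0

#: premature beats arrive after 0.6x the running-mean RR interval
PREMATURE_RR_FRACTION = 0.6

#: premature beats lose 30% of their pulse amplitude
PREMATURE_AMPLITUDE_FACTOR = 0.7

TRUTH_COLUMNS = [
    "beat_idx",
    "t_foot_prox_s",
    "t_foot_dist_s",
    "pwtt_ms",
    "spap_mmHg",
    "mpap_mmHg",
    "dpap_mmHg",
    "premature",
]


@dataclass
class SimulatedExperiment:
    """A synthetic recording together with its per-beat ground truth.

    ``truth`` has one row per simulated beat with columns
    ``beat_idx, t_foot_prox_s, t_foot_dist_s, pwtt_ms, spap_mmHg,
    mpap_mmHg, dpap_mmHg, premature``. The distal foot time equals the
    proximal foot time plus the true transit time exactly (before sampling
    discretisation).
    """

    recording: PressureRecording
    truth: pd.DataFrame
    config: SimulationConfig


def _beat_values(
    tt: np.ndarray,
    p_dia: float,
    p_sys: float,
    rise_time: float,
    interval: float,
    p_dia_next: float,
) -> np.ndarray:
    """Evaluate the continuous beat template at times ``tt`` (s from foot).

    Raised cosine from ``p_dia`` to ``p_sys`` over ``rise_time``; then
    exponential decay reaching ``p_dia_next`` exactly at ``interval``.
    """
    tt = np.asarray(tt, dtype=float)
    amplitude = p_sys - p_dia
    out = np.empty_like(tt)
    rising = tt < rise_time
    if amplitude <= 1e-12:
        return np.full_like(tt, p_dia)
    out[rising] = p_dia + 0.5 * amplitude * (1.0 - np.cos(np.pi * tt[rising] / rise_time))
    decay = ~rising
    if np.any(decay):
        span = interval - rise_time
        ratio = p_sys / p_dia_next
        if abs(np.log(ratio)) < 1e-12:
            out[decay] = p_sys
        else:
            tau = span / np.log(ratio)
            out[decay] = p_sys * np.exp(-(tt[decay] - rise_time) / tau)
    return out


def beat_waveform(
    p_dia: float,
    p_sys: float,
    rise_time: float,
    interval: float,
    sampling_rate: float,
    p_dia_next: float | None = None,
) -> np.ndarray:
    """Render one beat template on the sample grid.

    Parameters
    ----------
    p_dia, p_sys : float
        Diastolic and systolic pressure of this beat, mmHg.
    rise_time : float
        Upstroke duration, seconds.
    interval : float
        Beat duration (this foot to the next), seconds.
    sampling_rate : float
        Hz.
    p_dia_next : float, optional
        Diastolic pressure the decay must reach at ``interval``; defaults
        to ``p_dia`` (stationary train).

    Returns
    -------
    ndarray
        ``round(interval * sampling_rate)`` samples; the first sample
        equals ``p_dia``.
    """
    if p_dia <= 0 or p_sys <= 0:
        raise ValueError("pressures must be positive")
    if p_dia > p_sys:
        raise ValueError("p_dia must not exceed p_sys")
    if not 0 < rise_time < interval:
        raise ValueError("need 0 < rise_time < interval")
    if p_dia_next is None:
        p_dia_next = p_dia
    if p_dia_next <= 0:
        raise ValueError("p_dia_next must be positive")
    n = int(round(interval * sampling_rate))
    tt = np.arange(n) / sampling_rate
    return _beat_values(tt, p_dia, p_sys, rise_time, interval, p_dia_next)


def _ramp_fraction(u: np.ndarray, shape: str) -> np.ndarray:
    """Pressure-trajectory shape: fraction of (target - baseline) applied.

    ``linear`` ramps monotonically across the whole recording (drug
    infusion); ``plateau`` rises to the target, holds it, and returns
    (transient hypoxic episode).
    """
    if shape == "linear":
        return np.asarray(u, dtype=float)
    # plateau: baseline 15%, rise 15%, hold 45%, fall 15%, baseline 10%
    return np.interp(u, [0.0, 0.15, 0.30, 0.75, 0.90, 1.0], [0.0, 0.0, 1.0, 1.0, 0.0, 0.0])


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate one two-channel recording with per-beat ground truth.

    Beat-to-beat RR intervals are lognormal with the configured mean and
    coefficient of variation. Premature beats (probability
    ``premature_prob`` per beat) arrive after 0.6x the running-mean RR and
    carry 30% less pulse amplitude. Per-beat systolic/diastolic endpoint
    pressures follow the configured ramp plus independent Gaussian jitter;
    the true transit time is ``pwtt_intercept_a - pwtt_slope_b * sPAP_i``
    plus jitter, clipped at 5 ms. White measurement noise is added per
    channel after the ground truth is extracted. Identical configs
    (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    duration = config.duration
    mean_rr = 60.0 / config.heart_rate_mean

    # lognormal RR with the requested mean and CV
    sigma2 = np.log1p(config.heart_rate_cv**2)
    mu = np.log(mean_rr) - 0.5 * sigma2
    sigma = np.sqrt(sigma2)

    # A premature beat arrives early: the RR interval *preceding* it is
    # shortened to 0.6x the running mean, so the flag sits on the beat whose
    # rr_interval the detection-side rule will see as short.
    lead_in = 0.8  # flat diastole before the first foot, s
    foot_times: list[float] = [lead_in]
    premature: list[bool] = [False]
    normal_rrs: list[float] = []
    while True:
        is_prem = bool(rng.random() < config.premature_prob)
        if config.heart_rate_cv > 0:
            rr = float(rng.lognormal(mu, sigma))
        else:
            rr = mean_rr
        if is_prem:
            running = np.mean(normal_rrs) if normal_rrs else mean_rr
            rr = PREMATURE_RR_FRACTION * float(running)
        else:
            normal_rrs.append(rr)
        t_next = foot_times[-1] + rr
        if t_next + 1.2 * mean_rr > duration:
            break
        foot_times.append(t_next)
        premature.append(is_prem)
    n_beats = len(foot_times)
    if n_beats < 3:
        raise ValueError(
            f"duration {duration} s holds only {n_beats} beats; need at least 3"
        )
    foot = np.asarray(foot_times)
    prem = np.asarray(premature)

    # per-beat endpoint pressures along the ramp
    u = foot / duration
    g = _ramp_fraction(u, config.ramp_shape)
    sys_p = config.baseline_sPAP + (config.target_sPAP - config.baseline_sPAP) * g
    dia_p = config.baseline_dPAP + (config.target_dPAP - config.baseline_dPAP) * g
    if config.pressure_jitter_sd > 0:
        sys_p = sys_p + rng.normal(0.0, config.pressure_jitter_sd, n_beats)
        dia_p = dia_p + rng.normal(0.0, config.pressure_jitter_sd, n_beats)
    dia_p = np.clip(dia_p, 1.0, sys_p - 2.0)

    # premature beats lose pulse amplitude
    sys_p = np.where(prem, dia_p + PREMATURE_AMPLITUDE_FACTOR * (sys_p - dia_p), sys_p)

    # true transit time law (ms), driven by systolic pressure
    pwtt_ms = config.pwtt_intercept_a - config.pwtt_slope_b * sys_p
    if config.pwtt_jitter_sd > 0:
        pwtt_ms = pwtt_ms + rng.normal(0.0, config.pwtt_jitter_sd, n_beats)
    pwtt_ms = np.maximum(pwtt_ms, MIN_TRUE_PWTT_MS)

    rise = config.rise_time / 1000.0
    n_samples = int(round(duration * fs))
    times = np.arange(n_samples) / fs

    def render(feet: np.ndarray, sys_arr: np.ndarray, dia_arr: np.ndarray) -> np.ndarray:
        chan = np.full(n_samples, dia_arr[0])
        for i in range(n_beats):
            t0 = feet[i]
            t1 = feet[i + 1] if i + 1 < n_beats else duration
            interval = t1 - t0
            if interval <= rise:
                continue  # pathological overlap; keep previous samples
            k0 = int(np.ceil(t0 * fs))
            k1 = n_samples if i + 1 == n_beats else int(np.ceil(t1 * fs))
            p_next = dia_arr[i + 1] if i + 1 < n_beats else dia_arr[i]
            chan[k0:k1] = _beat_values(
                times[k0:k1] - t0, dia_arr[i], sys_arr[i], rise, interval, p_next
            )
        return chan

    prox = render(foot, sys_p, dia_p)
    dist_foot = foot + pwtt_ms / 1000.0
    amp = config.distal_pulse_amplification
    sys_dist = dia_p + amp * (sys_p - dia_p)
    dist = render(dist_foot, sys_dist, dia_p)

    # ground-truth mean pressure: time average of the noiseless proximal beat
    mpap = np.empty(n_beats)
    for i in range(n_beats):
        k0 = int(np.ceil(foot[i] * fs))
        k1 = n_samples if i + 1 == n_beats else int(np.ceil(foot[i + 1] * fs))
        mpap[i] = prox[k0:k1].mean() if k1 > k0 else dia_p[i]

    if config.noise_sd > 0:
        prox = prox + rng.normal(0.0, config.noise_sd, n_samples)
        dist = dist + rng.normal(0.0, config.noise_sd, n_samples)

    truth = pd.DataFrame(
        {
            "beat_idx": np.arange(n_beats),
            "t_foot_prox_s": foot,
            "t_foot_dist_s": dist_foot,
            "pwtt_ms": pwtt_ms,
            "spap_mmHg": sys_p,
            "mpap_mmHg": mpap,
            "dpap_mmHg": dia_p,
            "premature": prem,
        }
    )
    recording = PressureRecording(
        proximal=prox,
        distal=dist,
        sampling_rate=fs,
        animal_id=f"sim-{config.seed}",
        condition="synthetic",
        sensor_distance=config.sensor_distance,
    )
    return SimulatedExperiment(recording=recording, truth=truth, config=config)


def write_truth_csv(experiment: SimulatedExperiment, path: str | Path) -> None:
    """Write the per-beat ground-truth table as CSV."""
    experiment.truth.to_csv(path, index=False, float_format="%.6f")


def write_experiment(
    experiment: SimulatedExperiment, recording_path: str | Path, truth_path: str | Path
) -> None:
    """Write recording and truth table side by side."""
    write_recording_csv(experiment.recording, recording_path)
    write_truth_csv(experiment, truth_path)
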