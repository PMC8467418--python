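"""Simulation configuration: the knobs of the synthetic dual-site recording.

A :class:`SimulationConfig` fully determines one synthetic experiment
(waveform morphology, pressure trajectory, transit-time law, noise and
arrhythmia model, and the random seed). Configs round-trip through flat
YAML files whose keys mirror the field names.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["SimulationConfig", "load_config", "save_config"]

_RAMP_SHAPES = ("linear", "plateau")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic paired-site pressure recording.

    Pressures are in mmHg, times in the units stated per field. The
    transit-time law is linear in systolic pressure:
    ``PWTT_i = pwtt_intercept_a - pwtt_slope_b * sPAP_i + jitter``,
    clipped below at 5 ms.

    Parameters
    ----------
    sampling_rate : float
        Samples per second for both channels (Hz).
    duration : float
        Recording length in seconds.
    heart_rate_mean : float
        Mean heart rate in beats per minute.
    heart_rate_cv : float
        Coefficient of variation of the lognormal RR-interval distribution.
    baseline_sPAP, baseline_dPAP : float
        Systolic/diastolic pressures at the start of the recording (mmHg).
    target_sPAP, target_dPAP : float
        Pressures at the ramp endpoint (mmHg); equal to baseline for a
        stationary recording.
    ramp_shape : str
        ``"linear"`` — pressures ramp linearly over the whole recording
        (drug-infusion scenario); ``"plateau"`` — baseline, linear rise,
        sustained plateau at target, return to baseline (hypoxic-episode
        scenario).
    pwtt_intercept_a : float
        Intercept of the transit-time law (ms).
    pwtt_slope_b : float
        Slope of the transit-time law (ms per mmHg of systolic pressure),
        entered as a positive number (transit time falls as pressure rises).
    pwtt_jitter_sd : float
        SD of per-beat Gaussian jitter on the true transit time (ms).
    pressure_jitter_sd : float
        SD of independent per-beat Gaussian jitter applied to the systolic
        and diastolic endpoint pressures (mmHg). Decorrelates the systolic
        and diastolic trajectories the way beat-to-beat physiology does.
    noise_sd : float
        SD of additive white measurement noise per channel (mmHg).
    distal_pulse_amplification : float
        Multiplier on the distal pulse amplitude (systolic minus diastolic);
        the diastolic level is shared between sites.
    premature_prob : float
        Per-beat probability of a premature (ectopic) beat: RR shortened to
        0.6x the running-mean RR, pulse amplitude reduced by 30%.
    rise_time : float
        Systolic upstroke duration in milliseconds.
    sensor_distance : float or None
        Separation of the two sensors in metres; ``None`` when unknown
        (velocity then stays unreported).
    seed : int
        Seed of the generator's random stream.
    """

    sampling_rate: float = 10_000.0
    duration: float = 60.0
    heart_rate_mean: float = 90.0
    heart_rate_cv: float = 0.03
    baseline_sPAP: float = 28.7
    baseline_dPAP: float = 15.0
    target_sPAP: float = 43.7
    target_dPAP: float = 21.8
    ramp_shape: str = "linear"
    pwtt_intercept_a: float = 70.945
    pwtt_slope_b: float = 0.481
    pwtt_jitter_sd: float = 1.5
    pressure_jitter_sd: float = 0.8
    noise_sd: float = 0.5
    distal_pulse_amplification: float = 0.9
    premature_prob: float = 0.0
    rise_time: float = 80.0
    sensor_distance: float | None = 0.11
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.heart_rate_mean <= 0:
            raise ValueError("heart_rate_mean must be positive")
        if self.heart_rate_cv < 0:
            raise ValueError("heart_rate_cv must be non-negative")
        for lo, hi, tag in (
            (self.baseline_dPAP, self.baseline_sPAP, "baseline"),
            (self.target_dPAP, self.target_sPAP, "target"),
        ):
            if not 0 < lo < hi:
                raise ValueError(
                    f"need 0 < {tag}_dPAP < {tag}_sPAP, got {lo} and {hi}"
                )
        if self.ramp_shape not in _RAMP_SHAPES:
            raise ValueError(f"ramp_shape must be one of {_RAMP_SHAPES}")
        if self.rise_time <= 0 or self.rise_time >= 60_000.0 / self.heart_rate_mean:
            raise ValueError("rise_time must lie in (0, mean beat interval)")
        if self.pwtt_slope_b < 0:
            raise ValueError("pwtt_slope_b must be non-negative")
        if not 0.0 <= self.premature_prob <= 1.0:
            raise ValueError("premature_prob must lie in [0, 1]")
        if self.pwtt_jitter_sd < 0 or self.noise_sd < 0 or self.pressure_jitter_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.distal_pulse_amplification <= 0:
            raise ValueError("distal_pulse_amplification must be positive")
        if self.sensor_distance is not None and self.sensor_distance <= 0:
            raise ValueError("sensor_distance must be positive or None")

    def replace(self, **changes) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a flat YAML mapping of field name -> value."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**raw)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
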