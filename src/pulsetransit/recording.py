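"""Synchronised two-site pressure recording container and its CSV dialect.

The on-disk format is deliberately plain: a header line
``time_s,proximal_mmHg,distal_mmHg`` followed by one row per sample,
'.' decimal separator. Everything downstream (filtering, foot detection,
beat matching) consumes the in-memory container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PressureRecording", "read_recording_csv", "write_recording_csv"]

_CONDITIONS = ("baseline", "TXA", "hypoxia", "synthetic")


@dataclass
class PressureRecording:
    """Two synchronously sampled pressure channels.

    Attributes
    ----------
    proximal, distal : ndarray
        Pressure samples in mmHg, equal length.
    sampling_rate : float
        Hz.
    animal_id : str
        Subject label.
    condition : str
        One of ``baseline``, ``TXA``, ``hypoxia``, ``synthetic``.
    sensor_distance : float or None
        Sensor separation in metres, if measured.
    """

    proximal: np.ndarray
    distal: np.ndarray
    sampling_rate: float
    animal_id: str = "unknown"
    condition: str = "synthetic"
    sensor_distance: float | None = None

    def __post_init__(self) -> None:
        self.proximal = np.asarray(self.proximal, dtype=float)
        self.distal = np.asarray(self.distal, dtype=float)
        if self.proximal.ndim != 1 or self.distal.ndim != 1:
            raise ValueError("channels must be one-dimensional")
        if self.proximal.shape != self.distal.shape:
            raise ValueError("proximal and distal channels differ in length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not (np.isfinite(self.proximal).all() and np.isfinite(self.distal).all()):
            raise ValueError("pressure samples must be finite")
        if self.condition not in _CONDITIONS:
            raise ValueError(f"condition must be one of {_CONDITIONS}")

    @property
    def n_samples(self) -> int:
        return self.proximal.size

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds (first sample at t = 0)."""
        return np.arange(self.n_samples) / self.sampling_rate


def write_recording_csv(recording: PressureRecording, path: str | Path) -> None:
    """Write ``time_s, proximal_mmHg, distal_mmHg`` with a header row."""
    df = pd.DataFrame(
        {
            "time_s": recording.times(),
            "proximal_mmHg": recording.proximal,
            "distal_mmHg": recording.distal,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_recording_csv(
    path: str | Path,
    sampling_rate: float | None = None,
    animal_id: str = "unknown",
    condition: str = "synthetic",
    sensor_distance: float | None = None,
) -> PressureRecording:
    """Read the recording dialect written by :func:`write_recording_csv`.

    The sampling rate is inferred from the ``time_s`` column (median step)
    unless given explicitly.
    """
    df = pd.read_csv(path)
    required = {"time_s", "proximal_mmHg", "distal_mmHg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"recording file {path} lacks columns {sorted(missing)}")
    if sampling_rate is None:
        steps = np.diff(df["time_s"].to_numpy())
        if steps.size == 0 or np.median(steps) <= 0:
            raise ValueError("cannot infer sampling rate from time column")
        sampling_rate = 1.0 / float(np.median(steps))
    return PressureRecording(
        proximal=df["proximal_mmHg"].to_numpy(),
        distal=df["distal_mmHg"].to_numpy(),
        sampling_rate=sampling_rate,
        animal_id=animal_id,
        condition=condition,
        sensor_distance=sensor_distance,
    )
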