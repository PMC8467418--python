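"""Quick-look plots for recordings, tangent construction and fits."""

from __future__ import annotations

import numpy as np

from .recording import PressureRecording
from .stats import TransitPressureResults

__all__ = ["plot_recording", "plot_regression", "plot_pwv_pressure"]


def _require_axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_recording(
    recording: PressureRecording,
    start: float = 0.0,
    stop: float | None = None,
    ax=None,
):
    """Overlay the proximal and distal pressure traces over a time window."""
    ax = _require_axes(ax)
    t = recording.times()
    stop = recording.duration if stop is None else stop
    sel = (t >= start) & (t <= stop)
    ax.plot(t[sel], recording.proximal[sel], lw=0.8, label="proximal")
    ax.plot(t[sel], recording.distal[sel], lw=0.8, label="distal")
    ax.set_xlabel("time [s]")
    ax.set_ylabel("pressure [mmHg]")
    ax.set_title(f"{recording.animal_id} ({recording.condition})")
    ax.legend(frameon=False)
    return ax


def plot_regression(
    results: TransitPressureResults,
    pwtt: np.ndarray,
    pressure: np.ndarray,
    ax=None,
):
    """Scatter of transit time vs pressure with the fitted line."""
    ax = _require_axes(ax)
    ax.plot(pressure, pwtt, ".", ms=2, alpha=0.4)
    grid = np.linspace(np.nanmin(pressure), np.nanmax(pressure), 50)
    ax.plot(grid, results.predict(grid), "k-", lw=1.5)
    ax.set_xlabel(f"{results.pressure_type} [mmHg]")
    ax.set_ylabel("PWTT [ms]")
    ax.set_title(
        f"{results.animal_id or 'fit'}: r = {results.r:.3f}, n = {results.n}"
    )
    return ax


def plot_pwv_pressure(pairs, pressure_type: str = "sPAP", ax=None):
    """Wave velocity against pressure (hyperbolic at fixed distance)."""
    ax = _require_axes(ax)
    col = {"sPAP": "spap", "mPAP": "mpap", "dPAP": "dpap"}[pressure_type]
    ax.plot(pairs[col], pairs["pwv_mps"], ".", ms=3, alpha=0.5)
    ax.set_xlabel(f"{pressure_type} [mmHg]")
    ax.set_ylabel("PWV [m/s]")
    return ax
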