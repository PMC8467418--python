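"""Bundled reference numbers and the default synthetic cohort.

``load_published_regressions`` returns the per-animal linear-regression
summary statistics (intercept, slope, r^2, F, n) reported by the invasive
porcine pulmonary-hypertension validation study whose processing chain
this package reimplements: six animals under thromboxane-analogue-induced
PH and five under hypoxic vasoconstriction, transit time regressed on
each of systolic/mean/diastolic pressure. These summaries are inputs
(e.g. for Fisher-z pooling); the underlying beat-level recordings were
never deposited, which is why the synthetic cohort below exists.

``default_txa_cohort`` builds six simulation configs whose per-animal
baseline/peak pressures and transit-time coefficients are anchored to the
same study's reported animal-level values, so parameter-recovery tests
compare estimates against generating values in the published range.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .config import SimulationConfig

__all__ = [
    "load_published_regressions",
    "published_pooling_inputs",
    "default_txa_cohort",
    "ANOMALOUS_ROWS",
]

#: (group, animal, pressure_type) rows whose printed F is inconsistent with
#: the printed r^2 and n under F = r^2 (n-2)/(1-r^2); excluded from
#: consistency checks, taken as a transcription artifact in the source.
ANOMALOUS_ROWS = [("TXA", 4, "mPAP")]

# per-animal anchors for the default drug-infusion cohort:
# (baseline sPAP, baseline dPAP, peak sPAP, peak dPAP,
#  transit intercept a [ms], transit slope b [ms/mmHg], sensor distance [m])
_TXA_COHORT_ANCHORS = {
    "pig1": (42.5, 22.5, 60.4, 20.0, 70.945, 0.481, None),
    "pig2": (28.7, 15.9, 37.5, 21.6, 98.938, 1.298, 0.105),
    "pig3": (25.6, 11.9, 42.1, 22.3, 42.133, 0.646, 0.063),
    "pig4": (25.0, 12.6, 47.3, 21.3, 46.632, 0.683, 0.065),
    "pig5": (21.5, 9.3, 28.4, 16.3, 81.659, 2.047, 0.104),
    "pig6": (29.1, 18.6, 46.8, 29.5, 63.723, 0.972, 0.071),
}


def load_published_regressions() -> pd.DataFrame:
    """Published per-animal regression summaries (both treatment groups)."""
    path = resources.files("pulsetransit") / "data" / "porcine_ph_regressions.csv"
    with path.open() as fh:
        return pd.read_csv(fh)


def published_pooling_inputs(group: str) -> dict[str, list[tuple[float, int]]]:
    """Per-pressure-type (r, n) pairs for one group, ready for pooling.

    ``r`` is recovered as ``sqrt(r_squared)`` (all reported relationships
    are negative; pooling uses magnitudes).
    """
    df = load_published_regressions()
    sub = df[df["group"] == group]
    if sub.empty:
        raise ValueError(f"unknown group {group!r}")
    out: dict[str, list[tuple[float, int]]] = {}
    for pt in ("sPAP", "mPAP", "dPAP"):
        rows = sub[sub["pressure_type"] == pt]
        out[pt] = [
            (float(row.r_squared) ** 0.5, int(row.n_beats))
            for row in rows.itertuples()
        ]
    return out


def default_txa_cohort(
    seed: int = 0,
    duration: float = 240.0,
    premature_prob: float = 0.02,
    **overrides,
) -> dict[str, SimulationConfig]:
    """Six-animal drug-infusion cohort with animal-specific anchors.

    Each animal ramps linearly from its baseline to its peak pressures
    over ``duration`` seconds (~360 beats at the default 90 bpm) with the
    default noise levels (measurement noise 0.5 mmHg, transit jitter
    1.5 ms, endpoint-pressure jitter 0.8 mmHg). Animal seeds are derived
    deterministically from ``seed``.
    """
    cohort: dict[str, SimulationConfig] = {}
    for i, (animal, anchor) in enumerate(_TXA_COHORT_ANCHORS.items()):
        base_s, base_d, targ_s, targ_d, a, b, distance = anchor
        cohort[animal] = SimulationConfig(
            duration=duration,
            baseline_sPAP=base_s,
            baseline_dPAP=base_d,
            target_sPAP=targ_s,
            target_dPAP=targ_d,
            ramp_shape="linear",
            pwtt_intercept_a=a,
            pwtt_slope_b=b,
            premature_prob=premature_prob,
            sensor_distance=distance,
            seed=(seed * 1009 + i * 101) % (2**31 - 1),
            **overrides,
        )
    return cohort
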