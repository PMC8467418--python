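"""Statistics layer: per-animal regression, Fisher-z pooling, rmANOVA.

The core questions this layer answers, in order:

1. Within one animal, how strongly does transit time track each pressure
   (systolic/mean/diastolic)? — ordinary least squares of PWTT on
   pressure, with the F-test of the regression
   (``F = r^2 (n-2) / (1 - r^2)`` on 1 and n-2 degrees of freedom).
2. Across animals of a treatment group, what is the pooled correlation?
   — Fisher z-transform each animal's |r|, average (unweighted by
   default; (n-3)-weighted available), back-transform with tanh.
3. Do the three pressure types differ in how well they correlate?
   — one-way repeated-measures ANOVA on the variance-stabilised z values
   with animal as the repeated unit, plus Holm-corrected paired t
   contrasts.

The regression is exposed statsmodels-style: a
:class:`TransitPressureModel` built from arrays or a pair-table DataFrame,
whose :meth:`~TransitPressureModel.fit` returns a
:class:`TransitPressureResults` carrying estimates, the F/p diagnostics
and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TransitPressureModel",
    "TransitPressureResults",
    "RegressionResult",
    "fit_linear",
    "QuadraticComparison",
    "fit_quadratic_compare",
    "PooledCorrelation",
    "pool_correlations",
    "RmAnovaResult",
    "rm_anova",
    "CohortResults",
    "analyze_cohort",
]

PRESSURE_TYPES = ("sPAP", "mPAP", "dPAP")
_PRESSURE_COLUMNS = {"sPAP": "spap", "mPAP": "mpap", "dPAP": "dpap"}


@dataclass
class TransitPressureResults:
    """OLS fit of transit time on one pressure type for one animal.

    ``r`` carries the sign of the slope; ``F`` and ``p`` satisfy
    ``F = r^2 (n-2)/(1-r^2)`` and ``p = SF_F(1, n-2)(F)``. A perfect fit
    reports ``F = inf`` and ``p = 0``.
    """

    pressure_type: str
    intercept: float  # ms
    slope: float  # ms per mmHg
    r: float
    r_squared: float
    F: float
    p: float
    n: int
    animal_id: str = ""

    def predict(self, pressure: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(pressure, dtype=float)

    def summary(self) -> str:
        sign = "-" if self.slope < 0 else "+"
        eq = (
            f"PWTT = {self.intercept:.3f} {sign} "
            f"({abs(self.slope):.3f} * {self.pressure_type})"
        )
        lines = [
            "Transit-time vs pressure regression",
            "=" * 43,
            f"animal:        {self.animal_id or '-'}",
            f"pressure type: {self.pressure_type}",
            f"n beats:       {self.n}",
            f"equation:      {eq}",
            f"r:             {self.r:.4f}",
            f"r^2:           {self.r_squared:.4f}",
            f"F(1, {self.n - 2}):    {self.F:.3f}",
            f"p:             {self.p:.3g}",
        ]
        return "\n".join(lines)


# the per-animal regression record; alias kept for discoverability
RegressionResult = TransitPressureResults


class TransitPressureModel:
    """Simple linear model of transit time (ms) on one pressure (mmHg)."""

    def __init__(
        self,
        pwtt: np.ndarray,
        pressure: np.ndarray,
        pressure_type: str = "sPAP",
        animal_id: str = "",
    ) -> None:
        pwtt = np.asarray(pwtt, dtype=float)
        pressure = np.asarray(pressure, dtype=float)
        if pwtt.shape != pressure.shape or pwtt.ndim != 1:
            raise ValueError("pwtt and pressure must be equal-length 1-d arrays")
        mask = np.isfinite(pwtt) & np.isfinite(pressure)
        pwtt, pressure = pwtt[mask], pressure[mask]
        if pwtt.size < 3:
            raise ValueError("need at least 3 finite observations")
        if pressure_type not in PRESSURE_TYPES:
            raise ValueError(f"pressure_type must be one of {PRESSURE_TYPES}")
        self.pwtt = pwtt
        self.pressure = pressure
        self.pressure_type = pressure_type
        self.animal_id = animal_id

    @classmethod
    def from_pair_table(
        cls, pairs: pd.DataFrame, pressure_type: str = "sPAP", animal_id: str = ""
    ) -> "TransitPressureModel":
        """Build from a pair table with ``pwtt_ms`` and ``spap/mpap/dpap``."""
        col = _PRESSURE_COLUMNS[pressure_type]
        return cls(
            pairs["pwtt_ms"].to_numpy(),
            pairs[col].to_numpy(),
            pressure_type,
            animal_id,
        )

    def fit(self) -> TransitPressureResults:
        """Ordinary least squares with the regression F-test."""
        x, y = self.pressure, self.pwtt
        if np.ptp(x) == 0:
            raise ValueError("pressure has zero variance")
        res = sps.linregress(x, y)
        r = float(res.rvalue)
        r2 = r * r
        n = x.size
        if 1.0 - r2 < 1e-12:
            F, p = np.inf, 0.0
        else:
            F = r2 * (n - 2) / (1.0 - r2)
            p = float(sps.f.sf(F, 1, n - 2))
        return TransitPressureResults(
            pressure_type=self.pressure_type,
            intercept=float(res.intercept),
            slope=float(res.slope),
            r=r,
            r_squared=r2,
            F=float(F),
            p=p,
            n=n,
            animal_id=self.animal_id,
        )


def fit_linear(
    pwtt: np.ndarray,
    pressure: np.ndarray,
    pressure_type: str = "sPAP",
    animal_id: str = "",
) -> TransitPressureResults:
    """Convenience wrapper: build the model and fit it."""
    return TransitPressureModel(pwtt, pressure, pressure_type, animal_id).fit()


@dataclass
class QuadraticComparison:
    """Linear vs quadratic fit of transit time on pressure."""

    r2_linear: float
    r2_quadratic: float
    aic_linear: float
    aic_quadratic: float
    preferred: str  # "linear" | "quadratic"


def _poly_r2_aic(x: np.ndarray, y: np.ndarray, degree: int) -> tuple[float, float]:
    coef = np.polyfit(x, y, degree)
    resid = y - np.polyval(coef, x)
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    n = x.size
    k = degree + 2  # polynomial coefficients + error variance
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * k
    return r2, aic


def fit_quadratic_compare(pwtt: np.ndarray, pressure: np.ndarray) -> QuadraticComparison:
    """Compare degree-1 and degree-2 polynomial fits by AIC.

    Used to check whether the transit-pressure relationship shows
    reproducible curvature; the quadratic r^2 can never be below the
    linear one (nested models), so preference is decided by AIC.
    """
    x = np.asarray(pressure, dtype=float)
    y = np.asarray(pwtt, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 4:
        raise ValueError("need at least 4 observations for the quadratic fit")
    if np.ptp(x) == 0:
        raise ValueError("pressure has zero variance")
    r2_lin, aic_lin = _poly_r2_aic(x, y, 1)
    r2_quad, aic_quad = _poly_r2_aic(x, y, 2)
    return QuadraticComparison(
        r2_linear=r2_lin,
        r2_quadratic=r2_quad,
        aic_linear=aic_lin,
        aic_quadratic=aic_quad,
        preferred="linear" if aic_lin <= aic_quad else "quadratic",
    )


@dataclass
class PooledCorrelation:
    """Fisher-z pooled correlation across the animals of one group.

    ``dispersion`` is the sample SD of the per-animal |r| (descriptive
    only; labelled by ``dispersion_method``).
    """

    pressure_type: str
    per_animal_r: list[float]
    pooled_r: float
    dispersion: float
    method: str
    group: str = ""
    dispersion_method: str = "sd_of_r"


def _extract_r_n(item) -> tuple[float, int | None]:
    if isinstance(item, TransitPressureResults):
        return abs(item.r), item.n
    return abs(float(item)), None


def pool_correlations(
    results: Sequence,
    method: str = "unweighted_z_mean",
    pressure_type: str = "",
    group: str = "",
) -> PooledCorrelation:
    """Pool per-animal correlation magnitudes via Fisher's z-transform.

    Each animal contributes ``z = atanh(|r|)``; the pooled coefficient is
    ``tanh`` of the (optionally (n-3)-weighted) mean z. Accepts
    :class:`TransitPressureResults` or plain correlation values. With a
    single animal the pooled value equals that animal's |r|.
    """
    if method not in ("unweighted_z_mean", "nz_weighted_z_mean"):
        raise ValueError(f"unknown pooling method {method!r}")
    if len(results) == 0:
        raise ValueError("need at least one animal")
    rs, ns = [], []
    for item in results:
        r, n = _extract_r_n(item)
        if r >= 1.0:
            raise ValueError("|r| = 1 has infinite Fisher z; cannot pool")
        rs.append(r)
        ns.append(n)
    r_arr = np.asarray(rs)
    z = np.arctanh(r_arr)
    if method == "nz_weighted_z_mean":
        if any(n is None for n in ns):
            raise ValueError("sample sizes required for (n-3)-weighted pooling")
        w = np.asarray([n - 3 for n in ns], dtype=float)
        if np.any(w <= 0):
            raise ValueError("all sample sizes must exceed 3 for weighting")
        z_mean = float(np.average(z, weights=w))
    else:
        z_mean = float(z.mean())
    dispersion = float(np.std(r_arr, ddof=1)) if r_arr.size > 1 else 0.0
    return PooledCorrelation(
        pressure_type=pressure_type,
        per_animal_r=[float(r) for r in r_arr],
        pooled_r=float(np.tanh(z_mean)),
        dispersion=dispersion,
        method=method,
        group=group,
    )


@dataclass
class RmAnovaResult:
    """One-way repeated-measures ANOVA with Holm-corrected paired contrasts."""

    F: float
    df: tuple[int, int]
    p: float
    pairwise: list[tuple[str, float, float]]  # (contrast, t, corrected p)
    column_names: tuple[str, ...] = PRESSURE_TYPES

    def summary(self) -> str:
        lines = [
            "Repeated-measures ANOVA on Fisher-z correlations",
            "=" * 48,
            f"F({self.df[0]}, {self.df[1]}) = {self.F:.3f}, p = {self.p:.4g}",
            "pairwise (Holm-corrected):",
        ]
        for name, t, p in self.pairwise:
            lines.append(f"  {name}: t = {t:.3f}, p = {p:.4g}")
        return "\n".join(lines)


def rm_anova(
    z_matrix: np.ndarray, column_names: Sequence[str] = PRESSURE_TYPES
) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on an animals x conditions matrix.

    Rows are animals (the repeated unit), columns the conditions (the
    three pressure types' Fisher-z values). Sums of squares are
    partitioned into condition, subject and residual; the condition effect
    is tested on ``(k-1, (k-1)(n-1))`` degrees of freedom. All pairwise
    paired t-tests follow, Holm-corrected.
    """
    z = np.asarray(z_matrix, dtype=float)
    if z.ndim != 2:
        raise ValueError("z_matrix must be 2-d (animals x conditions)")
    n, k = z.shape
    if k != len(column_names):
        raise ValueError("column_names length must match the number of columns")
    if n < 3:
        raise ValueError("need at least 3 animals")
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if not np.isfinite(z).all():
        raise ValueError("z_matrix contains missing values; design must be complete")

    grand = z.mean()
    ss_cond = n * float(((z.mean(axis=0) - grand) ** 2).sum())
    ss_subj = k * float(((z.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((z - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_err = ss_err / df_err
    if ms_err <= 1e-300:
        F = 0.0 if ss_cond <= 1e-300 else np.inf
    else:
        F = (ss_cond / df_cond) / ms_err
    p = float(sps.f.sf(F, df_cond, df_err)) if np.isfinite(F) else 0.0

    contrasts = [(i, j) for i in range(k) for j in range(i + 1, k)]
    t_vals, p_raw, names = [], [], []
    for i, j in contrasts:
        t, pv = sps.ttest_rel(z[:, i], z[:, j])
        t_vals.append(float(t))
        p_raw.append(float(pv))
        names.append(f"{column_names[i]}-{column_names[j]}")
    _, p_corr, _, _ = multipletests(p_raw, method="holm")
    pairwise = list(zip(names, t_vals, [float(pc) for pc in p_corr]))
    return RmAnovaResult(
        F=float(F), df=(df_cond, df_err), p=p, pairwise=pairwise,
        column_names=tuple(column_names),
    )


@dataclass
class CohortResults:
    """Group-level results: per-animal fits, pooled correlations, ANOVA."""

    group: str
    per_animal: pd.DataFrame
    pooled: dict[str, PooledCorrelation]
    anova: RmAnovaResult | None

    def pooled_table(self) -> pd.DataFrame:
        rows = [
            {
                "group": self.group,
                "pressure_type": pt,
                "pooled_r": pc.pooled_r,
                "dispersion_sd_r": pc.dispersion,
                "method": pc.method,
                "n_animals": len(pc.per_animal_r),
            }
            for pt, pc in self.pooled.items()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Cohort '{self.group}': {self.per_animal['animal'].nunique()} animals"]
        for pt, pc in self.pooled.items():
            lines.append(
                f"  pooled |r| {pt}: {pc.pooled_r:.3f} (SD of r {pc.dispersion:.3f})"
            )
        if self.anova is not None:
            lines.append(self.anova.summary())
        return "\n".join(lines)


def analyze_cohort(
    pair_tables: Mapping[str, pd.DataFrame],
    group: str = "",
    pooling_method: str = "unweighted_z_mean",
) -> CohortResults:
    """Per-animal regressions for all pressure types, pooling, rmANOVA.

    ``pair_tables`` maps animal id to that animal's pair table. The ANOVA
    runs on the animals x pressure-types matrix of ``atanh(|r|)`` and is
    skipped (``None``) with fewer than 3 animals.
    """
    rows = []
    fits: dict[str, dict[str, TransitPressureResults]] = {}
    for animal, table in pair_tables.items():
        fits[animal] = {}
        for pt in PRESSURE_TYPES:
            res = TransitPressureModel.from_pair_table(table, pt, animal).fit()
            fits[animal][pt] = res
            rows.append(
                {
                    "animal": animal,
                    "pressure_type": pt,
                    "n": res.n,
                    "intercept": res.intercept,
                    "slope": res.slope,
                    "r": res.r,
                    "r_squared": res.r_squared,
                    "F": res.F,
                    "p": res.p,
                }
            )
    per_animal = pd.DataFrame(rows)
    pooled = {
        pt: pool_correlations(
            [fits[a][pt] for a in fits], pooling_method, pressure_type=pt, group=group
        )
        for pt in PRESSURE_TYPES
    }
    anova = None
    if len(fits) >= 3:
        z = np.array(
            [[np.arctanh(abs(fits[a][pt].r)) for pt in PRESSURE_TYPES] for a in fits]
        )
        anova = rm_anova(z, PRESSURE_TYPES)
    return CohortResults(group=group, per_animal=per_animal, pooled=pooled, anova=anova)
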