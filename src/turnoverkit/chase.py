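"""Half-life estimation from synthesis shut-off (chloramphenicol chase) assays.

After translation is blocked, a protein degraded with first-order kinetics
decays as P(t) = P(0) * 2^(-t / t_half). Band intensities from the chase are
normalised to the t = 0 sample per replicate and fitted on the log2 scale by
ordinary least squares across pooled replicates, the standard densitometry
practice: the fit is exact on noise-free data and the half-life is -1/slope.

A protein that shows no significant decay over the chase is reported as
censored — the half-life is a lower bound equal to the chase duration
(e.g. "> 120 min"), never a number extrapolated beyond the data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChaseCourse",
    "HalfLifeEstimate",
    "HalfLifeDifference",
    "normalize_chase",
    "estimate_halflife",
    "compare_halflives",
]

logger = logging.getLogger(__name__)

_COLUMNS = ("replicate", "time_min", "intensity")


@dataclass(frozen=True)
class ChaseCourse:
    """Tidy chase time course: one band intensity per (replicate, time)."""

    data: pd.DataFrame
    condition: str = ""

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"chase table is missing columns {missing}")
        n_bad = int((df["intensity"] <= 0).sum())
        if n_bad:
            logger.warning(
                "dropping %d non-positive intensities from chase '%s'", n_bad, self.condition
            )
            df = df[df["intensity"] > 0]
        df = df.sort_values(["replicate", "time_min"]).reset_index(drop=True)
        for rep, grp in df.groupby("replicate"):
            t = grp["time_min"].to_numpy(dtype=float)
            if t[0] != 0:
                raise ValueError(f"replicate {rep!r} has no t = 0 sample")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"replicate {rep!r} times are not strictly increasing")
            if len(t) < 3:
                raise ValueError(f"replicate {rep!r} has fewer than 3 usable time points")
        object.__setattr__(self, "data", df)

    @classmethod
    def from_arrays(cls, times, intensities, condition: str = "", replicate=1) -> "ChaseCourse":
        """Single-replicate convenience constructor."""
        return cls(
            pd.DataFrame(
                {"replicate": replicate, "time_min": np.asarray(times, float),
                 "intensity": np.asarray(intensities, float)}
            ),
            condition=condition,
        )

    @property
    def duration(self) -> float:
        return float(self.data["time_min"].max())


@dataclass(frozen=True)
class HalfLifeEstimate:
    """Fitted half-life with a two-sided 95% CI; censored when no decay is seen.

    When ``censored`` is true the half-life is a lower bound equal to
    ``censor_bound`` (the chase duration) and should be read as
    "> censor_bound minutes".
    """

    halflife: float
    ci: tuple[float, float]
    censored: bool
    censor_bound: float
    slope: float  # log2 intensity per minute
    slope_se: float
    n_points: int
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.halflife > 0:
            raise ValueError("half-life must be positive")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.censored:
            return f"> {self.censor_bound:g} min (censored)"
        return f"{self.halflife:.3g} min (95% CI {self.ci[0]:.3g}-{self.ci[1]:.3g})"


def normalize_chase(course: ChaseCourse) -> ChaseCourse:
    """Divide each replicate by its own t = 0 intensity.

    Idempotent; errors if any replicate lacks a positive t = 0 sample (the
    constructor already guarantees both).
    """
    df = course.data.copy()
    for rep, grp in df.groupby("replicate"):
        ref = grp.loc[grp["time_min"] == 0, "intensity"]
        if ref.empty or ref.iloc[0] <= 0:
            raise ValueError(f"replicate {rep!r}: missing or non-positive t = 0 intensity")
        df.loc[grp.index, "intensity"] = grp["intensity"] / ref.iloc[0]
    return ChaseCourse(df, condition=course.condition)


def estimate_halflife(course: ChaseCourse, alpha: float = 0.05) -> HalfLifeEstimate:
    """Pooled log-linear half-life estimate from a chase course.

    Replicates are normalised to t = 0, stacked, and log2(intensity) is
    regressed on time. halflife = -1/slope. The estimate is censored when the
    one-sided test for a negative slope is not significant at ``alpha`` or
    when the fitted half-life exceeds the chase duration; censored estimates
    report the chase duration as a lower bound.
    """
    norm = normalize_chase(course)
    t = norm.data["time_min"].to_numpy(dtype=float)
    y = np.log2(norm.data["intensity"].to_numpy(dtype=float))
    if len(t) < 3:
        raise ValueError("need at least 3 points to estimate a half-life")
    duration = norm.duration

    if np.ptp(y) == 0.0:
        # perfectly flat course: no decay information at all
        return HalfLifeEstimate(
            halflife=duration, ci=(duration, math.inf), censored=True,
            censor_bound=duration, slope=0.0, slope_se=0.0, n_points=len(t),
            condition=course.condition,
        )

    fit = stats.linregress(t, y)
    slope, se = fit.slope, fit.stderr
    dof = len(t) - 2
    # one-sided p-value for H1: slope < 0
    p_one = fit.pvalue / 2 if slope < 0 else 1 - fit.pvalue / 2
    tcrit = stats.t.ppf(1 - alpha / 2, dof) if dof > 0 else math.inf
    lo_slope, hi_slope = slope - tcrit * se, slope + tcrit * se

    if slope >= 0 or p_one > alpha:
        return HalfLifeEstimate(
            halflife=duration, ci=(duration, math.inf), censored=True,
            censor_bound=duration, slope=slope, slope_se=se, n_points=len(t),
            condition=course.condition,
        )

    halflife = -1.0 / slope
    ci_lo = -1.0 / lo_slope  # steepest plausible slope -> shortest half-life
    ci_hi = -1.0 / hi_slope if hi_slope < 0 else math.inf
    if halflife > duration:
        return HalfLifeEstimate(
            halflife=duration, ci=(max(ci_lo, 0.0), math.inf), censored=True,
            censor_bound=duration, slope=slope, slope_se=se, n_points=len(t),
            condition=course.condition,
        )
    return HalfLifeEstimate(
        halflife=halflife, ci=(ci_lo, ci_hi), censored=False, censor_bound=duration,
        slope=slope, slope_se=se, n_points=len(t), condition=course.condition,
    )


@dataclass(frozen=True)
class HalfLifeDifference:
    """Difference between two half-life estimates, in minutes."""

    difference: float | None
    ci: tuple[float, float] | None
    bound_only: bool
    note: str = ""


def compare_halflives(
    est_a: HalfLifeEstimate, est_b: HalfLifeEstimate, alpha: float = 0.05
) -> HalfLifeDifference:
    """Point difference est_a - est_b with an interval propagated from the fits.

    Var(t_half) = (se_slope / slope^2)^2 by the delta method on -1/slope.
    If either estimate is censored only a bound can be stated.
    """
    if est_a.censored or est_b.censored:
        lower = (est_a.censor_bound if est_a.censored else est_a.halflife) - (
            est_b.halflife if not est_b.censored else est_b.censor_bound
        )
        return HalfLifeDifference(
            difference=None, ci=None, bound_only=True,
            note=f"censored input; difference bounded by {lower:.3g} min on one side",
        )
    diff = est_a.halflife - est_b.halflife
    se = math.hypot(est_a.slope_se / est_a.slope**2, est_b.slope_se / est_b.slope**2)
    z = stats.norm.ppf(1 - alpha / 2)
    return HalfLifeDifference(difference=diff, ci=(diff - z * se, diff + z * se), bound_only=False)
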