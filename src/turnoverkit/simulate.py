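"""Synthetic study data: growth curves, abundance courses, chases and Ct tables.

Every input the analysis consumes can be generated here under known ground
truth, so each stage — and the pipeline end to end — is testable by parameter
recovery. The emulated measurements:

* culture growth: logistic OD600(t) anchored to OD 0.4 at t = 0, OD 1.0 at
  160 min and a stationary plateau near OD 1.5;
* band densitometry: relative protein abundance from the forward turnover
  solver (optionally under a time-varying, piecewise-constant synthesis
  profile) with multiplicative lognormal noise per replicate;
* chase assays: first-order decays 2^(-t/t_half) with the same noise model;
* qPCR: Ct tables where the target Ct encodes log2 relative expression over
  a constant reference gene, with cycle-scale Gaussian jitter.

All randomness flows through a seeded generator: identical settings and
seed produce identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chase import ChaseCourse
from .model import (
    DegradationSchedule,
    TimeOdMap,
    TurnoverModel,
    _segment_step,
    analytic_trajectory,
)
from .qpcr import CtTable
from .synthesis import AbundanceSeries

__all__ = [
    "GrowthModel",
    "NoiseSpec",
    "KsProfile",
    "generate_growth_curve",
    "solve_piecewise_abundance",
    "generate_abundance_course",
    "generate_chase_course",
    "generate_ct_table",
    "linear_decline_profile",
]

#: logistic growth constant (per minute) that carries OD 0.4 to OD 1.0 in
#: 160 min with carrying capacity 1.5: r = ln(5.5)/160
DEFAULT_GROWTH_RATE = math.log(5.5) / 160.0


@dataclass(frozen=True)
class GrowthModel:
    """Logistic culture growth OD(t) = K / (1 + ((K - od0)/od0) e^(-r t))."""

    od0: float = 0.4
    K: float = 1.5
    r: float = DEFAULT_GROWTH_RATE

    def __post_init__(self) -> None:
        if not 0 < self.od0 < self.K:
            raise ValueError("need 0 < od0 < K")
        if not self.r > 0:
            raise ValueError("growth constant must be positive")

    def od(self, t):
        t = np.asarray(t, dtype=float)
        b = (self.K - self.od0) / self.od0
        return self.K / (1.0 + b * np.exp(-self.r * t))

    @classmethod
    def from_anchor(cls, od0: float, K: float, t_anchor: float, od_anchor: float) -> "GrowthModel":
        """Solve the growth constant so OD(t_anchor) = od_anchor."""
        if not od0 < od_anchor < K:
            raise ValueError("anchor OD must lie strictly between od0 and K")
        b = (K - od0) / od0
        r = math.log(b * od_anchor / (K - od_anchor)) / t_anchor
        return cls(od0=od0, K=K, r=r)


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative lognormal noise of a given CV, with an explicit seed."""

    cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.cv >= 1:
            import logging
            logging.getLogger(__name__).warning(
                "noise cv %.2f >= 1 heavily distorts multiplicative data", self.cv
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def factors(self, rng: np.random.Generator, size) -> np.ndarray:
        """Unit-mean lognormal multipliers with the requested CV."""
        if self.cv == 0:
            return np.ones(size)
        sigma2 = math.log(1.0 + self.cv**2)
        return rng.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class KsProfile:
    """Piecewise-constant synthesis rate.

    ``values[i]`` applies on the interval (change_times[i-1], change_times[i]]
    (the first value also covers t = 0), so the instantaneous synthesis rate
    AT each change time equals the profile value there — the convention the
    point-wise estimator inverts exactly. Change points may be finer than the
    sampling grid to emulate a smooth decline.
    """

    change_times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        ct = np.asarray(self.change_times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if ct.shape != v.shape or ct.size == 0:
            raise ValueError("change_times and values must be non-empty, equal length")
        if np.any(np.diff(ct) <= 0):
            raise ValueError("change_times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("synthesis rates must be non-negative")
        object.__setattr__(self, "change_times", ct)
        object.__setattr__(self, "values", v)

    def at(self, t: float) -> float:
        i = int(np.searchsorted(self.change_times, t, side="left"))
        return float(self.values[min(i, len(self.values) - 1)])

    @classmethod
    def constant(cls, ks: float, t_end: float) -> "KsProfile":
        return cls(change_times=np.array([t_end]), values=np.array([ks]))


def linear_decline_profile(
    schedule: DegradationSchedule,
    fold: float,
    t_end: float,
    grid_step: float = 10.0,
    p_start: float = 1.0,
) -> tuple[KsProfile, float]:
    """Synthesis profile declining ``fold``-fold whose abundance falls linearly.

    Solves for the constant abundance slope s such that the continuous
    profile ks(t) = s + kd(t) (p_start + s t) drops exactly ``fold``-fold
    between t = 0 and ``t_end``, then discretises it as piecewise-constant
    segments on a ``grid_step`` grid (midpoint rule). Emulates the regime of
    a near-linear protein decline driven by collapsing synthesis.
    Returns (profile, s).
    """
    kd0 = float(schedule.rate(0.0))
    kde = float(schedule.rate(t_end))
    target = 1.0 / fold
    # s + kde (p_start + t_end s) = target (s + kd0 p_start)
    s = (target * kd0 - kde) * p_start / (1.0 + kde * t_end - target)
    edges = np.arange(0.0, t_end + grid_step / 2, grid_step)
    mids = (edges[:-1] + edges[1:]) / 2
    vals = s + schedule.rate(mids) * (p_start + s * mids)
    if np.any(vals < 0):
        raise ValueError("decline too steep: synthesis would go negative")
    return KsProfile(change_times=edges[1:], values=vals), float(s)


def generate_growth_curve(model: GrowthModel, times) -> tuple[pd.DataFrame, TimeOdMap]:
    """OD600 readings on a time grid plus the induced time<->OD map."""
    times = np.asarray(times, dtype=float)
    od = model.od(times)
    df = pd.DataFrame({"time_min": times, "od600": od})
    return df, TimeOdMap(times=times, ods=od)


def solve_piecewise_abundance(
    profile: KsProfile,
    schedule: DegradationSchedule,
    p0: float,
    times,
) -> np.ndarray:
    """Exact abundance under a piecewise-constant synthesis profile.

    Chains the closed-form constant-ks propagator across the union of profile
    change points and requested times.
    """
    times = np.asarray(times, dtype=float)
    schedule.check_window(times)
    knots = np.unique(np.concatenate([[schedule.window[0]], profile.change_times, times]))
    knots = knots[(knots >= schedule.window[0]) & (knots <= times.max())]
    p = p0
    t_prev = schedule.window[0]
    vals = {t_prev: p0}
    for t in knots[knots > t_prev]:
        ks = profile.at(float(t))  # value in force on (t_prev, t]
        p = _segment_step(schedule, ks, p, float(t_prev), float(t))
        vals[float(t)] = p
        t_prev = t
    return np.array([vals[float(t)] for t in times])


def generate_abundance_course(
    model: TurnoverModel | tuple[KsProfile, DegradationSchedule, float],
    sample_times,
    noise: NoiseSpec = NoiseSpec(cv=0.0),
    n_replicates: int = 1,
    od_map: TimeOdMap | None = None,
    labels=None,
) -> tuple[AbundanceSeries, pd.DataFrame]:
    """Densitometry-like abundance series from the forward turnover model.

    Accepts either a constant-synthesis :class:`TurnoverModel` or a
    ``(KsProfile, DegradationSchedule, p0)`` triple for time-varying
    synthesis. Each replicate is the noise-free trajectory times lognormal
    factors of the requested CV. Returns the replicate-mean series (with SD
    when n_replicates > 1) and the tidy per-replicate table.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    if isinstance(model, TurnoverModel):
        truth = analytic_trajectory(model, sample_times).values
    else:
        profile, schedule, p0 = model
        truth = solve_piecewise_abundance(profile, schedule, p0, sample_times)

    rng = noise.rng()
    reps = []
    for r in range(1, n_replicates + 1):
        vals = truth * noise.factors(rng, truth.shape)
        reps.append(pd.DataFrame({"replicate": r, "time_min": sample_times,
                                  "abundance": vals}))
    tidy = pd.concat(reps, ignore_index=True)

    mean = tidy.groupby("time_min")["abundance"].mean().to_numpy()
    sd = tidy.groupby("time_min")["abundance"].std().to_numpy()
    df = pd.DataFrame({"time_min": sample_times, "abundance": mean})
    if n_replicates > 1:
        df["sd"] = sd
    if od_map is not None:
        df.insert(1, "od600", od_map.od_at(sample_times))
        tidy.insert(2, "od600", od_map.od_at(tidy["time_min"].to_numpy()))
    if labels is not None:
        df["label"] = list(labels)
    return AbundanceSeries(df), tidy


def generate_chase_course(
    halflife: float,
    times,
    noise: NoiseSpec = NoiseSpec(cv=0.0),
    n_replicates: int = 1,
    condition: str = "",
) -> ChaseCourse:
    """First-order chase decay 2^(-t/t_half) with multiplicative noise."""
    if not halflife > 0:
        raise ValueError("half-life must be positive")
    times = np.asarray(times, dtype=float)
    truth = np.exp2(-times / halflife)
    rng = noise.rng()
    reps = []
    for r in range(1, n_replicates + 1):
        reps.append(pd.DataFrame({
            "replicate": r, "time_min": times,
            "intensity": truth * noise.factors(rng, truth.shape),
        }))
    return ChaseCourse(pd.concat(reps, ignore_index=True), condition=condition)


def generate_ct_table(
    rel_expr: dict[str, float],
    od600: dict[str, float] | None = None,
    target: str = "dnaA",
    reference: str = "16S",
    base_ct: float = 22.0,
    reference_ct: float = 12.0,
    jitter_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> CtTable:
    """Ct table encoding known relative expression per sample.

    Ct_target = base_ct - log2(rel_expr) + jitter; Ct_reference is constant
    (up to jitter), so the comparative Ct analysis recovers ``rel_expr``
    exactly at zero jitter (for a calibrator with rel_expr 1).
    """
    if any(v <= 0 for v in rel_expr.values()):
        raise ValueError("relative expressions must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, expr in rel_expr.items():
        for rep in range(1, n_replicates + 1):
            jt = rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0
            jr = rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0
            row_od = od600.get(sample, np.nan) if od600 else np.nan
            rows.append((sample, row_od, target, rep, base_ct - math.log2(expr) + jt))
            rows.append((sample, row_od, reference, rep, reference_ct + jr))
    return CtTable(pd.DataFrame(rows, columns=["sample", "od600", "gene", "replicate", "ct"]))
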