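"""Point-wise inference of the protein synthesis rate and translation rate.

Rearranging the turnover balance dP/dt = ks(t) - kd(t) P(t) gives the
point-wise estimator

    ks(t_i) = dP/dt + kd(t_i) * P(t_i),

where P(t_i) is the measured relative abundance, kd(t_i) = ln2 / t_half(t_i)
comes from chase-assay half-lives assigned to each time point, and dP/dt is a
single global slope from a linear fit through the abundance data (excluding
the overnight point). Dividing the normalised synthesis profile by the
normalised mRNA abundance m(t) from qPCR yields a per-transcript translation
rate r(t) = ks(t) / m(t).

Profiles are normalised to their first point, matching how relative
densitometry series are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import LN2
from .qpcr import ExpressionSeries

__all__ = [
    "AbundanceSeries",
    "HalfLifeAssignment",
    "SynthesisProfile",
    "TranslationProfile",
    "fit_global_slope",
    "infer_synthesis_pointwise",
    "translation_rates",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AbundanceSeries:
    """Measured relative protein abundance at (time, OD) points.

    Columns: time_min, abundance, optionally od600, label (e.g. "overnight")
    and sd (replicate spread). Times strictly increasing, abundances positive.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in ("time_min", "abundance"):
            if col not in df.columns:
                raise ValueError(f"abundance series missing column {col!r}")
        if "label" not in df.columns:
            df["label"] = ""
        df["label"] = df["label"].fillna("")
        df = df.sort_values("time_min").reset_index(drop=True)
        t = df["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(df["abundance"].to_numpy(dtype=float) <= 0):
            raise ValueError("abundances must be positive")
        object.__setattr__(self, "data", df)

    @classmethod
    def from_arrays(cls, times, abundances, od600=None, labels=None) -> "AbundanceSeries":
        df = pd.DataFrame({"time_min": np.asarray(times, float),
                           "abundance": np.asarray(abundances, float)})
        if od600 is not None:
            df["od600"] = np.asarray(od600, float)
        if labels is not None:
            df["label"] = list(labels)
        return cls(df)

    def included(self, exclude_labels=frozenset()) -> pd.DataFrame:
        mask = ~self.data["label"].isin(set(exclude_labels))
        return self.data[mask]

    @property
    def times(self) -> np.ndarray:
        return self.data["time_min"].to_numpy(dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.data["abundance"].to_numpy(dtype=float)


@dataclass(frozen=True)
class HalfLifeAssignment:
    """Half-life (minutes) assigned to each abundance time point."""

    mapping: dict[float, float]

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.mapping.values()):
            raise ValueError("assigned half-lives must be positive")

    @classmethod
    def split(cls, times, halflife_early: float, halflife_late: float) -> "HalfLifeAssignment":
        """Assign the early half-life to the first half of the points and the
        late one to the rest (for a 4-point series: first two / last two)."""
        times = [float(t) for t in times]
        n_early = (len(times) + 1) // 2
        return cls({t: (halflife_early if i < n_early else halflife_late)
                    for i, t in enumerate(times)})

    def halflife_at(self, t: float) -> float:
        try:
            return self.mapping[float(t)]
        except KeyError:
            raise KeyError(f"no half-life assigned to time point {t}") from None

    def rates(self, times) -> np.ndarray:
        return np.array([LN2 / self.halflife_at(t) for t in np.asarray(times, float)])


@dataclass(frozen=True)
class SynthesisProfile:
    """Inferred synthesis rate ks(t): raw (per minute) and first-point normalised."""

    times: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray = field(default=None)  # type: ignore[assignment]
    od600: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "raw", np.asarray(self.raw, float))
        if not np.all(np.isfinite(self.raw)):
            raise ValueError("raw synthesis rates must be finite")
        norm = self.raw / self.raw[0]
        object.__setattr__(self, "normalized", norm)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_min": self.times, "ks_raw": self.raw,
                           "ks_norm": self.normalized})
        if self.od600 is not None:
            df.insert(1, "od600", self.od600)
        return df


@dataclass(frozen=True)
class TranslationProfile:
    """Per-transcript translation rate r(t) = ks(t)/m(t), first-point normalised."""

    times: np.ndarray
    normalized: np.ndarray
    mrna: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "normalized", np.asarray(self.normalized, float))
        object.__setattr__(self, "mrna", np.asarray(self.mrna, float))


def fit_global_slope(data: AbundanceSeries, exclude_labels=frozenset({"overnight"})) -> float:
    """Ordinary least-squares slope of abundance vs time (per minute).

    A single global slope stands in for dP/dt at every point — the protein
    decline is treated as linear over the sampled window. Points whose label
    is in ``exclude_labels`` (the overnight sample by default) are left out.
    """
    df = data.included(exclude_labels)
    if len(df) < 2:
        raise ValueError("need at least 2 included points to fit a slope")
    slope, _ = np.polyfit(df["time_min"].to_numpy(float), df["abundance"].to_numpy(float), 1)
    return float(slope)


def infer_synthesis_pointwise(
    data: AbundanceSeries,
    halflives: HalfLifeAssignment,
    slope: float,
    exclude_labels=frozenset({"overnight"}),
) -> SynthesisProfile:
    """ks(t_i) = slope + (ln2 / t_half(t_i)) * P(t_i), normalised to the first point.

    Negative raw values (possible under measurement noise) are retained with
    a logged warning rather than clipped, so inconsistent inputs stay visible.
    """
    df = data.included(exclude_labels)
    t = df["time_min"].to_numpy(dtype=float)
    p = df["abundance"].to_numpy(dtype=float)
    raw = slope + halflives.rates(t) * p
    if np.any(raw < 0):
        logger.warning("inferred %d negative raw synthesis rates (kept, not clipped)",
                       int((raw < 0).sum()))
    od = df["od600"].to_numpy(dtype=float) if "od600" in df.columns else None
    return SynthesisProfile(times=t, raw=raw, od600=od)


def translation_rates(
    synth: SynthesisProfile,
    mrna: ExpressionSeries,
    od_tolerance: float = 0.1,
) -> TranslationProfile:
    """Divide the synthesis profile by matched relative mRNA abundance.

    Protein and transcript samples are matched by OD600 (nearest sample
    within ``od_tolerance``), since both assays are sampled on OD grids.
    The mRNA series is renormalised to the sample matching the first protein
    point, then r(t_i) = ks_norm(t_i) / m(t_i), normalised to the first point.
    """
    if synth.od600 is None:
        raise ValueError("synthesis profile carries no OD600 metadata for matching")
    m = np.empty_like(synth.times)
    for i, od in enumerate(synth.od600):
        try:
            m[i] = mrna.value_at_od(float(od), tolerance=od_tolerance)
        except ValueError as err:
            raise ValueError(
                f"cannot match protein point at OD {od:.3g} (t = {synth.times[i]:g} min) "
                f"to an mRNA sample: {err}"
            ) from None
    m = m / m[0]
    if np.any(m <= 0):
        raise ValueError("matched mRNA abundances must be positive")
    r = synth.normalized / m
    return TranslationProfile(times=synth.times, normalized=r / r[0], mrna=m)
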