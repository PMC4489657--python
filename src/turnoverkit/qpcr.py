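"""Relative expression by the comparative Ct method.

Each target Ct is normalised against an endogenous reference gene (16S rRNA
in the emulated assay) and against a calibrator sample:

    dCt   = Ct_target - Ct_reference          (per sample)
    ddCt  = dCt_sample - dCt_calibrator
    fold  = efficiency ** (-ddCt)             (efficiency 2.0 = perfect doubling)

Replicates are averaged on the Ct scale. Wells that failed the dissociation
curve check can be flagged in a ``qc_pass`` column and are excluded with a
logged count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CtTable", "ExpressionSeries", "delta_delta_ct", "summarize_series"]

logger = logging.getLogger(__name__)

_REQUIRED = ("sample", "gene", "replicate", "ct")


@dataclass(frozen=True)
class CtTable:
    """Tidy qPCR table: one well per row (sample, gene, replicate, ct[, od600, qc_pass])."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"Ct table is missing columns {missing}")
        if "qc_pass" in df.columns:
            n_flagged = int((~df["qc_pass"].astype(bool)).sum())
            if n_flagged:
                logger.warning("excluding %d wells flagged by dissociation-curve QC", n_flagged)
            df = df[df["qc_pass"].astype(bool)].drop(columns=["qc_pass"])
        ct = df["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
            raise ValueError("Ct values must be finite and positive")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    def samples(self) -> list[str]:
        return list(pd.unique(self.data["sample"]))


@dataclass(frozen=True)
class ExpressionSeries:
    """Relative expression (fold vs calibrator) per sample, with replicate spread.

    Columns: sample, od600 (NaN when unknown), rel_expr, sd (NaN for a single
    replicate). The calibrator row has rel_expr exactly 1.
    """

    data: pd.DataFrame
    target: str = ""
    reference: str = ""
    calibrator: str = ""

    def __post_init__(self) -> None:
        for col in ("sample", "rel_expr"):
            if col not in self.data.columns:
                raise ValueError(f"expression series missing column {col!r}")
        if np.any(self.data["rel_expr"].to_numpy(dtype=float) <= 0):
            raise ValueError("relative expression must be positive")

    def value_at_od(self, od: float, tolerance: float = 0.1) -> float:
        """Relative expression of the sample nearest in OD600 (within tolerance)."""
        ods = self.data["od600"].to_numpy(dtype=float)
        if np.all(np.isnan(ods)):
            raise ValueError("expression series carries no OD600 metadata")
        i = int(np.nanargmin(np.abs(ods - od)))
        if abs(ods[i] - od) > tolerance:
            raise ValueError(f"no expression sample within {tolerance} OD of {od}")
        return float(self.data["rel_expr"].iloc[i])


def delta_delta_ct(
    table: CtTable,
    target: str,
    reference: str,
    calibrator: str,
    efficiency: float = 2.0,
) -> ExpressionSeries:
    """Relative expression of ``target`` vs ``reference``, calibrated to one sample.

    Replicate Cts are averaged per (sample, gene); the replicate SD of the
    ddCt is propagated to the fold-change scale by the delta method
    (sd_fold = fold * ln(efficiency) * sd_ddCt). Raises if the reference gene
    is missing for any sample, naming the sample.
    """
    df = table.data
    for gene, role in ((target, "target"), (reference, "reference")):
        if gene not in set(df["gene"]):
            raise ValueError(f"{role} gene {gene!r} not present in the table")
    if calibrator not in set(df["sample"]):
        raise ValueError(f"calibrator sample {calibrator!r} not present in the table")

    stats_ = (
        df[df["gene"].isin([target, reference])]
        .groupby(["sample", "gene"])["ct"]
        .agg(mean="mean", sd="std", n="count")
    )
    rows = []
    for sample in table.samples():
        try:
            tgt = stats_.loc[(sample, target)]
            ref = stats_.loc[(sample, reference)]
        except KeyError as err:
            missing = target if (sample, target) not in stats_.index else reference
            raise ValueError(f"sample {sample!r} lacks gene {missing!r}") from err
        dct = tgt["mean"] - ref["mean"]
        var = (0.0 if tgt["n"] < 2 else tgt["sd"] ** 2 / tgt["n"]) + (
            0.0 if ref["n"] < 2 else ref["sd"] ** 2 / ref["n"]
        )
        single = tgt["n"] < 2 and ref["n"] < 2
        rows.append((sample, dct, math.sqrt(var), single))
    dct_tab = pd.DataFrame(rows, columns=["sample", "dct", "dct_se", "single"])

    cal_dct = float(dct_tab.loc[dct_tab["sample"] == calibrator, "dct"].iloc[0])
    log_eff = math.log(efficiency)
    dct_tab["rel_expr"] = efficiency ** -(dct_tab["dct"] - cal_dct)
    dct_tab["sd"] = np.where(
        dct_tab["single"], np.nan, dct_tab["rel_expr"] * log_eff * dct_tab["dct_se"]
    )

    od = (
        df.groupby("sample")["od600"].first()
        if "od600" in df.columns
        else pd.Series(np.nan, index=dct_tab["sample"])
    )
    out = pd.DataFrame(
        {
            "sample": dct_tab["sample"],
            "od600": dct_tab["sample"].map(od).astype(float),
            "rel_expr": dct_tab["rel_expr"],
            "sd": dct_tab["sd"],
        }
    )
    return ExpressionSeries(out, target=target, reference=reference, calibrator=calibrator)


def summarize_series(series: ExpressionSeries) -> pd.DataFrame:
    """Order an expression series by OD600 with mean and SD across biological replicates.

    Samples sharing an OD are treated as biological replicates and averaged;
    a single replicate reports SD as missing (NaN), not zero.
    """
    df = series.data
    if df["od600"].isna().any():
        raise ValueError("every sample needs OD600 metadata to be summarised")
    if "bio_replicate" not in df.columns and df["od600"].duplicated().any():
        raise ValueError("duplicate OD labels need a 'bio_replicate' column")
    grouped = (
        df.groupby("od600")["rel_expr"]
        .agg(rel_expr="mean", sd="std", n="count")
        .reset_index()
        .sort_values("od600")
        .reset_index(drop=True)
    )
    grouped.loc[grouped["n"] == 1, "sd"] = np.nan
    return grouped.drop(columns=["n"])
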