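"""Scenario-driven generation of a complete synthetic study.

A scenario (a plain dict, typically loaded from YAML) specifies the growth
model, the degradation schedule, the synthesis profile, the chase assays and
the mRNA profile; :func:`generate_scenario` writes the four input tables the
pipeline consumes plus a ``truth.json`` of generating parameters for
recovery tests.

The default scenario encodes the modelled study conditions: growth from
OD 0.4 to a plateau of 1.5 passing OD 1.0 at 160 min; degradation half-life
23 min in exponential phase accelerating linearly to 20 min at 160 min; a
20-fold collapse of the synthesis rate shaped so protein abundance declines
near-linearly over 0-400 min; chases at 23 and 20 min plus a protease-deficient
stable control; and dnaA-like mRNA staying at or above 65% of its
exponential-phase level.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_table
from .model import build_linear_schedule
from .simulate import (
    GrowthModel,
    KsProfile,
    NoiseSpec,
    generate_abundance_course,
    generate_chase_course,
    generate_ct_table,
    generate_growth_curve,
    linear_decline_profile,
)

__all__ = ["default_scenario", "generate_scenario"]


def default_scenario() -> dict:
    """Study-condition scenario used throughout the tests and analyses."""
    return {
        "growth": {"od0": 0.4, "K": 1.5, "anchor": {"t": 160.0, "od": 1.0}},
        "schedule": {"halflife_t0_min": 23.0, "halflife_t1_min": 20.0,
                     "t1_min": 160.0, "window_end_min": 400.0,
                     # chase assays show degradation stops accelerating once
                     # stationary phase begins, so the generating truth
                     # plateaus at the t1 half-life
                     "plateau_after_t1": True},
        "synthesis": {"mode": "linear_decline", "fold": 20.0, "grid_step_min": 10.0},
        "sampling": {"start_min": 0.0, "stop_min": 400.0, "step_min": 50.0,
                     "n_replicates": 3},
        "noise": {"densitometry_cv": 0.10, "ct_jitter_sd_cycles": 0.2},
        "chases": [
            {"condition": "exponential", "halflife_min": 23.0,
             "times_min": [0, 10, 20, 30, 40], "n_replicates": 3},
            {"condition": "stationary_onset", "halflife_min": 20.0,
             "times_min": [0, 10, 20, 30, 40], "n_replicates": 3},
            {"condition": "lon_minus", "halflife_min": 1.0e6,
             "times_min": list(range(0, 121, 10)), "n_replicates": 2},
        ],
        "mrna": {"target": "dnaA", "reference": "16S",
                 "terminal_fraction": 0.65, "base_ct": 22.0, "reference_ct": 12.0,
                 "n_replicates": 3},
    }


def _subseed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def generate_scenario(config: dict | None = None, outdir=None, seed: int = 0) -> dict:
    """Generate all pipeline inputs for a scenario.

    Returns a dict with the in-memory objects (growth table, abundance
    series, chase courses, Ct table, truth dict); when ``outdir`` is given
    the tables are also written as growth.csv, abundance.csv, chase.csv,
    ct.csv and truth.json.
    """
    cfg = copy.deepcopy(default_scenario())
    if config:
        for key, val in config.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val

    g = cfg["growth"]
    if "anchor" in g:
        growth = GrowthModel.from_anchor(g["od0"], g["K"], g["anchor"]["t"], g["anchor"]["od"])
    else:
        growth = GrowthModel(od0=g["od0"], K=g["K"], r=g["r"])

    s = cfg["schedule"]
    schedule = build_linear_schedule(
        s["halflife_t0_min"], s["halflife_t1_min"], s["t1_min"], s["window_end_min"],
        clamp_after_t1=bool(s.get("plateau_after_t1", False)),
    )

    samp = cfg["sampling"]
    times = np.arange(samp["start_min"], samp["stop_min"] + samp["step_min"] / 2,
                      samp["step_min"])
    growth_df, od_map = generate_growth_curve(growth, times)

    syn = cfg["synthesis"]
    truth: dict = {"schedule": {"kd0_per_min": schedule.kd0, "a_per_min2": schedule.a,
                                "halflife_t1_min": s["halflife_t1_min"]},
                   "seed": seed}
    if syn["mode"] == "linear_decline":
        profile, slope = linear_decline_profile(
            schedule, syn["fold"], samp["stop_min"], grid_step=syn["grid_step_min"]
        )
        truth["synthesis"] = {
            "mode": "linear_decline", "fold": syn["fold"],
            "abundance_slope_per_min": slope,
            "terminal_fraction": 1.0 / syn["fold"],
            "ks0_per_min": profile.at(0.0),
        }
    elif syn["mode"] == "steady_state":
        ks0 = schedule.kd0 * 1.0
        profile = KsProfile.constant(ks0, samp["stop_min"])
        truth["synthesis"] = {"mode": "steady_state", "fold": 1.0,
                              "terminal_fraction": 1.0, "ks0_per_min": ks0}
    else:
        raise ValueError(f"unknown synthesis mode {syn['mode']!r}")

    noise = cfg["noise"]
    series, tidy = generate_abundance_course(
        (profile, schedule, 1.0), times,
        noise=NoiseSpec(cv=noise["densitometry_cv"], seed=_subseed(seed, 1)),
        n_replicates=samp["n_replicates"], od_map=od_map,
    )

    chase_frames = []
    chase_truth = {}
    for k, ch in enumerate(cfg["chases"]):
        course = generate_chase_course(
            ch["halflife_min"], np.asarray(ch["times_min"], float),
            noise=NoiseSpec(cv=noise["densitometry_cv"], seed=_subseed(seed, 10 + k)),
            n_replicates=ch["n_replicates"], condition=ch["condition"],
        )
        df = course.data.copy()
        df.insert(0, "condition", ch["condition"])
        chase_frames.append(df)
        chase_truth[ch["condition"]] = ch["halflife_min"]
    chase_df = pd.concat(chase_frames, ignore_index=True)
    truth["chase_halflives_min"] = chase_truth

    m = cfg["mrna"]
    mrna_frac = np.interp(times, [times[0], times[-1]], [1.0, m["terminal_fraction"]])
    rel = {f"od_{od:.2f}": float(f) for od, f in zip(od_map.od_at(times), mrna_frac)}
    ods = {f"od_{od:.2f}": float(od) for od in od_map.od_at(times)}
    ct = generate_ct_table(
        rel, od600=ods, target=m["target"], reference=m["reference"],
        base_ct=m["base_ct"], reference_ct=m["reference_ct"],
        jitter_sd=noise["ct_jitter_sd_cycles"], n_replicates=m["n_replicates"],
        seed=_subseed(seed, 20),
    )
    truth["mrna"] = {"terminal_fraction": m["terminal_fraction"],
                     "terminal_translation_fraction":
                         truth["synthesis"]["terminal_fraction"] / m["terminal_fraction"]}

    out = {"config": cfg, "growth": growth_df, "od_map": od_map,
           "abundance": series, "abundance_replicates": tidy,
           "chase": chase_df, "ct": ct, "truth": truth,
           "schedule": schedule, "profile": profile}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(growth_df, outdir / "growth.csv")
        write_table(series.data, outdir / "abundance.csv")
        write_table(chase_df, outdir / "chase.csv")
        write_table(ct.data, outdir / "ct.csv")
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return out
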