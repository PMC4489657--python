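#!/usr/bin/env python
"""Fit degradation acceleration to the measured-like abundance course.

With kd(0) anchored by the exponential-phase chase (23-min half-life), fits
the constant synthesis rate and the linear degradation acceleration by
relative least squares and reports the half-life the best fit implies at
160 min. On the default synthetic data — where the true cause of the decline
is collapsing synthesis, not faster degradation — the fitted acceleration
shows how short the half-life would have to become if degradation alone had
to explain the decline. Writes results/fit.json and results/fit.csv.
"""

import argparse
import json
from pathlib import Path

from turnoverkit import fit_degradation_acceleration
from turnoverkit.io import read_table, write_table
from turnoverkit.model import analytic_trajectory
from turnoverkit.pipeline import _round_floats
from turnoverkit.synthesis import AbundanceSeries


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--abundance", type=Path,
                        default=Path("results/data/abundance.csv"))
    parser.add_argument("--halflife-t0", type=float, default=23.0)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    series = AbundanceSeries(read_table(args.abundance, "abundance"))
    fit = fit_degradation_acceleration(series, halflife_t0=args.halflife_t0,
                                       seed=args.seed)
    report = fit.to_dict()
    report["halflife_at_160min"] = fit.halflife_at(160.0)
    args.outdir.mkdir(parents=True, exist_ok=True)
    (args.outdir / "fit.json").write_text(
        json.dumps(_round_floats(report), indent=2, sort_keys=True))
    traj = analytic_trajectory(fit.model(p0=float(series.values[0])), series.times)
    write_table(traj.to_frame(), args.outdir / "fit.csv")

    print(f"fitted ks = {fit.ks:.4g}/min, a = {fit.a:.4g}/min^2 "
          f"(objective {fit.objective:.3g})")
    print(f"best-fit half-life at 160 min: {fit.halflife_at(160.0):.2f} min "
          f"(vs 23 min at t = 0) — degradation would have to accelerate this "
          "much to reproduce the decline on its own")


if __name__ == "__main__":
    main()
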