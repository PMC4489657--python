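#!/usr/bin/env python
"""Infer the synthesis and translation profiles over the growth curve.

Runs the full pipeline on the generated inputs: chase half-lives anchor
kd(t), the point-wise estimator ks(t) = dP/dt + kd(t) P(t) gives the
synthesis profile, and dividing by the qPCR mRNA profile gives the
per-transcript translation rate. On the default scenario, synthesis falls
~20-fold while mRNA stays at or above ~65% — so translation, not transcript
abundance, carries the regulation. Writes the per-stage tables and
summary.json under results/pipeline/.
"""

import argparse
import json
from pathlib import Path

from turnoverkit import PipelineConfig, run_pipeline


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--outdir", type=Path, default=Path("results/pipeline"))
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    cfg = PipelineConfig(
        abundance=args.data / "abundance.csv",
        chase=args.data / "chase.csv",
        ct=args.data / "ct.csv",
        output_dir=args.outdir,
        seed=args.seed,
    )
    summary = run_pipeline(cfg)

    synth = summary["stages"]["synthesis"]
    qpcr = summary["stages"]["qpcr"]
    print(f"global abundance slope: {synth['global_slope_per_min']:.5f}/min")
    print(f"synthesis fold change over the growth curve: "
          f"{synth['synthesis_fold_change']:.1f}x down")
    print(f"terminal mRNA fraction: {qpcr['terminal_mrna_fraction']:.2f}")
    print(f"terminal translation fraction: "
          f"{qpcr['terminal_translation_fraction']:.3f} "
          "(per-transcript synthesis at stationary onset vs exponential phase)")
    truth_path = args.data / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        print(f"[generating truth: synthesis fold {truth['synthesis']['fold']:.0f}, "
              f"terminal translation "
              f"{truth['mrna']['terminal_translation_fraction']:.3f}]")


if __name__ == "__main__":
    main()
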