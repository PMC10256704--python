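#!/usr/bin/env python
"""Generate the synthetic study inputs: a phantom CT stack and a cohort.

Writes results/data/phantom/{image,mask}.nii.gz + levels.csv, the phantom
ground truth (truth.csv), and results/data/cohort.csv. Everything downstream
(02-04) consumes only these files.
"""

import argparse
from pathlib import Path

import pandas as pd

from aortamac.cohort_sim import CohortSpec, generate_cohort
from aortamac.io import write_study, write_table
from aortamac.pipeline import simulate_study

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--cohort-n", type=int, default=4000)
    ap.add_argument("--slices-per-level", type=int, default=3)
    args = ap.parse_args()

    data_dir = ROOT / "results" / "data"
    study = simulate_study(args.seed, args.slices_per_level)
    paths = write_study(study, data_dir / "phantom")
    truth = pd.DataFrame({
        "slice_index": range(len(study.levels)),
        "level": study.levels,
        "truth_calc_area_mm2": [t.calc_area for t in study.truths],
        "truth_wall_fraction": [t.calc_wall_fraction for t in study.truths],
    })
    write_table(truth, data_dir / "phantom" / "truth.csv")
    print(f"phantom study: {len(study.slices)} slices across "
          f"{len(set(study.levels))} levels -> {paths['image'].parent}")

    cohort = generate_cohort(CohortSpec(n=args.cohort_n, seed=args.seed))
    write_table(cohort, data_dir / "cohort.csv")
    zero = (cohort["truth_mac_mean"] == 0).mean()
    print(f"cohort: n={len(cohort)}, zero-MAC fraction {zero:.3f}, "
          f"elevated (L3/L4 > 4.21%) {cohort['truth_elevated'].mean():.3f}")


if __name__ == "__main__":
    main()
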