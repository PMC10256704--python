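#!/usr/bin/env python
"""Cohort statistics: descriptive tables, elevated-vs-normal FRS, regression.

Reads the cohort and its Framingham scores, writes descriptive tables
(results/table_by_sex.csv, table_by_age.csv), the association report
(results/association.csv), and summary figures (results/figures/). Pass
--drop-missing-sbp for the sensitivity re-analysis restricted to measured SBP.
"""

import argparse
from pathlib import Path

import pandas as pd

from aortamac.analysis import (
    compare_frs_by_mac,
    describe,
    log_mac,
    regress_frs_on_logmac,
)
from aortamac.io import read_cohort, write_table
from aortamac.plots import save_summary_plots

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--drop-missing-sbp", action="store_true")
    args = ap.parse_args()

    cohort = read_cohort(ROOT / "results" / "data" / "cohort.csv")
    scored = pd.read_csv(ROOT / "results" / "framingham.csv")
    merged = cohort.assign(frs=scored["total_points"].to_numpy())
    if args.drop_missing_sbp:
        merged = merged[merged["sbp"].notna()]
        print(f"sensitivity analysis: {len(merged)} participants with measured SBP")

    merged = merged.assign(log_mac=log_mac(merged["truth_mac_mean"].to_numpy()))
    cont = ["age", "bmi", "truth_mac_mean", "log_mac", "frs"]
    write_table(describe(merged, cont, categorical=["sex", "smoker"], strata="sex"),
                ROOT / "results" / "table_by_sex.csv")
    write_table(describe(merged, ["truth_mac_mean", "frs"], strata="age"),
                ROOT / "results" / "table_by_age.csv")

    comp = compare_frs_by_mac(merged["frs"].to_numpy(), merged["truth_elevated"].to_numpy())
    reg = regress_frs_on_logmac(merged["frs"].to_numpy(), merged["truth_mac_mean"].to_numpy())
    write_table(pd.DataFrame([
        {"quantity": "frs_mean_elevated", "value": comp.means[0]},
        {"quantity": "frs_mean_normal", "value": comp.means[1]},
        {"quantity": "frs_median_elevated", "value": comp.medians[0]},
        {"quantity": "frs_median_normal", "value": comp.medians[1]},
        {"quantity": "rank_sum_p", "value": comp.p_value},
        {"quantity": "welch_t_p", "value": comp.secondary_p_value},
        {"quantity": "ols_intercept", "value": reg.intercept},
        {"quantity": "ols_slope", "value": reg.slope},
        {"quantity": "ols_slope_se", "value": reg.slope_se},
        {"quantity": "ols_slope_p", "value": reg.p_value},
        {"quantity": "ols_r_squared", "value": reg.r_squared},
    ]), ROOT / "results" / "association.csv")
    save_summary_plots(merged, ROOT / "results" / "figures")

    print(f"elevated-MAC mean FRS {comp.means[0]:.2f} vs normal {comp.means[1]:.2f} "
          f"(rank-sum p = {comp.p_value:.2e})")
    print(f"OLS FRS ~ log(MAC+0.01): slope {reg.slope:.3f} (SE {reg.slope_se:.3f}), "
          f"intercept {reg.intercept:.2f}, R^2 {reg.r_squared:.3f}")


if __name__ == "__main__":
    main()
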