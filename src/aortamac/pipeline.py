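"""End-to-end orchestration: slices -> per-level metrics -> cohort report.

`score_slices` runs the detection/unfurling chain on in-memory slices;
`run_all` drives the full demo pipeline (phantom study + synthetic cohort ->
metrics -> Framingham scores -> statistical report) and writes a machine-
parseable manifest.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import compare_frs_by_mac, describe, log_mac, regress_frs_on_logmac
from .calcium import (
    LEVELS,
    AortaMask,
    AxialSlice,
    aggregate_level,
    calcification_threshold,
    compute_lumen_reference,
    detect_calcification,
    slice_metrics,
    summarize_participant,
)
from .cohort_sim import CohortSpec, generate_cohort
from .framingham import score_cohort
from .io import read_study, write_study, write_table
from .phantom import generate_phantom_stack, random_phantom_spec
from .wall import (
    DEFAULT_N_BINS,
    MAC_THRESHOLD_BALANCED,
    MAC_THRESHOLD_SENSITIVITY,
    classify_mac,
    unfurl_wall,
    wall_area_level,
    wall_calc_pct,
)


@dataclass(frozen=True)
class ScoreConfig:
    """Algorithm parameters of the detection/unfurling chain."""

    connectivity: int = 8
    min_region_px: int = 1
    search_domain: str = "aorta-minus-lumen"
    n_bins: int = DEFAULT_N_BINS
    mac_threshold: float = MAC_THRESHOLD_SENSITIVITY
    mac_threshold_balanced: float = MAC_THRESHOLD_BALANCED
    n_sd: float = 5.0


def score_slices(
    pairs: list[tuple[AxialSlice, AortaMask]],
    config: ScoreConfig = ScoreConfig(),
    participant_id: int | str = 0,
) -> pd.DataFrame:
    """Score one participant's slices into a per-level metrics table.

    Slices without a vertebral level label are ignored. Returns one row per
    available level with LevelMetrics columns plus the participant-level
    elevated flags (classified from L3/L4).
    """
    by_level: dict[str, list] = {}
    for slc, mask in pairs:
        if slc.vertebral_level is None:
            continue
        ref = compute_lumen_reference(slc, mask)
        thr = calcification_threshold(ref, config.n_sd)
        calc = detect_calcification(
            slc, mask, thr,
            min_region_px=config.min_region_px,
            connectivity=config.connectivity,
            search_domain=config.search_domain,
        )
        sm_ = slice_metrics(slc, mask, calc)
        wm = unfurl_wall(mask, calc, slc.pixel_spacing, slc.slice_thickness, config.n_bins)
        by_level.setdefault(slc.vertebral_level, []).append((sm_, wm))

    levels = {}
    for level in LEVELS:
        entries = by_level.get(level, [])
        if not entries:
            continue
        mets = [e[0] for e in entries]
        wms = [e[1] for e in entries]
        levels[level] = aggregate_level(
            mets, level, pairs[0][0].slice_thickness,
            total_wall_area=wall_area_level(wms),
            wall_calc_pct=wall_calc_pct(wms),
        )

    pct = {lv: m.wall_calc_pct for lv, m in levels.items()}
    elev_s = classify_mac(pct, config.mac_threshold)
    elev_b = classify_mac(pct, config.mac_threshold_balanced)
    summary = summarize_participant(levels)

    rows = []
    for lv, m in levels.items():
        rows.append({
            "participant_id": participant_id,
            "level": lv,
            "n_slices": m.n_slices,
            "calc_area": m.calc_area,
            "calc_volume": m.calc_volume,
            "total_wall_area": m.total_wall_area,
            "wall_calc_pct": m.wall_calc_pct,
            "mean_attenuation": m.mean_attenuation,
            "elevated_sensitivity": elev_s,
            "elevated_balanced": elev_b,
            "zero_calcification": summary.zero_calcification if summary else None,
        })
    return pd.DataFrame(rows)


def export_unfurled(
    pairs: list[tuple[AxialSlice, AortaMask]],
    config: ScoreConfig = ScoreConfig(),
) -> pd.DataFrame:
    """Unfurled wall maps as a (slice x angular bin) 0/1 table for inspection."""
    rows = []
    for k, (slc, mask) in enumerate(pairs):
        ref = compute_lumen_reference(slc, mask)
        thr = calcification_threshold(ref, config.n_sd)
        calc = detect_calcification(
            slc, mask, thr,
            min_region_px=config.min_region_px,
            connectivity=config.connectivity,
            search_domain=config.search_domain,
        )
        wm = unfurl_wall(mask, calc, slc.pixel_spacing, slc.slice_thickness, config.n_bins)
        rows.append({
            "slice_index": k,
            "level": slc.vertebral_level,
            **{f"bin_{b}": int(v) for b, v in enumerate(wm.occupancy)},
        })
    return pd.DataFrame(rows)


def simulate_study(seed: int, slices_per_level: int = 2, lumen_mean_hu: float = 200.0):
    """A small random phantom study used by the demo pipeline and CI."""
    rng = np.random.default_rng(seed)
    specs = {
        level: [
            random_phantom_spec(rng, level=level, lumen_mean_hu=lumen_mean_hu)
            for _ in range(slices_per_level)
        ]
        for level in LEVELS
    }
    return generate_phantom_stack(specs)


def run_all(out_dir: str | Path, seed: int = 0, cohort_n: int = 2000,
            slices_per_level: int = 2, config: ScoreConfig = ScoreConfig()) -> dict:
    """Phantom study + synthetic cohort -> metrics, scores, report, manifest.

    Deterministic given the seed: every output file except the manifest's
    timestamps is byte-identical across repeated runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")

    # imaging arm: one phantom participant, written and re-scored from disk
    study = simulate_study(seed, slices_per_level)
    paths = write_study(study, out / "phantom")
    pairs = read_study(paths["image"], paths["mask"], paths["levels"])
    metrics = score_slices(pairs, config)
    write_table(metrics, out / "metrics.csv")

    # cohort arm
    cohort = generate_cohort(CohortSpec(n=cohort_n, seed=seed))
    write_table(cohort, out / "cohort.csv")
    scored, rule_counts = score_cohort(cohort)
    scored = pd.concat([cohort[["participant_id"]], scored], axis=1)
    write_table(scored, out / "framingham.csv")

    merged = cohort.assign(frs=scored["total_points"])
    desc = describe(
        merged.assign(log_mac=log_mac(merged["truth_mac_mean"].to_numpy())),
        continuous=["age", "truth_mac_mean", "log_mac", "frs"],
        categorical=["sex"],
        strata="sex",
    )
    write_table(desc, out / "report_descriptives.csv")

    comparison = compare_frs_by_mac(merged["frs"].to_numpy(), merged["truth_elevated"].to_numpy())
    regression = regress_frs_on_logmac(merged["frs"].to_numpy(), merged["truth_mac_mean"].to_numpy())
    report = pd.DataFrame([
        {"quantity": "frs_mean_elevated", "value": comparison.means[0]},
        {"quantity": "frs_mean_normal", "value": comparison.means[1]},
        {"quantity": "rank_sum_p", "value": comparison.p_value},
        {"quantity": "welch_t_p", "value": comparison.secondary_p_value},
        {"quantity": "ols_intercept", "value": regression.intercept},
        {"quantity": "ols_slope", "value": regression.slope},
        {"quantity": "ols_slope_p", "value": regression.p_value},
        {"quantity": "ols_r_squared", "value": regression.r_squared},
    ])
    write_table(report, out / "report_association.csv")

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "cohort_n": cohort_n,
        "slices_per_level": slices_per_level,
        "rows": {
            "metrics": int(len(metrics)),
            "cohort": int(len(cohort)),
            "framingham": int(len(scored)),
        },
        "imputation_rule_counts": rule_counts,
        "started": started,
        "finished": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
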