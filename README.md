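# aortamac

Quantification of abdominal aortic calcification from axial CT, and its
relation to cardiovascular risk scores.

Routine abdominal CT contains an unused cardiovascular signal: calcified
plaque in the wall of the descending aorta. `aortamac` implements a
vertebral-indexed (L1–L4) calcification scoring pipeline for such scans —
aimed at body-composition / opportunistic-screening researchers — together
with the synthetic phantoms and cohorts needed to validate every step when
clinical images cannot be shared.

## Method

**Dynamic-threshold detection.** On each axial slice a central lumen
sampling zone gives blood-pool statistics (μ_ref, σ_ref) in Hounsfield
units. Calcification is every 8-connected region of vessel-wall pixels with

&nbsp;&nbsp;&nbsp;&nbsp;HU > μ_ref + 5 σ_ref.

Because the cutoff rides on the lumen itself, detection is invariant to
intravenous contrast: enhancing the blood pool raises μ_ref and the
threshold together while plaque attenuation stays put.

**Wall unfurling and the MAC score.** Each slice's wall is unfurled about
the vessel centroid into angular bins; a bin is occluded when a calcified
pixel's angular footprint covers its center. The MAC (morphomic aortic
calcification) score at a vertebral level is the calcified percentage of the
unfurled wall surface (Σ occluded-bin arc length × slice thickness over
Σ circumference × thickness). MAC is *elevated* when L3 or L4 strictly
exceeds 4.21 % (maximum-sensitivity calibration) or 12.93 % (balanced
calibration).

**Framingham risk points.** Sex-specific general-CVD point tables (lipid
arm, or the office/BMI arm when lipids are unavailable), shipped as a
versioned CSV, with seven conservative imputation rules for incomplete
records (missing smoking → never; missing diabetes → none; missing SBP →
0-point component; missing lipids → BMI arm; missing BMI → lowest band;
missing BP-medication status → midpoint of treated/untreated points;
measurements older than 25 years → missing). Every imputed field carries a
provenance flag.

**Cohort statistics.** MAC is strongly zero-inflated (~70 % of participants
have none), so tables report mean (SD), median and the 90th percentile, and
regression uses log(MAC + 0.01). Elevated vs normal MAC groups are compared
by Wilcoxon rank-sum (Welch t secondary); FRS is regressed on log-MAC by
OLS.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
inputs (phantom CT stack plus a 4 000-participant cohort):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_score_calcification.py
python analysis/03_framingham_scores.py
python analysis/04_cohort_analysis.py
```

Output from that exact sequence:

```
cohort: n=4000, zero-MAC fraction 0.702, elevated (L3/L4 > 4.21%) 0.228
...
max |detected - designed| level mean area: 0.0000 mm^2
scored 4000 participants: mean FRS 7.20, median 7.0, max 22.0
imputation rule firing fractions:
  rule_1: 0.4903
  rule_3: 0.1852
  rule_4: 0.7442
...
elevated-MAC mean FRS 9.00 vs normal 6.67 (rank-sum p = 6.98e-33)
OLS FRS ~ log(MAC+0.01): slope 0.363 (SE 0.025), intercept 8.17, R^2 0.051
```

Reading: detection recovers the designed plaque areas exactly (the phantom's
ground truth is its rasterized arc set); imputation rules fire at the rates
implied by the injected record missingness (e.g. rule 4 ≈ the 74.9 % lipid
missingness); and the analysis recovers the injected MAC–FRS association —
the cohort was generated with E[FRS] rising 0.34 points per log-unit MAC,
and the fitted slope of 0.363 (SE 0.025) covers it.

The same steps are available as one command:

```bash
aortamac run-all --out results/run --seed 1
```

with subcommands `simulate`, `score`, `framingham`, `analyze` for the
individual stages (see `aortamac --help`).

## Layout

```
src/aortamac/    phantom.py      synthetic CT phantoms with exact truth
                 cohort_sim.py   synthetic cohorts (missingness, zero-inflated
                                 MAC, injected FRS association)
                 calcium.py      dynamic-threshold detection + level metrics
                 wall.py         unfurling, wall area, MAC score, classification
                 framingham.py   risk points + imputation rules (+ data/ tables)
                 analysis.py     descriptives, group tests, regression, exclusions
                 io.py, cli.py, pipeline.py, plots.py
analysis/        numbered study drivers (simulate → score → FRS → statistics)
tests/           pytest suite, including end-to-end property checks
docs/methods.md  modelling assumptions, parameter choices, limitations
```
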