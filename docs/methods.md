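# Methods

## Detection model

A slice is a 2-D HU grid with pixel spacing (mm) and slice thickness (mm);
segmentation masks (full aorta cross-section and a central lumen sampling
zone, lumen ⊆ aorta) are inputs — the package performs no segmentation.
The lumen reference is the sample mean and SD (n−1 denominator) of HU over
the lumen zone; a zone of fewer than two pixels is a degenerate-reference
error. The calcification cutoff is μ_ref + 5 σ_ref. Candidate pixels are
those **strictly above** the cutoff ("above" is read as exceedance, so ties
are excluded) inside the search domain, by default the aorta minus the lumen
zone: excluding the reference zone prevents a contrast-bright blood pool
from self-triggering. A full-aorta search is available
(`search_domain="aorta"`). Components are labeled under 8-connectivity
(4-connectivity optional) and components smaller than `min_region_px`
(default 1, i.e. no size filter) are discarded. Region area is pixel count ×
pixel area, exactly, so Σ region areas always equals the mask count times
pixel area.

Per-level metrics: calcified area is the mean over the level's slices,
volume is Σ slice-area × thickness, mean attenuation is the mean HU over the
**full vessel mask** (the quantity is ambiguous between lumen-only,
wall-only and whole-vessel readings; whole-vessel is used and stated here so
downstream users can reinterpret). Participant-level values are unweighted
means over available levels; a participant with no labeled level is an
exclusion marker, not an exception. Slices without a vertebral label are
ignored.

## Wall unfurling and the MAC score

The wall is parameterized by angle about the aorta-mask centroid (degrees,
counter-clockwise from the image +x axis) and split into `n_bins` (default
360) equal bins. A bin is occluded when its center angle falls inside the
angular footprint of at least one calcified pixel, the footprint being the
pixel's center angle ± arctan(half pixel width / pixel radius). The
footprint rule matters: pixel *center* angles alone cannot densely cover 1°
bins at aortic radii (centers on a ring of radius r sit ~spacing/r apart, a
few degrees), so center-only binning would undercount occlusion roughly
two-fold; the footprint rule reproduces a 90° designed arc as 90–92 occluded
bins at the default geometry.

Slice circumference is the digital perimeter of the aorta mask: the Crofton
4-direction estimator scaled by pixel spacing for isotropic grids (within
~1 % of 2πr on discs of aortic caliber), falling back to marching-squares
contour length for anisotropic grids (a few percent high on discs). Level
wall area is Σ circumference × thickness — an unfurled-surface reading whose
magnitude (~10³ mm² per level) matches reported total-wall-area scales. The
level MAC score is the calcified share of that surface,
100 × Σ(occluded bins × bin arc length × thickness) / Σ(circumference ×
thickness), i.e. a whole-level surface ratio rather than a mean of per-slice
percentages. Elevation is strict exceedance at L3 or L4 only (4.21 %
sensitivity-calibrated threshold, 12.93 % balanced); with neither level
available the participant is unclassifiable (None).

## Framingham scoring

Sex-specific general-CVD point tables, lipid arm and office/BMI arm, stored
in `src/aortamac/data/framingham_points.csv` with a schema version; bands
are [lower, upper) and the outer bands extend to ±∞, so out-of-domain values
(e.g. age 18–29 or >75) fall in the terminal band rather than erroring.
Former smokers score as non-current (the tables carry a current-smoking flag
only). The seven imputation rules are applied in one pass with per-field
provenance (`observed` / `imputed_rule_k`); rule 3 pins the SBP component to
0 without fabricating a numeric SBP, rule 6 sets it to the exact midpoint of
treated/untreated points (half-integers are kept, never rounded), rule 4
switches the entire score to the BMI arm, and rule 7 demotes lipid/SBP
values older than 25 years to missing before the other rules run.
Imputation is idempotent, and age-point monotonicity holds over the whole
table domain. Scoring totals are deterministic table lookups; profiles
missing age or sex are unscorable and reported, not dropped.

## Synthetic phantoms

A phantom slice is background (−50 HU) holding a lumen disc (Gaussian HU,
default mean 200 enhanced / 40 unenhanced, SD 10), a noise-free soft-tissue
wall annulus (40 HU), and calcified annulus sectors overwritten with a
constant plaque HU that must exceed μ + 5σ by construction. Rasterization is
pixel-center membership, making the designed pixel set the exact ground
truth; the noise-free wall means the detector should recover it pixel for
pixel. Defaults — 128×128 grid, 0.5 mm pixels, 12 mm lumen radius, 3 mm
wall, 5 mm slices — were chosen from a geometric analysis of angular
rasterization overshoot (±arctan(half-pixel/radius) ≈ ±1.2° per arc end at
this scale) so designed arc angles are reproduced within the binning
tolerances quoted above, while remaining anatomically plausible for the
abdominal aorta. Phantoms emulate contrast phase only through the lumen
mean; no beam hardening, partial-volume effects, or anatomic variability
(tortuosity, bifurcation) are modeled — phantom-based tests validate the
*geometry and thresholding logic*, not robustness to real CT physics.

## Synthetic cohorts

Defaults encode the study conditions the analysis assumes: n as requested,
male fraction 0.659, age ~ Normal(41.6, 18.4) truncated to [18, 91],
missingness BMI 26.54 %, HDL/total cholesterol 74.91 % (drawn comonotonically
— one lab panel — so the BMI-arm switch fires at ≈74.9 %, not the ~94 % that
independent draws would give), SBP 19.22 %, smoking 48.12 %; zero-MAC
fraction 0.696. Positive MAC at the L3 index level is lognormal(μ=2.3,
σ=1.18) capped at 95 %, scaled per level by (L1, L2, L3, L4) =
(0.30, 0.55, 1.00, 0.97) to reproduce the inferior-greater-than-superior
gradient; these shape parameters are configuration, not claims — the true
joint law of the emulated population is unknown, and with the defaults the
emergent elevated fraction is ≈0.23.

The injected association is E[FRS | MAC] = age points + intercept +
slope × log(mac_mean + 0.01), defaults intercept 3.0 (placing mean FRS near
6.5) and slope 0.34 points per log-unit. Because the non-age Framingham
total is an integer from a pattern-dependent achievable set A (missing SBP
pins its component; missing lipids restrict to BMI points; etc.), sampling a
continuous target and rounding/clamping onto A would attenuate the slope.
Instead, per missingness pattern the generator tabulates A, computes
h(m) = E[nearest_A(m + ε)] for ε ~ Normal(0, noise_sd = 2 points) on a grid,
and draws the latent mean at m = h⁻¹(target), so the delivered totals have
the requested conditional mean by construction (verified unbiased to within
sampling error over 60 seeds). Covariate values are then sampled uniformly
inside the bands realizing each delivered component, so re-scoring the
emitted table through the Framingham module returns exactly the delivered
points. Caveat: covariate *marginals* other than age/sex/missingness are a
by-product of this construction, not calibrated targets.

## Statistics

Descriptives report n, mean, SD, median and 90th percentile per stratum
(sex, vertebral level, or age bands 18–40, 40–49, …, 80+), with missing
values excluded per variable; quantiles use linear interpolation between
order statistics. The elevated/normal FRS comparison is a two-sided
Mann–Whitney rank-sum test (the groups are independent) with Welch t as
secondary; the association is OLS of FRS on log(MAC + 0.01). The exclusion
filter removes minors, aortic-stent carriers and participants without
abdominal levels from flag columns and returns a ledger satisfying
rows_in = rows_out + unique exclusions. The missing-SBP sensitivity analysis
is a row filter (`--drop-missing-sbp`), not a separate pipeline.

## Problem sizes and numerical choices

Test and verification runs use 128×128 grids, 50–100 random phantoms,
cohorts of 400–4000, 20 seeds for slope recovery, and 500 replicates for
null calibration — sizes at which every stochastic check has comfortable
power while the whole suite stays interactive. Determinism: every stochastic
component takes a single integer seed through `numpy.random.default_rng`;
identical seed and spec give byte-identical phantoms, cohorts and pipeline
outputs (manifest timestamps aside). Degenerate inputs are typed errors
(empty lumen zone, empty aorta mask, zero wall area, zero-variance
regressor) or explicit markers (missing level → None, unclassifiable
participant → None) as listed in `errors.py`.

## Known limitations

* Masks are trusted inputs; no segmentation or mask-quality checks.
* Per-slice angular model only — no 3-D wall surface reconstruction; wall
  area from circumference × thickness ignores through-plane obliquity.
* The office/BMI-arm point model is one published formulation among several
  Framingham variants; the shipped CSV makes the choice auditable and
  swappable.
* No Agatston/mass scoring, no pooled-cohort (ASCVD 2013) equations, no
  10-year risk-probability conversion, and no contrast-phase confounding
  correction — out of scope by design.
* Synthetic cohorts validate the pipeline's statistical machinery, not
  epidemiological claims: passing tests show the code recovers what was
  injected under the stated missingness and zero-inflation, nothing more.
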