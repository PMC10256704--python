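"""Synthetic participant cohorts with controlled MAC-FRS structure.

The generator emulates the statistical shape the analysis assumes from an
electronic-record trauma cohort:

* zero-inflated MAC: a point mass of participants with no detectable
  calcification (default 69.6 %), the rest right-skewed (lognormal);
* record missingness per covariate (defaults: BMI 26.54 %, HDL and total
  cholesterol 74.91 % — drawn jointly, as one lab panel — systolic BP
  19.22 %, smoking 48.12 %);
* an injected linear association: E[FRS | MAC] = age points +
  frs_intercept + frs_mac_slope * log(mac + 0.01).

The last point is the delicate one. The Framingham total is an integer sum
of banded components, and which components are adjustable depends on the
participant's missingness pattern (missing lipids force the BMI variant,
missing SBP pins that component to 0, ...). Sampling a continuous target
and rounding/clamping it onto the achievable point set would attenuate the
injected slope. Instead, for every missingness pattern the generator
tabulates the achievable set A of non-age point totals, computes the mean
delivery map h(m) = E[nearest_A(m + noise)], and draws the latent target at
m = h^{-1}(intercept + slope * log(mac + 0.01)). Delivered totals are then
nearest-achievable, and the conditional mean of the delivered score is the
requested linear function by construction. Covariates are finally sampled
uniformly inside the bands realizing each delivered component, so re-scoring
the emitted table through the Framingham module reproduces the delivered
points exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .framingham import _band_points, _bands, _flag_points

#: Per-level MAC as a multiple of the participant's L3 (index) value.
LEVEL_SCALE = {"L1": 0.30, "L2": 0.55, "L3": 1.00, "L4": 0.97}

#: Sampling ranges for the open-ended outer bands of each covariate.
_EDGE = {
    "sbp": (95.0, 200.0),
    "total_chol": (100.0, 340.0),
    "hdl": (20.0, 90.0),
    "bmi": (17.0, 45.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n: int = 2000
    sex_fraction_male: float = 0.659
    age_distribution: tuple[float, float] = (41.6, 18.4)  # mean, sd (years)
    age_bounds: tuple[float, float] = (18.0, 91.0)
    missingness: dict[str, float] = field(
        default_factory=lambda: {
            "bmi": 0.2654,
            "hdl": 0.7491,
            "total_chol": 0.7491,
            "sbp": 0.1922,
            "smoking": 0.4812,
        }
    )
    zero_mac_fraction: float = 0.696
    #: family + parameters of the MAC>0 law for the L3 index value (% wall)
    mac_positive_distribution: tuple[str, float, float] = ("lognormal", 2.3, 1.18)
    frs_mac_slope: float = 0.34  # points per log-unit MAC
    frs_intercept: float = 3.0  # expected non-age points at mac_mean = 1 %
    noise_sd: float = 2.0  # points
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise InputError("n must be at least 1")
        fracs = [self.sex_fraction_male, self.zero_mac_fraction, *self.missingness.values()]
        if any(not 0 <= f <= 1 for f in fracs):
            raise InputError("all fractions must lie in [0, 1]")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")


# -- achievable point sets per missingness pattern ---------------------------


def _component_options(sex: str, smoking_obs: bool, sbp_obs: bool,
                       lipids_obs: bool, bmi_obs: bool):
    """Choice list per component: (points, covariate recipe)."""
    smoke = [(0.0, {"smoker": "noncurrent"})]
    if smoking_obs:
        smoke.append((float(_flag_points("smoking", sex, "current")), {"smoker": "current"}))

    diab = [(0.0, {"diabetes": "no"}),
            (float(_flag_points("diabetes", sex, "yes")), {"diabetes": "yes"})]

    if sbp_obs:
        sbp = []
        for treated in (0, 1):
            lowers, points = _bands("sbp", sex, treated)
            for lo, pts in zip(lowers, points):
                sbp.append((float(pts), {"sbp_band": float(lo), "bp_treated": "yes" if treated else "no"}))
    else:
        sbp = [(0.0, {"sbp_band": None, "bp_treated": "no"})]

    if lipids_obs:
        lip = []
        tc_lo, tc_pts = _bands("total_chol", sex)
        h_lo, h_pts = _bands("hdl", sex)
        for (tlo, tp), (hlo, hp) in itertools.product(zip(tc_lo, tc_pts), zip(h_lo, h_pts)):
            lip.append((float(tp + hp), {"tc_band": float(tlo), "hdl_band": float(hlo)}))
    elif bmi_obs:
        b_lo, b_pts = _bands("bmi", sex)
        lip = [(float(p), {"bmi_band": float(lo)}) for lo, p in zip(b_lo, b_pts)]
    else:
        lip = [(0.0, {"bmi_band": None})]

    return [smoke, diab, sbp, lip]


def _achievable(sex: str, smoking_obs: bool, sbp_obs: bool, lipids_obs: bool, bmi_obs: bool):
    """Sorted achievable totals and one canonical covariate recipe per total."""
    options = _component_options(sex, smoking_obs, sbp_obs, lipids_obs, bmi_obs)
    recipes: dict[float, dict] = {}
    for combo in itertools.product(*options):
        total = round(sum(c[0] for c in combo), 6)
        if total not in recipes:
            merged: dict = {}
            for _, rec in combo:
                merged.update(rec)
            recipes[total] = merged
    totals = np.array(sorted(recipes), dtype=float)
    return totals, recipes


def _delivery_grid(totals: np.ndarray, noise_sd: float):
    """Grid of m vs h(m) = E[nearest(totals, m + N(0, noise_sd))]."""
    mids = (totals[:-1] + totals[1:]) / 2.0
    lo = totals[0] - 4.0 * noise_sd - 2.0
    hi = totals[-1] + 4.0 * noise_sd + 2.0
    m = np.arange(lo, hi, 0.05)
    if noise_sd == 0:
        h = totals[np.searchsorted(mids, m)]
        return m, h
    z = (mids[None, :] - m[:, None]) / noise_sd
    cdf = stats.norm.cdf(z)
    probs = np.diff(np.concatenate([np.zeros((m.size, 1)), cdf, np.ones((m.size, 1))], axis=1), axis=1)
    return m, probs @ totals


def _sample_in_band(rng, lowers: np.ndarray, band_lo: float, name: str, size: int):
    """Uniform values inside [band_lo, next band edge), outer edges bounded."""
    lo_bound, hi_bound = _EDGE[name]
    idx = np.searchsorted(lowers, band_lo)
    lo = band_lo if np.isfinite(band_lo) else lo_bound
    hi = lowers[idx + 1] if idx + 1 < lowers.size else hi_bound
    return rng.uniform(lo, hi - 1e-6, size)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort table; identical spec + seed is bit-identical.

    Truth columns are prefixed ``truth_``; covariate cells are NaN/empty when
    missing from the simulated record.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    sex = np.where(rng.random(n) < spec.sex_fraction_male, "male", "female")
    mu, sd = spec.age_distribution
    lo, hi = spec.age_bounds
    age = stats.truncnorm.rvs((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd,
                              size=n, random_state=rng)

    # zero-inflated MAC (L3 index value, % of wall)
    family, p1, p2 = spec.mac_positive_distribution
    if family != "lognormal":
        raise InputError(f"unsupported MAC distribution family {family!r}")
    zero = rng.random(n) < spec.zero_mac_fraction
    idx_mac = np.where(zero, 0.0, np.minimum(rng.lognormal(p1, p2, n), 95.0))
    levels = {lv: idx_mac * s for lv, s in LEVEL_SCALE.items()}
    mac_mean = np.mean([levels[lv] for lv in LEVEL_SCALE], axis=0)
    log_mac = np.log(mac_mean + 0.01)
    elevated = (levels["L3"] > 4.21) | (levels["L4"] > 4.21)

    # missingness flags (lipid panel drawn jointly: one lab, two analytes)
    miss = {}
    miss["lipids"] = rng.random(n) < spec.missingness.get("hdl", 0.0)
    miss["bmi"] = rng.random(n) < spec.missingness.get("bmi", 0.0)
    miss["sbp"] = rng.random(n) < spec.missingness.get("sbp", 0.0)
    miss["smoking"] = rng.random(n) < spec.missingness.get("smoking", 0.0)

    eps = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else np.zeros(n)
    former_draw = rng.random(n)  # split never/former among non-current smokers
    cov_draw = rng  # band-interior sampling below continues the same stream

    target = spec.frs_intercept + spec.frs_mac_slope * log_mac

    cols = {
        "sbp": np.full(n, np.nan), "total_chol": np.full(n, np.nan),
        "hdl": np.full(n, np.nan), "bmi": np.full(n, np.nan),
        "bp_treated": np.full(n, None, dtype=object),
        "smoker": np.full(n, None, dtype=object),
        "diabetes": np.full(n, None, dtype=object),
    }
    expected_nonage = np.zeros(n)

    patterns = list(zip(sex, ~miss["smoking"], ~miss["sbp"], ~miss["lipids"], ~miss["bmi"]))
    order = {}
    for i, pat in enumerate(patterns):
        order.setdefault(pat, []).append(i)

    for pat in sorted(order):
        sx, smoking_obs, sbp_obs, lipids_obs, bmi_obs = pat
        members = np.array(order[pat])
        totals, recipes = _achievable(sx, smoking_obs, sbp_obs, lipids_obs, bmi_obs)
        m_grid, h_grid = _delivery_grid(totals, spec.noise_sd)
        y = np.clip(target[members], h_grid[0] + 1e-9, h_grid[-1] - 1e-9)
        m = np.interp(y, h_grid, m_grid)
        mids = (totals[:-1] + totals[1:]) / 2.0
        delivered = totals[np.searchsorted(mids, m + eps[members])]
        expected_nonage[members] = y

        lowers = {name: _bands(name, sx)[0] for name in ("total_chol", "hdl")}
        lowers["bmi"] = _bands("bmi", sx)[0]
        sbp_lowers = _bands("sbp", sx, 0)[0]
        for i, tot in zip(members, delivered):
            rec = recipes[float(tot)]
            cols["smoker"][i] = (
                None if not smoking_obs
                else "current" if rec["smoker"] == "current"
                else ("former" if former_draw[i] < 0.35 else "never")
            )
            cols["diabetes"][i] = rec["diabetes"]
            if sbp_obs:
                cols["bp_treated"][i] = rec["bp_treated"]
                cols["sbp"][i] = _sample_in_band(cov_draw, sbp_lowers, rec["sbp_band"], "sbp", 1)[0]
            else:
                cols["bp_treated"][i] = rec["bp_treated"]
            if lipids_obs:
                cols["total_chol"][i] = _sample_in_band(cov_draw, lowers["total_chol"], rec["tc_band"], "total_chol", 1)[0]
                cols["hdl"][i] = _sample_in_band(cov_draw, lowers["hdl"], rec["hdl_band"], "hdl", 1)[0]
            elif bmi_obs:
                cols["bmi"][i] = _sample_in_band(cov_draw, lowers["bmi"], rec["bmi_band"], "bmi", 1)[0]

    # BMI is recorded whenever observed, even for lipid-variant participants
    lipid_and_bmi = ~miss["lipids"] & ~miss["bmi"]
    if lipid_and_bmi.any():
        k = int(lipid_and_bmi.sum())
        cols["bmi"][lipid_and_bmi] = cov_draw.uniform(18.0, 40.0, k)

    age_pts = np.array([_band_points("age", s, a) for s, a in zip(sex, age)])

    df = pd.DataFrame({
        "participant_id": np.arange(n),
        "age": age,
        "sex": sex,
        "bmi": cols["bmi"],
        "total_chol": cols["total_chol"],
        "hdl": cols["hdl"],
        "sbp": cols["sbp"],
        "bp_treated": cols["bp_treated"],
        "smoker": cols["smoker"],
        "diabetes": cols["diabetes"],
        "measurement_age_gap": np.zeros(n),
        **{f"truth_mac_{lv.lower()}": levels[lv] for lv in ("L1", "L2", "L3", "L4")},
        "truth_mac_mean": mac_mean,
        "truth_log_mac": log_mac,
        "truth_elevated": elevated,
        "truth_frs_expected": age_pts + expected_nonage,
    })
    return df
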