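"""Framingham general-CVD risk points with conservative missing-data rules.

Scores use the sex-specific general cardiovascular risk point tables
(D'Agostino-style office/BMI arm when lipids are unavailable), shipped as a
versioned CSV so every band and point value is auditable.

Electronic-record extracts are rarely complete, so scoring applies seven
conservative imputation rules, each leaving a provenance flag:

1. missing smoking status -> never smoker;
2. missing diabetes status -> no diabetes;
3. missing systolic blood pressure -> the SBP point component is fixed to 0
   (the points a 120-130 mmHg untreated reading would earn), no numeric SBP
   is fabricated;
4. missing total or HDL cholesterol -> the whole score switches to the
   BMI-based variant;
5. missing BMI -> the lowest BMI band (<25, zero points);
6. missing BP-medication status -> the SBP component is the midpoint of the
   treated and untreated points (half-integers possible, never rounded);
7. lipid/SBP measurements taken more than 25 years before the scan are
   treated as missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .errors import UnscorableProfileError

MAX_MEASUREMENT_GAP_YEARS = 25.0

SEXES = ("female", "male")


@dataclass(frozen=True)
class RiskProfile:
    """Covariates as extracted from the record; None marks a missing value."""

    age: float
    sex: str
    total_chol: float | None = None
    hdl: float | None = None
    sbp: float | None = None
    bp_treated: str | None = None  # "yes" / "no" / None
    smoker: str | None = None  # "current" / "former" / "never" / None
    diabetes: str | None = None  # "yes" / "no" / None
    bmi: float | None = None
    measurement_age_gap: float = 0.0  # years from lab measurement to CT

    def __post_init__(self):
        if self.sex not in SEXES:
            raise UnscorableProfileError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age is None or not math.isfinite(self.age):
            raise UnscorableProfileError("age is required for scoring")
        for name in ("total_chol", "hdl", "sbp", "bmi"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v <= 0):
                raise UnscorableProfileError(f"{name} must be positive and finite")


@dataclass(frozen=True)
class ImputedProfile:
    """A scoreable profile: every component resolvable, with provenance.

    ``provenance`` maps each field to ``observed`` or ``imputed_rule_<k>``.
    Under rule 3 ``sbp`` stays None and the SBP component is pinned to 0;
    under rule 6 ``bp_treated`` stays None and the SBP component is the
    treated/untreated midpoint — both encoded by the provenance flags rather
    than by fabricated values.
    """

    age: float
    sex: str
    variant: str  # "lipid" or "bmi"
    total_chol: float | None
    hdl: float | None
    sbp: float | None
    bp_treated: str | None
    smoker: str
    diabetes: str
    bmi: float | None
    provenance: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class FraminghamResult:
    total_points: float
    component_points: dict[str, float]
    variant: str


@lru_cache(maxsize=1)
def points_table() -> pd.DataFrame:
    """The versioned points table shipped with the package."""
    with resources.files("aortamac").joinpath("data/framingham_points.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    df["lower"] = df["lower"].fillna(-np.inf)
    df["upper"] = df["upper"].fillna(np.inf)
    return df


@lru_cache(maxsize=None)
def _bands(component: str, sex: str, treated: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sorted band lower edges and their point values, for fast lookup."""
    df = points_table()
    sel = (df["component"] == component) & (df["sex"] == sex)
    if treated is not None:
        sel &= df["treated"] == treated
    rows = df[sel].sort_values("lower")
    if not len(rows):
        raise UnscorableProfileError(f"no point bands for {component} (sex={sex})")
    # bands must tile the line: each upper edge is the next lower edge
    uppers = rows["upper"].to_numpy()
    lowers = rows["lower"].to_numpy(dtype=float)
    if not (np.all(uppers[:-1] == lowers[1:]) and uppers[-1] == np.inf):
        raise UnscorableProfileError(f"point bands for {component}/{sex} do not tile")
    return lowers, rows["points"].to_numpy(dtype=float)


def _band_points(component: str, sex: str, value: float, variant: str | None = None,
                 treated: int | None = None) -> float:
    lowers, points = _bands(component, sex, treated)
    idx = int(np.searchsorted(lowers, value, side="right")) - 1
    return float(points[max(idx, 0)])


@lru_cache(maxsize=None)
def _flag_points(component: str, sex: str, category: str) -> int:
    df = points_table()
    rows = df[(df["component"] == component) & (df["sex"] == sex)]
    hit = rows[rows["category"] == category]
    return int(hit["points"].iloc[0]) if len(hit) else 0


def impute_profile(p: RiskProfile | ImputedProfile) -> ImputedProfile:
    """Apply rules 1-7 and record per-field provenance. Idempotent."""
    if isinstance(p, ImputedProfile):
        return replace(p, provenance=dict(p.provenance))

    prov: dict[str, str] = {}
    stale = p.measurement_age_gap > MAX_MEASUREMENT_GAP_YEARS

    total_chol, hdl, sbp = p.total_chol, p.hdl, p.sbp
    if stale:
        # rule 7: measurements too far from the scan do not count as observed
        if total_chol is not None or hdl is not None:
            total_chol = hdl = None
            prov["lipids_stale"] = "imputed_rule_7"
        if sbp is not None:
            sbp = None
            prov["sbp_stale"] = "imputed_rule_7"

    if p.smoker is None:
        smoker, prov["smoker"] = "never", "imputed_rule_1"
    else:
        smoker, prov["smoker"] = p.smoker, "observed"

    if p.diabetes is None:
        diabetes, prov["diabetes"] = "no", "imputed_rule_2"
    else:
        diabetes, prov["diabetes"] = p.diabetes, "observed"

    prov["sbp"] = "observed" if sbp is not None else "imputed_rule_3"
    if p.bp_treated is None:
        # rule 6; when SBP is itself missing the midpoint is moot (rule 3
        # pins the component to 0) but the provenance still records the gap
        bp_treated, prov["bp_treated"] = None, "imputed_rule_6"
    else:
        bp_treated, prov["bp_treated"] = p.bp_treated, "observed"

    if total_chol is None or hdl is None:
        variant = "bmi"
        prov["lipids"] = "imputed_rule_4"
        if p.bmi is None:
            bmi, prov["bmi"] = None, "imputed_rule_5"  # band "<25", zero points
        else:
            bmi, prov["bmi"] = p.bmi, "observed"
    else:
        variant = "lipid"
        prov["lipids"] = "observed"
        bmi = p.bmi

    return ImputedProfile(
        age=p.age,
        sex=p.sex,
        variant=variant,
        total_chol=total_chol,
        hdl=hdl,
        sbp=sbp,
        bp_treated=bp_treated,
        smoker=smoker,
        diabetes=diabetes,
        bmi=bmi,
        provenance=prov,
    )


def _sbp_component(p: ImputedProfile) -> float:
    if p.provenance.get("sbp") == "imputed_rule_3" or p.sbp is None:
        return 0.0
    untreated = _band_points("sbp", p.sex, p.sbp, treated=0)
    treated = _band_points("sbp", p.sex, p.sbp, treated=1)
    if p.provenance.get("bp_treated") == "imputed_rule_6" or p.bp_treated is None:
        return (treated + untreated) / 2.0
    return float(treated if p.bp_treated == "yes" else untreated)


def framingham_points(p: ImputedProfile) -> FraminghamResult:
    """Sex-specific point total; deterministic table lookups only."""
    comp: dict[str, float] = {}
    comp["age"] = float(_band_points("age", p.sex, p.age))
    if p.variant == "lipid":
        comp["lipids_or_bmi"] = float(
            _band_points("total_chol", p.sex, p.total_chol, variant="lipid")
            + _band_points("hdl", p.sex, p.hdl, variant="lipid")
        )
    else:
        comp["lipids_or_bmi"] = (
            0.0 if p.bmi is None else float(_band_points("bmi", p.sex, p.bmi, variant="bmi"))
        )
    comp["sbp"] = _sbp_component(p)
    comp["smoking"] = float(_flag_points("smoking", p.sex, p.smoker)) if p.smoker == "current" else 0.0
    comp["diabetes"] = float(_flag_points("diabetes", p.sex, p.diabetes)) if p.diabetes == "yes" else 0.0
    return FraminghamResult(
        total_points=float(sum(comp.values())),
        component_points=comp,
        variant=p.variant,
    )


def score_profile(p: RiskProfile) -> tuple[ImputedProfile, FraminghamResult]:
    imp = impute_profile(p)
    return imp, framingham_points(imp)


_RULE_FLAGS = [f"imputed_rule_{k}" for k in range(1, 8)]


def score_cohort(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Score a cohort table row by row.

    Expects columns age, sex, total_chol, hdl, sbp, bp_treated, smoker,
    diabetes, bmi (empty cells = missing) and optionally
    measurement_age_gap. Returns a row-aligned results frame (with
    ``unscorable`` True where age or sex is unusable) and a summary of how
    often each imputation rule fired.
    """
    rule_counts = {flag: 0 for flag in _RULE_FLAGS}
    records = []
    for row in df.itertuples(index=False):
        rec = {
            "total_points": np.nan,
            "variant": None,
            "unscorable": False,
            **{f"rule_{k}": False for k in range(1, 8)},
        }
        try:
            profile = RiskProfile(
                age=_num(getattr(row, "age", None)),
                sex=getattr(row, "sex", None),
                total_chol=_num(getattr(row, "total_chol", None)),
                hdl=_num(getattr(row, "hdl", None)),
                sbp=_num(getattr(row, "sbp", None)),
                bp_treated=_cat(getattr(row, "bp_treated", None)),
                smoker=_cat(getattr(row, "smoker", None)),
                diabetes=_cat(getattr(row, "diabetes", None)),
                bmi=_num(getattr(row, "bmi", None)),
                measurement_age_gap=_num(getattr(row, "measurement_age_gap", 0.0)) or 0.0,
            )
            imp, res = score_profile(profile)
        except (UnscorableProfileError, TypeError):
            rec["unscorable"] = True
            records.append(rec)
            continue
        rec["total_points"] = res.total_points
        rec["variant"] = res.variant
        for flag in set(imp.provenance.values()):
            if flag in rule_counts:
                rule_counts[flag] += 1
                rec[f"rule_{flag[-1]}"] = True
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    summary = {f"rule_{k}": rule_counts[f"imputed_rule_{k}"] for k in range(1, 8)}
    summary["unscorable"] = int(out["unscorable"].sum()) if len(out) else 0
    return out, summary


def _num(v):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def _cat(v):
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return str(v)
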