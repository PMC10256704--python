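"""Cohort-level statistics for zero-inflated calcification measurements.

With roughly 70 % of participants showing no detectable calcification, the
medians of MAC metrics are 0 and quartiles are uninformative; descriptive
tables therefore report mean (SD), median, and the 90th percentile, and the
MAC variable enters regression as log(MAC + 0.01).

The two-group FRS comparison uses the two-sample Wilcoxon rank-sum
(Mann-Whitney) test as primary — the comparison is between independent
elevated/normal groups — with a Welch t-test as a secondary check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .errors import AnalysisError

AGE_BINS = [18, 40, 50, 60, 70, 80, np.inf]
AGE_LABELS = ["18-40", "40-49", "50-59", "60-69", "70-79", "80+"]


@dataclass(frozen=True)
class GroupComparison:
    groups: tuple[str, str]
    means: tuple[float, float]
    medians: tuple[float, float]
    test: str
    statistic: float
    p_value: float
    secondary_test: str
    secondary_p_value: float


@dataclass(frozen=True)
class RegressionResult:
    intercept: float
    slope: float
    slope_se: float
    p_value: float
    r_squared: float
    n: int


def log_mac(mac_pct) -> np.ndarray | float:
    """Natural log of (MAC percent + 0.01); the offset admits exact zeros."""
    arr = np.asarray(mac_pct, dtype=float)
    if np.any(arr < 0):
        raise AnalysisError("MAC percent cannot be negative")
    out = np.log(arr + 0.01)
    return float(out) if np.isscalar(mac_pct) or arr.ndim == 0 else out


def _p90(x: np.ndarray) -> float:
    # linear interpolation between order statistics (numpy default rule)
    return float(np.percentile(x, 90))


def describe(
    df: pd.DataFrame,
    continuous: list[str],
    categorical: list[str] | None = None,
    strata: str | None = None,
) -> pd.DataFrame:
    """Per-stratum descriptive rows: n, mean, SD, median, 90th percentile.

    ``strata`` may be a column name ("sex", "level", ...) or "age" for the
    standard age bands. Missing values are excluded per variable with the
    remaining n reported; categoricals get count and percent per category.
    """
    work = df.copy()
    if strata is None:
        work["_stratum"] = "all"
    elif strata == "age":
        if "age" not in work.columns:
            raise AnalysisError("age stratification requires an 'age' column")
        work["_stratum"] = pd.cut(work["age"], AGE_BINS, labels=AGE_LABELS, right=False)
    elif strata in work.columns:
        work["_stratum"] = work[strata]
    else:
        raise AnalysisError(f"unknown stratum {strata!r}")

    rows = []
    for stratum, grp in work.groupby("_stratum", observed=True):
        for var in continuous:
            vals = grp[var].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                rows.append({"stratum": stratum, "variable": var, "n": 0})
                continue
            rows.append({
                "stratum": stratum, "variable": var, "n": int(vals.size),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "median": float(np.median(vals)),
                "p90": _p90(vals),
            })
        for var in categorical or []:
            vals = grp[var].dropna()
            for cat, cnt in vals.value_counts().items():
                rows.append({
                    "stratum": stratum, "variable": f"{var}={cat}",
                    "n": int(vals.size), "count": int(cnt),
                    "percent": 100.0 * cnt / len(vals),
                })
    return pd.DataFrame(rows)


def compare_frs_by_mac(frs: np.ndarray, elevated: np.ndarray) -> GroupComparison:
    """Rank-sum comparison of FRS between elevated- and normal-MAC groups."""
    frs = np.asarray(frs, dtype=float)
    elevated = np.asarray(elevated, dtype=bool)
    a, b = frs[elevated], frs[~elevated]
    if a.size == 0 or b.size == 0:
        raise AnalysisError("both MAC groups must be non-empty for comparison")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    _, p_t = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        groups=("elevated", "normal"),
        means=(float(a.mean()), float(b.mean())),
        medians=(float(np.median(a)), float(np.median(b))),
        test="wilcoxon_rank_sum",
        statistic=float(stat),
        p_value=float(p),
        secondary_test="welch_t",
        secondary_p_value=float(p_t),
    )


def regress_frs_on_logmac(frs: np.ndarray, mac_pct: np.ndarray) -> RegressionResult:
    """OLS of FRS on log(MAC + 0.01)."""
    frs = np.asarray(frs, dtype=float)
    x = log_mac(np.asarray(mac_pct, dtype=float))
    ok = np.isfinite(frs) & np.isfinite(x)
    frs, x = frs[ok], x[ok]
    if frs.size < 3:
        raise AnalysisError("need at least 3 complete pairs for regression")
    if np.ptp(x) == 0:
        raise AnalysisError("degenerate predictor: log-MAC has zero variance")
    model = sm.OLS(frs, sm.add_constant(x)).fit()
    return RegressionResult(
        intercept=float(model.params[0]),
        slope=float(model.params[1]),
        slope_se=float(model.bse[1]),
        p_value=float(model.pvalues[1]),
        r_squared=float(model.rsquared),
        n=int(frs.size),
    )


def apply_exclusions(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Cohort entry filter: adults, no aortic stent, usable abdominal levels.

    Expects columns ``age`` and optional boolean flags ``stent`` and
    ``no_abdominal_levels``. Returns the filtered table and a ledger with
    per-criterion counts, the unique total, and a conservation check
    rows_in = rows_out + unique_excluded.
    """
    age_excl = df["age"] < 18 if "age" in df.columns else pd.Series(False, index=df.index)
    stent_excl = df["stent"].fillna(False).astype(bool) if "stent" in df.columns else pd.Series(False, index=df.index)
    scan_excl = (
        df["no_abdominal_levels"].fillna(False).astype(bool)
        if "no_abdominal_levels" in df.columns
        else pd.Series(False, index=df.index)
    )
    any_excl = age_excl | stent_excl | scan_excl
    ledger = {
        "rows_in": int(len(df)),
        "excluded_age_under_18": int(age_excl.sum()),
        "excluded_stent": int(stent_excl.sum()),
        "excluded_no_abdominal_levels": int(scan_excl.sum()),
        "excluded_unique": int(any_excl.sum()),
        "rows_out": int((~any_excl).sum()),
    }
    return df[~any_excl].copy(), ledger
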