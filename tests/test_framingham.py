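"""Framingham points and the seven conservative imputation rules.

The hand-scored bank below was computed manually from the published
sex-specific general-CVD point tables (lipid and office/BMI arms) and frozen
before the scorer ran against it.
"""

import numpy as np
import pandas as pd
import pytest

from aortamac.errors import UnscorableProfileError
from aortamac.framingham import (
    ImputedProfile,
    RiskProfile,
    _band_points,
    framingham_points,
    impute_profile,
    score_cohort,
    score_profile,
)

# (profile, expected total) — hand table lookups, lipid arm unless noted
HAND_SCORED = [
    (RiskProfile(52, "female", total_chol=210, hdl=48, sbp=125, bp_treated="no",
                 smoker="current", diabetes="no"), 13.0),
    (RiskProfile(61, "male", total_chol=150, hdl=62, sbp=118, bp_treated="no",
                 smoker="never", diabetes="yes"), 10.0),
    (RiskProfile(33, "female", total_chol=250, hdl=34, sbp=165, bp_treated="yes",
                 smoker="never", diabetes="no"), 13.0),
    (RiskProfile(45, "male", total_chol=185, hdl=41, sbp=142, bp_treated="yes",
                 smoker="current", diabetes="no"), 16.0),
    (RiskProfile(75, "female", total_chol=300, hdl=52, sbp=155, bp_treated="no",
                 smoker="current", diabetes="yes"), 27.0),
    (RiskProfile(80, "male", total_chol=239, hdl=45, sbp=160, bp_treated="no",
                 smoker="never", diabetes="no"), 20.0),
    # office/BMI arm (lipids absent -> rule 4)
    (RiskProfile(44, "female", bmi=27, sbp=128, bp_treated="no",
                 smoker="never", diabetes="no"), 5.0),
    (RiskProfile(57, "male", bmi=31, sbp=135, bp_treated="yes",
                 smoker="current", diabetes="yes"), 22.0),
    (RiskProfile(18, "female", bmi=24, sbp=119, bp_treated="no",
                 smoker="never", diabetes="no"), -3.0),
    (RiskProfile(39, "male", total_chol=160, hdl=50, sbp=120, bp_treated="no",
                 smoker="current", diabetes="no"), 6.0),
    (RiskProfile(59, "female", total_chol=159, hdl=35, sbp=150, bp_treated="no",
                 smoker="never", diabetes="no"), 13.0),
    # rules 1-3 together: missing SBP, smoking; diabetic male, BMI arm
    (RiskProfile(70, "male", bmi=24, diabetes="yes"), 17.0),
]


@pytest.mark.parametrize("profile,expected", HAND_SCORED)
def test_hand_scored_bank_matches_exactly(profile, expected):
    _, result = score_profile(profile)
    assert result.total_points == expected
    assert result.total_points == sum(result.component_points.values())


class TestImputationRules:
    def test_fully_observed_is_identity(self):
        p = HAND_SCORED[0][0]
        imp = impute_profile(p)
        assert all(v == "observed" for v in imp.provenance.values())
        assert (imp.total_chol, imp.hdl, imp.sbp) == (210, 48, 125)
        assert imp.variant == "lipid"

    def test_rules_1_and_2(self):
        imp = impute_profile(RiskProfile(50, "male", total_chol=200, hdl=50,
                                         sbp=130, bp_treated="no"))
        assert imp.smoker == "never" and imp.provenance["smoker"] == "imputed_rule_1"
        assert imp.diabetes == "no" and imp.provenance["diabetes"] == "imputed_rule_2"

    def test_rule_3_sbp_component_zero_regardless_of_treatment(self):
        for treated in ("yes", "no", None):
            p = RiskProfile(50, "female", total_chol=200, hdl=50,
                            bp_treated=treated, smoker="never", diabetes="no")
            imp, res = score_profile(p)
            assert imp.provenance["sbp"] == "imputed_rule_3"
            assert res.component_points["sbp"] == 0.0

    def test_rules_4_and_5_switch_to_bmi_variant(self):
        imp = impute_profile(RiskProfile(50, "female", hdl=50, sbp=130, bp_treated="no",
                                         smoker="never", diabetes="no"))
        assert imp.variant == "bmi"
        assert imp.provenance["lipids"] == "imputed_rule_4"
        assert imp.provenance["bmi"] == "imputed_rule_5"  # band "<25"
        _, res = score_profile(RiskProfile(50, "female", hdl=50, sbp=130, bp_treated="no",
                                           smoker="never", diabetes="no"))
        assert res.component_points["lipids_or_bmi"] == 0.0

    def test_rule_6_midpoint_and_bracketing(self):
        # female, SBP 135: untreated 1 point, treated 3 -> midpoint 2.0
        p = RiskProfile(50, "female", total_chol=200, hdl=50, sbp=135,
                        smoker="never", diabetes="no")
        imp, res = score_profile(p)
        assert imp.provenance["bp_treated"] == "imputed_rule_6"
        assert res.component_points["sbp"] == 2.0
        # bracketing holds across the whole SBP domain, both sexes
        for sex in ("female", "male"):
            for sbp in (100, 122, 133, 144, 155, 180):
                q = RiskProfile(50, sex, total_chol=200, hdl=50, sbp=sbp,
                                smoker="never", diabetes="no")
                mid = score_profile(q)[1].component_points["sbp"]
                lo = _band_points("sbp", sex, sbp, treated=0)
                hi = _band_points("sbp", sex, sbp, treated=1)
                assert min(lo, hi) <= mid <= max(lo, hi)

    def test_rule_6_can_produce_half_integer_total(self):
        # female 140-149 mmHg: untreated 2, treated 5 -> 3.5, total not rounded
        p = RiskProfile(50, "female", total_chol=200, hdl=50, sbp=144,
                        smoker="never", diabetes="no")
        _, res = score_profile(p)
        assert res.component_points["sbp"] == 3.5
        assert res.total_points % 1 == 0.5
        q = RiskProfile(50, "male", total_chol=200, hdl=50, sbp=125,
                        smoker="never", diabetes="no")
        assert score_profile(q)[1].component_points["sbp"] == 1.0  # (0 + 2) / 2

    def test_rule_7_stale_measurements_dropped(self):
        p = RiskProfile(50, "male", total_chol=200, hdl=50, sbp=130, bp_treated="no",
                        smoker="never", diabetes="no", bmi=26,
                        measurement_age_gap=26.0)
        imp, res = score_profile(p)
        assert imp.variant == "bmi"  # lipids no longer count as observed
        assert res.component_points["sbp"] == 0.0
        assert imp.provenance["lipids_stale"] == "imputed_rule_7"
        assert imp.provenance["sbp_stale"] == "imputed_rule_7"

    def test_idempotence(self):
        for p, _ in HAND_SCORED[:4] + HAND_SCORED[-2:]:
            once = impute_profile(p)
            twice = impute_profile(once)
            assert once == twice
            assert framingham_points(once) == framingham_points(twice)

    def test_provenance_complete(self):
        imp = impute_profile(RiskProfile(40, "female"))
        for fieldname in ("smoker", "diabetes", "sbp", "bp_treated", "lipids", "bmi"):
            flag = imp.provenance[fieldname]
            assert flag == "observed" or flag.startswith("imputed_rule_")

    def test_missing_age_or_sex_unscorable(self):
        with pytest.raises(UnscorableProfileError):
            RiskProfile(float("nan"), "male")
        with pytest.raises(UnscorableProfileError):
            RiskProfile(50, "unknown")


def test_age_points_monotone_over_table_domain():
    for sex in ("female", "male"):
        pts = [_band_points("age", sex, a) for a in range(18, 95)]
        assert all(a <= b for a, b in zip(pts, pts[1:]))


class TestCohortScoring:
    def test_all_complete_cohort_has_no_flags(self):
        df = pd.DataFrame([
            {"age": 52, "sex": "female", "total_chol": 210, "hdl": 48, "sbp": 125,
             "bp_treated": "no", "smoker": "current", "diabetes": "no", "bmi": 27},
        ] * 5)
        scored, counts = score_cohort(df)
        assert scored["total_points"].tolist() == [13.0] * 5
        assert all(v == 0 for v in counts.values())

    def test_empty_table(self):
        scored, counts = score_cohort(pd.DataFrame(columns=["age", "sex"]))
        assert len(scored) == 0 and counts["unscorable"] == 0

    def test_unscorable_rows_reported_not_dropped(self):
        df = pd.DataFrame([
            {"age": np.nan, "sex": "male"},
            {"age": 50, "sex": "male"},
        ])
        scored, counts = score_cohort(df)
        assert len(scored) == 2
        assert scored["unscorable"].tolist() == [True, False]
        assert counts["unscorable"] == 1

    def test_rule4_firing_fraction_matches_lipid_missingness(self):
        from aortamac.cohort_sim import CohortSpec, generate_cohort

        df = generate_cohort(CohortSpec(n=4000, seed=3))
        _, counts = score_cohort(df)
        frac = counts["rule_4"] / len(df)
        # binomial 3-sigma band around the lipid panel missingness
        assert abs(frac - 0.7491) <= 3 * np.sqrt(0.7491 * 0.2509 / len(df))
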