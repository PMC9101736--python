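"""Derived clinical quantities, indicator thresholds and the LEA
classifier."""

import itertools
import math

import numpy as np
import pytest

from leamq import (
    IndicatorProfile,
    ReferenceConfig,
    ValidationError,
    build_indicator_profile,
    classify_lea,
    cunningham_predicted_rmr,
    rmr_ratio,
    vermeulen_free_testosterone,
    weir_energy_expenditure,
)
from leamq.clinical import (
    INDICATORS,
    KA_ALBUMIN,
    KT_SHBG,
    ALBUMIN_MOLAR_MASS,
    MET,
    MISSING,
    NOT_MET,
    PRIMARY_INDICATORS,
)

#: reference without per-site ranges so the fixed fallback cutoffs apply
PLAIN_REF = ReferenceConfig(ranges={})


class TestDerivedQuantities:
    def test_weir_zero_and_hand_value(self):
        assert weir_energy_expenditure(0, 0) == 0
        # 3.941*0.25 + 1.106*0.20 = 1.2065 kcal/min = 5.048 kJ/min
        assert weir_energy_expenditure(0.25, 0.20) == pytest.approx(5.048, abs=5e-4)

    def test_weir_linearity_and_rq_warning(self):
        one = weir_energy_expenditure(0.3, 0.25)
        assert weir_energy_expenditure(0.6, 0.5) == pytest.approx(2 * one)
        with pytest.warns(UserWarning, match="respiratory quotient"):
            weir_energy_expenditure(0.3, 0.45)

    @pytest.mark.parametrize("ffm,expected", [(0.0, 500.0), (62.4, 1872.8), (73.6, 2119.2)])
    def test_cunningham_formula(self, ffm, expected):
        assert cunningham_predicted_rmr(ffm) == pytest.approx(expected)

    def test_rmr_ratio_identity_and_linearity(self):
        pred = cunningham_predicted_rmr(65.0)
        assert rmr_ratio(pred * 4.184, pred) == pytest.approx(1.0)
        assert rmr_ratio(pred * 4.184 / 2, pred) == pytest.approx(0.5)

    def test_rmr_ratio_warns_outside_plausible_band(self):
        with pytest.warns(UserWarning, match="RMR ratio"):
            rmr_ratio(30000.0, 2000.0)  # ratio ~3.6: unit mistake


def _free_t_bisection(tt_nmol, shbg_nmol, albumin_g=43.0, tol=1e-14):
    """Independent oracle: bisection on the mass-action balance.

    Total T as a function of free T:
        TT(FT) = FT * (1 + Ka*Alb) + Kt*FT*SHBG / (1 + Kt*FT)
    Solve TT(FT) = tt for FT in [0, tt].
    """
    tt = tt_nmol * 1e-9
    shbg = shbg_nmol * 1e-9
    n = 1.0 + KA_ALBUMIN * albumin_g / ALBUMIN_MOLAR_MASS

    def total(ft):
        return ft * n + KT_SHBG * ft * shbg / (1.0 + KT_SHBG * ft)

    lo, hi = 0.0, tt if tt > 0 else 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if total(mid) < tt:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(hi, 1e-30):
            break
    return 0.5 * (lo + hi) * 1e12  # pmol/L


class TestVermeulen:
    def test_zero_total_gives_zero_free(self):
        assert vermeulen_free_testosterone(0.0, 40.0) == 0.0

    def test_agrees_with_bisection_oracle(self):
        closed = vermeulen_free_testosterone(20.0, 40.0, 43.0)
        oracle = _free_t_bisection(20.0, 40.0, 43.0)
        assert closed == pytest.approx(oracle, rel=1e-6)

    def test_monotone_in_inputs_and_bounded_by_total(self):
        base = vermeulen_free_testosterone(20.0, 40.0, 43.0)
        assert vermeulen_free_testosterone(25.0, 40.0, 43.0) > base
        assert vermeulen_free_testosterone(20.0, 60.0, 43.0) < base
        assert vermeulen_free_testosterone(20.0, 40.0, 50.0) < base
        assert base < 20.0 * 1000  # free (pmol/L) below total (nmol/L -> pmol/L)

    def test_cohort_scale_plausibility(self):
        # cohort-mean total T with default albumin and typical SHBG should
        # land near the observed cohort mean free T (~425 pmol/L)
        ft = vermeulen_free_testosterone(19.8, 32.0)
        assert 425.3 * 0.75 < ft < 425.3 * 1.25


class TestIndicators:
    def _panel(self, **kw):
        base = {"athlete_id": "X", "centre": "AUS"}
        base.update(kw)
        return base

    def test_t3_cutoff_is_strict(self):
        low = build_indicator_profile(self._panel(t3=3.4), PLAIN_REF)
        at = build_indicator_profile(self._panel(t3=3.5), PLAIN_REF)
        assert low.statuses["low_t3"] == MET
        assert at.statuses["low_t3"] == NOT_MET

    def test_site_reference_quartile_overrides_fallback(self):
        ref = ReferenceConfig(ranges={"OSL": {"t3": (3.5, 6.5)}})
        # lowest quartile of the site range = 3.5 + 0.25*3 = 4.25
        prof = build_indicator_profile(self._panel(centre="OSL", t3=4.0), ref)
        assert prof.statuses["low_t3"] == MET
        prof = build_indicator_profile(self._panel(centre="OSL", t3=4.3), ref)
        assert prof.statuses["low_t3"] == NOT_MET

    def test_bmd_met_at_either_site(self):
        prof = build_indicator_profile(self._panel(spine_bmd_z=-1.2, femur_bmd_z=0.1), PLAIN_REF)
        assert prof.statuses["low_bmd"] == MET

    def test_hypotension_diastolic_branch(self):
        ok = build_indicator_profile(self._panel(systolic_bp=118, diastolic_bp=70), PLAIN_REF)
        low = build_indicator_profile(self._panel(systolic_bp=95, diastolic_bp=58), PLAIN_REF)
        assert ok.statuses["hypotension"] == NOT_MET
        assert low.statuses["hypotension"] == MET

    def test_cortisol_composite_with_missing_insulin(self):
        prof = build_indicator_profile(self._panel(cortisol=500.0), PLAIN_REF)
        assert prof.statuses["high_cortisol_or_ratio"] == NOT_MET
        prof = build_indicator_profile(self._panel(cortisol=600.0), PLAIN_REF)
        assert prof.statuses["high_cortisol_or_ratio"] == MET

    def test_testosterone_counts_once_via_total_or_free(self):
        prof = build_indicator_profile(
            self._panel(total_testosterone=18.0, free_testosterone=300.0), PLAIN_REF
        )
        assert prof.statuses["low_testosterone"] == MET
        assert prof.n_primary_met == 1

    def test_rmr_cutoff_depends_on_method(self):
        fp = build_indicator_profile(
            self._panel(rmr_ratio=1.0, rmr_method="first_principles"), PLAIN_REF
        )
        cart = build_indicator_profile(
            self._panel(rmr_ratio=1.0, rmr_method="metabolic_cart"), PLAIN_REF
        )
        assert fp.statuses["low_rmr_ratio"] == MET      # < 1.11
        assert cart.statuses["low_rmr_ratio"] == NOT_MET  # >= 0.88

    def test_missing_fields_propagate_to_missing_status(self):
        prof = build_indicator_profile(self._panel(), PLAIN_REF)
        assert all(s == MISSING for s in prof.statuses.values())


def _profile_from_statuses(statuses):
    return IndicatorProfile(dict(zip(INDICATORS, statuses)))


def _oracle_verdict(statuses):
    """Independent count-and-compare re-derivation of the rule."""
    primary = statuses[: len(PRIMARY_INDICATORS)]
    n_missing = sum(1 for s in statuses if s == MISSING)
    n_primary_missing = sum(1 for s in primary if s == MISSING)
    if n_missing >= 3 and n_primary_missing >= 1:
        return "excluded"
    if sum(1 for s in primary if s == MET) >= 2:
        return "case"
    if sum(1 for s in statuses if s == MET) >= 3:
        return "case"
    return "control"


class TestClassifier:
    @pytest.mark.parametrize(
        "n_primary_met,n_secondary_met,expected",
        [(2, 0, "case"), (1, 2, "case"), (1, 1, "control"), (0, 3, "case"), (0, 2, "control")],
    )
    def test_rule_examples(self, n_primary_met, n_secondary_met, expected):
        statuses = (
            [MET] * n_primary_met + [NOT_MET] * (4 - n_primary_met)
            + [MET] * n_secondary_met + [NOT_MET] * (6 - n_secondary_met)
        )
        assert classify_lea(_profile_from_statuses(statuses)).verdict == expected

    def test_exclusion_trumps_met_counts(self):
        statuses = [MISSING, MET, MET, NOT_MET, MISSING, MISSING] + [NOT_MET] * 4
        assert classify_lea(_profile_from_statuses(statuses)).verdict == "excluded"

    def test_matches_oracle_on_random_assignments(self, rng):
        opts = np.array([MET, NOT_MET, MISSING])
        for _ in range(2000):
            statuses = list(rng.choice(opts, size=10))
            assert classify_lea(_profile_from_statuses(statuses)).verdict == _oracle_verdict(statuses)

    def test_flipping_to_met_never_turns_case_into_control(self, rng):
        opts = np.array([MET, NOT_MET, MISSING])
        for _ in range(300):
            statuses = list(rng.choice(opts, size=10))
            before = classify_lea(_profile_from_statuses(statuses)).verdict
            for i in range(10):
                if statuses[i] == NOT_MET:
                    flipped = list(statuses)
                    flipped[i] = MET
                    after = classify_lea(_profile_from_statuses(flipped)).verdict
                    if before == "case":
                        assert after != "control"
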