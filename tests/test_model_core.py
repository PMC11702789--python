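import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mammorisk import (AbsoluteRiskModel, BaselineHazard, CovariateDef,
                       CovariateSchema, ModelSpec, RateTable, absolute_risk,
                       calibrate_baseline_hazard, impute_missing_profile,
                       percent_density_to_category, project_risks,
                       relative_risk, relative_risk_frame)


# ---------------------------------------------------------------------------
# relative risk
# ---------------------------------------------------------------------------

def test_all_reference_profile_has_unit_relative_risk(toy_spec):
    assert relative_risk({"smoker": "no", "dose": 0.0}, toy_spec) == 1.0


def test_single_log2_level_doubles_risk(toy_spec):
    assert relative_risk({"smoker": "yes", "dose": 0.0},
                         toy_spec) == pytest.approx(2.0)


def test_continuous_covariate_centred_at_reference(toy_spec):
    rr = relative_risk({"smoker": "no", "dose": 2.0}, toy_spec)
    assert rr == pytest.approx(1.5 ** 2)


def test_density_extreme_vs_fatty_ratio_within_literature_band():
    """A configured extreme-vs-fatty RR of 3 sits inside the established
    2- to 4-fold band and is reproduced exactly by the model."""
    schema = CovariateSchema((
        CovariateDef("density_category", "categorical",
                     ("1", "2", "3", "4"), "1"),))
    spec = ModelSpec("over50", schema,
                     {"density_category": {"1": 0.0, "2": math.log(1.5),
                                           "3": math.log(2.0),
                                           "4": math.log(3.0)}})
    ratio = (relative_risk({"density_category": "4"}, spec)
             / relative_risk({"density_category": "1"}, spec))
    assert ratio == pytest.approx(3.0)
    assert 2.0 <= ratio <= 4.0


def test_unknown_level_and_nonfinite_value_rejected(toy_spec):
    with pytest.raises(ValueError, match="smoker"):
        relative_risk({"smoker": "sometimes", "dose": 0.0}, toy_spec)
    with pytest.raises(ValueError, match="dose"):
        relative_risk({"smoker": "no", "dose": float("inf")}, toy_spec)
    # NaN counts as missing (handled by profile marginalization, not here)
    with pytest.raises(KeyError, match="dose"):
        relative_risk({"smoker": "no", "dose": float("nan")}, toy_spec)
    with pytest.raises(KeyError, match="dose"):
        relative_risk({"smoker": "no"}, toy_spec)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(smoker=st.sampled_from(["no", "yes"]),
       dose=st.floats(-5, 5, allow_nan=False))
def test_relative_risk_factorizes_across_covariate_blocks(smoker, dose):
    """rr(A union B) = rr(A at values, B at reference) * rr(B, A at ref)."""
    schema = CovariateSchema((
        CovariateDef("smoker", "categorical", ("no", "yes"), "no"),
        CovariateDef("dose", "continuous", reference_value=0.0),
    ))
    spec = ModelSpec("over50", schema,
                     {"smoker": {"no": 0.0, "yes": 0.7}, "dose": 0.3})
    full = relative_risk({"smoker": smoker, "dose": dose}, spec)
    part_a = relative_risk({"smoker": smoker, "dose": 0.0}, spec)
    part_b = relative_risk({"smoker": "no", "dose": dose}, spec)
    assert full == pytest.approx(part_a * part_b, rel=1e-12)


def test_vectorized_relative_risk_matches_scalar(toy_spec):
    df = pd.DataFrame({"smoker": ["no", "yes", "yes"],
                       "dose": [0.0, 1.0, 2.0]})
    vec = relative_risk_frame(df, toy_spec)
    scalar = [relative_risk(row, toy_spec) for row in
              df.to_dict(orient="records")]
    assert np.allclose(vec, scalar)


# ---------------------------------------------------------------------------
# percent density -> category
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("percent,scheme,expected", [
    (9.9, "cumulus", 1), (10.0, "cumulus", 2), (24.9, "cumulus", 2),
    (25.0, "cumulus", 3), (49.9, "cumulus", 3), (50.0, "cumulus", 4),
    (100.0, "cumulus", 4),
    (0.0, "cumulus", 1), (0.0, "stratus", 1),
    (1.9, "stratus", 1), (2.0, "stratus", 2), (7.9, "stratus", 2),
    (8.0, "stratus", 3), (48.9, "stratus", 3), (49.0, "stratus", 4),
])
def test_percent_density_thresholds(percent, scheme, expected):
    assert percent_density_to_category(percent, scheme) == expected


def test_percent_density_rejects_out_of_range_and_unknown_scheme():
    with pytest.raises(ValueError, match=r"\[0, 100\]"):
        percent_density_to_category(101.0, "cumulus")
    with pytest.raises(ValueError, match=r"\[0, 100\]"):
        percent_density_to_category(-0.1, "stratus")
    with pytest.raises(ValueError, match="scheme"):
        percent_density_to_category(10.0, "birads")


def test_percent_density_vectorized():
    out = percent_density_to_category([0, 15, 30, 80], "cumulus")
    assert list(out) == [1, 2, 3, 4]


# ---------------------------------------------------------------------------
# baseline calibration
# ---------------------------------------------------------------------------

def test_unit_mean_relative_risk_gives_lambda0_equal_incidence(
        toy_spec, flat_incidence):
    ref = pd.DataFrame({"smoker": ["no", "no"], "dose": [0.0, 0.0]})
    lam0 = calibrate_baseline_hazard(toy_spec, flat_incidence, ref)
    assert np.allclose(lam0.lambda0, flat_incidence.rates)


def test_two_individual_mean_rr_halves_baseline():
    """Equal-weight individuals at rr 1 and 3 (mean 2): lambda_m 0.002
    calibrates to lambda0 = 0.001."""
    schema = CovariateSchema((
        CovariateDef("g", "categorical", ("a", "b"), "a"),))
    spec = ModelSpec("over50", schema, {"g": {"a": 0.0, "b": math.log(3.0)}})
    ref = pd.DataFrame({"g": ["a", "b"]})
    incidence = RateTable(np.arange(50, 55), np.full(5, 0.002))
    lam0 = calibrate_baseline_hazard(spec, incidence, ref)
    assert np.allclose(lam0.lambda0, 0.001)


def test_calibration_identity_exact_at_every_age(toy_spec, toy_reference,
                                                 flat_incidence):
    """Reference-weighted mean of lambda0(a) * rr_i equals lambda_m(a) to
    machine precision at every age."""
    lam0 = calibrate_baseline_hazard(toy_spec, flat_incidence, toy_reference)
    rr = relative_risk_frame(toy_reference, toy_spec)
    w = toy_reference["weight"].to_numpy()
    for i, age in enumerate(flat_incidence.ages):
        mean_hazard = np.sum(w * lam0.lambda0[i] * rr) / np.sum(w)
        assert mean_hazard == pytest.approx(flat_incidence.rates[i], abs=1e-16)


def test_calibrated_hazard_reproduces_marginal_incidence_in_simulation(
        toy_spec, toy_reference):
    """Simulating one year of outcomes from lambda0 * rr_i at each age
    reproduces the marginal incidence within 2 Monte-Carlo SE."""
    incidence = RateTable(np.arange(50, 53), np.array([0.002, 0.005, 0.01]))
    lam0 = calibrate_baseline_hazard(toy_spec, incidence, toy_reference)
    rr = relative_risk_frame(toy_reference, toy_spec)
    w = toy_reference["weight"].to_numpy()
    p = w / w.sum()
    rng = np.random.default_rng(7)
    n = 200_000
    for i in range(3):
        draws = rng.choice(rr.size, size=n, p=p)
        events = rng.uniform(size=n) < lam0.lambda0[i] * rr[draws]
        lam = incidence.rates[i]
        se = math.sqrt(lam * (1 - lam) / n)
        assert abs(events.mean() - lam) < 2 * se


def test_attrition_adjustment_depletes_high_risk_reference(toy_spec):
    """With survivor re-weighting the later-age baseline exceeds the
    rare-disease value (high-rr women leave the risk set faster)."""
    ref = pd.DataFrame({"smoker": ["no"] * 50 + ["yes"] * 50,
                        "dose": [0.0] * 100})
    incidence = RateTable(np.arange(50, 70), np.full(20, 0.05))
    plain = calibrate_baseline_hazard(toy_spec, incidence, ref)
    adj = calibrate_baseline_hazard(toy_spec, incidence, ref,
                                    attrition_adjusted=True)
    assert adj.lambda0[0] == pytest.approx(plain.lambda0[0])
    assert np.all(adj.lambda0[1:] > plain.lambda0[1:])


def test_empty_reference_rejected(toy_spec, flat_incidence):
    with pytest.raises(ValueError, match="empty"):
        calibrate_baseline_hazard(toy_spec, flat_incidence,
                                  pd.DataFrame({"smoker": [], "dose": []}))


# ---------------------------------------------------------------------------
# absolute risk
# ---------------------------------------------------------------------------

def _const_hazard(value, ages=np.arange(40, 81)):
    return BaselineHazard(ages, np.full(ages.size, value))


def test_zero_hazard_gives_zero_risk(toy_spec, zero_mortality):
    proj = absolute_risk({"smoker": "no", "dose": 0.0}, toy_spec,
                         _const_hazard(0.0), zero_mortality, 50, 5)
    assert proj.risk == 0.0


def test_constant_hazard_closed_form(toy_spec, zero_mortality):
    proj = absolute_risk({"smoker": "no", "dose": 0.0}, toy_spec,
                         _const_hazard(0.01), zero_mortality, 50, 5)
    assert proj.risk == pytest.approx(1 - 0.99 ** 5, abs=1e-15)


def test_with_competing_mortality_matches_summation_oracle(toy_spec):
    """Independent term-by-term oracle for h=0.01, mu=0.02, tau=5."""
    mortality = RateTable(np.arange(40, 81), np.full(41, 0.02))
    proj = absolute_risk({"smoker": "no", "dose": 0.0}, toy_spec,
                         _const_hazard(0.01), mortality, 50, 5)
    oracle, surv = 0.0, 1.0
    for _ in range(5):
        oracle += surv * 0.01
        surv *= 1.0 - 0.01 - 0.02
    assert proj.risk == pytest.approx(oracle, abs=1e-12)


def test_risk_monotone_in_horizon_and_zero_at_tau_zero(toy_spec,
                                                       flat_mortality):
    risks = [absolute_risk({"smoker": "yes", "dose": 1.0}, toy_spec,
                           _const_hazard(0.01), flat_mortality, 50, tau).risk
             for tau in range(0, 8)]
    assert risks[0] == 0.0
    assert np.all(np.diff(risks) > 0)


def test_competing_mortality_strictly_decreases_risk(toy_spec, zero_mortality,
                                                     flat_mortality):
    args = ({"smoker": "no", "dose": 0.0}, toy_spec, _const_hazard(0.02))
    without = absolute_risk(*args, zero_mortality, 50, 5).risk
    with_mu = absolute_risk(*args, flat_mortality, 50, 5).risk
    assert with_mu < without


def test_risk_strictly_increasing_in_relative_risk(zero_mortality):
    lam0 = _const_hazard(0.01)
    risks = project_risks([0.5, 1.0, 2.0, 4.0], 50, lam0, zero_mortality, 5)
    assert np.all(np.diff(risks) > 0)


def test_hazard_clamped_when_h_plus_mu_exceeds_one(toy_spec, caplog):
    mortality = RateTable(np.arange(40, 81), np.full(41, 0.5))
    lam0 = _const_hazard(0.9)
    with caplog.at_level("WARNING", logger="mammorisk"):
        risks = project_risks([2.0], 50, lam0, mortality, 3)
    assert "clamped" in caplog.text
    assert 0.0 <= risks[0] <= 1.0


def test_projection_outside_support_rejected(toy_spec, flat_mortality):
    with pytest.raises(ValueError, match="support"):
        project_risks([1.0], 79, _const_hazard(0.01), flat_mortality, 5)


# ---------------------------------------------------------------------------
# missing-covariate marginalization
# ---------------------------------------------------------------------------

def test_complete_profile_matches_relative_risk(toy_spec, toy_reference):
    profile = {"smoker": "yes", "dose": 1.0}
    assert impute_missing_profile(profile, toy_spec, toy_reference) == \
        pytest.approx(relative_risk(profile, toy_spec))


def test_all_missing_gives_reference_mean_rr(toy_spec, toy_reference):
    rr = relative_risk_frame(toy_reference, toy_spec)
    w = toy_reference["weight"].to_numpy()
    expected = np.sum(w * rr) / np.sum(w)
    assert impute_missing_profile({}, toy_spec, toy_reference) == \
        pytest.approx(expected)


def test_one_missing_binary_covariate_two_row_reference():
    """Hand-enumerated completion: dose observed at 1.0, smoker missing,
    reference has smoker yes (w=1) and no (w=3)."""
    schema = CovariateSchema((
        CovariateDef("smoker", "categorical", ("no", "yes"), "no"),
        CovariateDef("dose", "continuous", reference_value=0.0),
    ))
    spec = ModelSpec("over50", schema,
                     {"smoker": {"no": 0.0, "yes": math.log(2.0)},
                      "dose": math.log(1.5)})
    ref = pd.DataFrame({"smoker": ["yes", "no"], "dose": [0.0, 0.0],
                        "weight": [1.0, 3.0]})
    # E[rr_smoker] = (1*2 + 3*1)/4 = 1.25; observed dose contributes 1.5
    got = impute_missing_profile({"dose": 1.0}, spec, ref)
    assert got == pytest.approx(1.5 * 1.25)


def test_unmatched_stratum_falls_back_to_marginal(toy_spec, toy_reference,
                                                  caplog):
    ref = toy_reference[toy_reference["smoker"] == "no"]
    with caplog.at_level("WARNING", logger="mammorisk"):
        got = impute_missing_profile({"smoker": "yes"}, toy_spec, ref)
    assert "falling back" in caplog.text
    # falls back to marginal mean of the dose contribution times rr(smoker=yes)
    rr_dose = relative_risk_frame(ref, toy_spec.subset(["dose"]))
    w = ref["weight"].to_numpy()
    assert got == pytest.approx(2.0 * np.sum(w * rr_dose) / np.sum(w))


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

def _stratified_specs():
    schema = CovariateSchema((
        CovariateDef("smoker", "categorical", ("no", "yes"), "no"),))
    under = ModelSpec("under50", schema,
                      {"smoker": {"no": 0.0, "yes": math.log(4.0)}})
    over = ModelSpec("over50", schema,
                     {"smoker": {"no": 0.0, "yes": math.log(2.0)}})
    return under, over


def test_estimator_switches_stratum_at_exact_age_50(flat_incidence,
                                                    zero_mortality):
    under, over = _stratified_specs()
    ref = pd.DataFrame({"smoker": ["no", "yes"]})
    model = AbsoluteRiskModel(spec_under50=under, spec_over50=over,
                              incidence=flat_incidence,
                              mortality=zero_mortality).fit(ref)
    X = pd.DataFrame({"smoker": ["yes", "yes"], "entry_age": [49.0, 50.0]})
    risks = model.predict(X)
    # under-50 stratum: rr 4 against mean 2.5; over-50: rr 2 against mean 1.5
    lam_u = 0.01 / 2.5 * 4.0
    lam_o = 0.01 / 1.5 * 2.0
    # entry 49 uses the under-50 model for the whole projection (no blending),
    # but ages >= 50 use the over-50 calibrated baseline
    h49 = [lam_u] + [0.01 / 1.5 * 4.0] * 4
    expected_49 = 0.0
    surv = 1.0
    for h in h49:
        expected_49 += surv * h
        surv *= 1 - h
    assert risks[0] == pytest.approx(expected_49, rel=1e-12)
    assert risks[1] == pytest.approx(1 - (1 - lam_o) ** 5, rel=1e-12)


def test_estimator_clones_and_roundtrips_params(flat_incidence,
                                                flat_mortality, toy_spec):
    from sklearn.base import clone
    model = AbsoluteRiskModel(spec_over50=toy_spec, incidence=flat_incidence,
                              mortality=flat_mortality, horizon=5)
    cloned = clone(model)
    assert cloned.get_params()["horizon"] == 5
    assert cloned.get_params()["spec_over50"] == toy_spec


def test_predict_before_fit_raises(toy_spec, flat_incidence, flat_mortality):
    model = AbsoluteRiskModel(spec_over50=toy_spec, incidence=flat_incidence,
                              mortality=flat_mortality)
    with pytest.raises(RuntimeError, match="not fitted"):
        model.predict(pd.DataFrame({"smoker": ["no"], "dose": [0.0],
                                    "entry_age": [50.0]}))


def test_predict_profile_marginalizes_missing_covariates(
        toy_spec, toy_reference, flat_incidence, zero_mortality):
    model = AbsoluteRiskModel(spec_over50=toy_spec, incidence=flat_incidence,
                              mortality=zero_mortality).fit(toy_reference)
    proj = model.predict_profile({"dose": 1.0}, entry_age=55)
    rr = impute_missing_profile({"dose": 1.0}, toy_spec, toy_reference)
    lam = model.baseline_hazard_.at(55)
    assert proj.risk == pytest.approx(1 - (1 - lam * rr) ** 5, rel=1e-10)
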