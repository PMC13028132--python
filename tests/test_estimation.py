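"""Input estimation: survival fits, information criteria, conversions,
transition matrices and recurrent-event GEEs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hfmarkov as hm
from hfmarkov.estimation import (
    MONTH_DAYS,
    EstimationError,
    SurvivalFit,
    build_cycle_panel,
    fit_all_families,
    fit_event_gee,
    fit_parametric_survival,
    proportion_to_cycle_probability,
    rate_to_cycle_probability,
    select_best_fit,
)


# -- parametric survival -----------------------------------------------------


def test_exponential_rate_recovery():
    rng = np.random.default_rng(2)
    true_rate = 0.5  # per year
    n = 3000
    t = rng.exponential(1 / true_rate, n)
    censor = np.full(n, 2.4)
    obs = t < censor
    fit = fit_parametric_survival(np.minimum(t, censor), obs, "exponential",
                                  endpoint="x", time_unit="years")
    rate_hat = 1.0 / fit.parameters["lambda_"]
    se = rate_hat / np.sqrt(obs.sum())  # asymptotic SE of an exponential MLE
    assert abs(rate_hat - true_rate) < 3 * se


def test_exponential_closed_form_identity():
    """lambda_hat = events / exposure for exponential fits (score equation)."""
    rng = np.random.default_rng(5)
    t = rng.exponential(2.0, 400)
    censor = np.full(400, 3.0)
    obs = t < censor
    d = np.minimum(t, censor)
    fit = fit_parametric_survival(d, obs, "exponential", time_unit="years")
    rate_hat = 1.0 / fit.parameters["lambda_"]
    assert rate_hat == pytest.approx(obs.sum() / d.sum(), rel=1e-8)


def test_single_subject_exponential():
    fit = fit_parametric_survival([2.5], [1], "exponential", time_unit="years")
    assert 1.0 / fit.parameters["lambda_"] == pytest.approx(1 / 2.5, rel=1e-6)


def test_information_criterion_identities():
    rng = np.random.default_rng(8)
    t = np.exp(rng.normal(0.5, 0.8, 500))
    obs = rng.random(500) < 0.7
    fits = fit_all_families(np.maximum(t, 1e-3), obs, endpoint="e", time_unit="years")
    for f in fits:
        k = f.n_parameters
        assert f.aic == pytest.approx(-2 * f.log_likelihood + 2 * k, abs=1e-9)
        assert f.bic == pytest.approx(-2 * f.log_likelihood + k * np.log(f.n), abs=1e-9)
        # cross-check against the fitter's own AIC where it exposes one
        if hasattr(f._fitter, "AIC_"):
            assert f.aic == pytest.approx(float(f._fitter.AIC_), rel=1e-6)
        s = f.survival(np.linspace(0.01, 28, 50))
        assert s[0] <= 1.0 + 1e-9
        assert np.all(np.diff(s) <= 1e-12)  # monotone non-increasing


def test_lognormal_selected_by_aic_when_true():
    rng = np.random.default_rng(12)
    n = 6000
    t = np.exp(rng.normal(np.log(2.33), 1.1, n))
    censor = np.full(n, 29 / 12)
    obs = t < censor
    fits = fit_all_families(np.minimum(t, censor), obs, endpoint="discontinuation",
                            time_unit="years")
    assert select_best_fit(fits, "AIC").family == "lognormal"


def test_all_censored_raises():
    with pytest.raises(EstimationError):
        fit_parametric_survival([1.0, 2.0], [0, 0], "exponential", time_unit="years")
    with pytest.raises(ValueError):
        fit_parametric_survival([-1.0, 2.0], [1, 1], "exponential", time_unit="years")


def _dummy_fit(family, aic, bic, k, endpoint="e"):
    return SurvivalFit(family=family, endpoint=endpoint, parameters={f"p{i}": 1.0 for i in range(k)},
                       log_likelihood=0.0, aic=aic, bic=bic, n=100, n_events=50)


def test_select_best_fit_argmin_and_tiebreak():
    fits = [_dummy_fit("a", 100, 101, 2), _dummy_fit("b", 98, 99, 2),
            _dummy_fit("c", 103, 104, 2)]
    assert select_best_fit(fits, "AIC").family == "b"
    # within 2 AIC units, the leaner family wins
    tie = [_dummy_fit("rich", 97.5, 95, 3), _dummy_fit("lean", 98.5, 99, 1)]
    assert select_best_fit(tie, "AIC").family == "lean"
    assert select_best_fit(tie, "BIC").family == "rich"  # BIC gap exceeds 2
    with pytest.raises(ValueError):
        select_best_fit([])
    with pytest.raises(ValueError):
        select_best_fit([_dummy_fit("a", 1, 1, 1, "x"), _dummy_fit("b", 1, 1, 1, "y")])


# -- probability conversions -------------------------------------------------


def test_rate_to_monthly_probability_matches_published_value():
    p = rate_to_cycle_probability(3.56, MONTH_DAYS)
    assert round(p.value, 4) == 0.0030
    assert rate_to_cycle_probability(0.0, MONTH_DAYS).value == 0.0
    # annual hazard of 12 over one month: 1 - e^-1
    p12 = rate_to_cycle_probability(1200.0, MONTH_DAYS)
    assert p12.value == pytest.approx(1 - np.exp(-1), rel=1e-12)
    with pytest.raises(ValueError):
        rate_to_cycle_probability(-1.0)


def test_proportion_to_cycle_probability():
    assert proportion_to_cycle_probability(0.0, 974.0, 28.0).value == 0.0
    p = proportion_to_cycle_probability(0.10, 32 * 365.25 / 12, 28.0)
    assert p.value == pytest.approx(0.00302, abs=5e-6)
    with pytest.raises(ValueError):
        proportion_to_cycle_probability(1.0, 974.0, 28.0)
    with pytest.raises(ValueError):
        proportion_to_cycle_probability(0.1, 10.0, 28.0)


@settings(max_examples=50, derandomize=True)
@given(prop=st.floats(0.0, 0.95), ratio=st.floats(1.0, 60.0))
def test_proportion_conversion_inverse_identity(prop, ratio):
    """Compounding the per-cycle probability over followup/cycle cycles
    recovers the original proportion."""
    followup = 28.0 * ratio
    p = proportion_to_cycle_probability(prop, followup, 28.0).value
    recovered = 1.0 - (1.0 - p) ** (followup / 28.0)
    assert recovered == pytest.approx(prop, abs=1e-9)


def test_cycle_probability_rescaling_roundtrip():
    p = hm.CycleProbability(0.05, source_window_days=28.0)
    q = p.for_cycle(MONTH_DAYS)
    back = hm.CycleProbability(q, source_window_days=MONTH_DAYS).for_cycle(28.0)
    assert back == pytest.approx(0.05, rel=1e-12)


# -- transition matrices -----------------------------------------------------


def _panel(rows):
    return pd.DataFrame(rows, columns=["patient_id", "time_days", "score"])


def test_transition_identity_when_static():
    panel = _panel([("p1", 0, 20), ("p1", 30, 20), ("p1", 60, 20),
                    ("p2", 0, 95), ("p2", 30, 95)])
    tm = hm.estimate_transition_matrix(panel)
    assert np.allclose(tm.matrix[0], [1, 0, 0, 0])
    assert np.allclose(tm.matrix[3], [0, 0, 0, 1])


def test_transition_hand_count():
    panel = _panel([("p1", 0, 10), ("p1", 30, 10),
                    ("p2", 0, 10), ("p2", 30, 60)])
    tm = hm.estimate_transition_matrix(panel)
    assert np.allclose(tm.matrix[0], [0.5, 0.5, 0, 0])


def test_boundary_scores_are_lower_closed():
    from hfmarkov.kccq import assign_quartile
    assert list(assign_quartile([50.0, 69.8, 87.5, 100.0, 1.0])) == [1, 2, 3, 3, 0]


def test_fitted_transition_matrix_row_stochastic(fitted):
    for arm in ("control", "active"):
        m = getattr(fitted.inputs, arm).transition.matrix
        assert np.all(m >= 0)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)


# -- GEE ---------------------------------------------------------------------


def test_gee_intercept_only_matches_observed_mean(small_trial):
    """Score-equation identity: with only an intercept, the GEE-predicted
    per-cycle count equals the observed mean count per unit exposure."""
    panel = build_cycle_panel(small_trial.baseline, small_trial.events, "HHF",
                              arm="control")
    observed = panel["count"].sum() / (panel["exposure_days"].sum() / 28.0)
    m = fit_event_gee(small_trial.baseline, small_trial.events, "HHF", "control",
                      covariates=(), working_correlation="independence")
    assert np.exp(m.coefficients["intercept"]) == pytest.approx(observed, rel=1e-6)
    # the exchangeable weighting perturbs the identity only marginally
    mx = fit_event_gee(small_trial.baseline, small_trial.events, "HHF", "control",
                       covariates=())
    assert np.exp(mx.coefficients["intercept"]) == pytest.approx(observed, rel=0.01)


def test_gee_null_covariates_recovered():
    """With covariate-free generation, age/sex/race coefficients are 0
    within 3 SE."""
    models = {(e, a): hm.EventRateModel.from_rate(r, e, a)
              for (e, a), r in {("HHF", "control"): 10.5, ("HHF", "active"): 10.5,
                                ("UHFV", "control"): 0.0, ("UHFV", "active"): 0.0}.items()}
    trial = hm.generate_trial(hm.GeneratorConfig(n_per_arm=2000, seed=23,
                                                 true_event_models=models))
    m = fit_event_gee(trial.baseline, trial.events, "HHF", "control")
    for key in ("age", "sex_male", "race_Asian", "race_Other"):
        assert abs(m.coefficients[key]) < 3 * m.stderr[key]


def test_gee_zero_events_flagged():
    baseline = pd.DataFrame({
        "patient_id": ["a", "b"], "arm": "control",
        "age_baseline": [70.0, 75.0], "sex": ["male", "female"],
        "race": ["White", "White"], "kccq_baseline": [50.0, 60.0],
        "death_time": [np.nan, np.nan], "death_cause": ["", ""],
        "discontinuation_time": [np.nan, np.nan], "censor_time": [400.0, 400.0]})
    events = pd.DataFrame({"patient_id": [], "time_days": [], "event_type": []})
    with pytest.warns(UserWarning):
        m = fit_event_gee(baseline, events, "HHF", "control")
    assert m.zero_rate
    assert m.per_cycle_rate(72.0, "male", "White") == 0.0


def test_event_rate_model_reference_calibration():
    m = hm.EventRateModel.from_rate(10.5, "HHF", "control", age=0.025, sex_male=0.1,
                                    ref_age=72.0, ref_male_fraction=0.545,
                                    ref_race_mix={"White": 1.0})
    got = float(m.expected_per_cycle(72.0, 0.545, {"White": 1.0}))
    assert got == pytest.approx(10.5 / 100 * 28 / 365.25, rel=1e-12)
    # cycle rescaling is linear in cycle length
    assert float(m.expected_per_cycle(72.0, 0.545, {"White": 1.0}, cycle_days=56.0)) \
        == pytest.approx(2 * got, rel=1e-12)
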