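"""Cohort engine: stepping, mortality caps, accrual, closed forms, invariants."""

import numpy as np
import pytest

import hfmarkov as hm
from hfmarkov.engine import (
    STATES,
    ArmInputs,
    EngineError,
    ModelInputs,
    ModelSpec,
    accrue_qaly,
    build_mortality_schedule,
    expected_events,
    on_treatment_fraction,
    run_cohort,
    step_cohort,
)
from hfmarkov.estimation import CycleProbability, EventRateModel, TransitionMatrix

IDENTITY = TransitionMatrix.identity()
OCC_COLS = [f"occ_{s}" for s in STATES]


def _const_inputs(p_all=0.0, p_cv=0.0, event_rate=0.0, life_table=None):
    em = {}
    if event_rate >= 0:
        em = {"HHF": EventRateModel.from_rate(event_rate, "HHF", "control")}
    ai = ArmInputs(transition=IDENTITY, event_models=em,
                   cv_mortality=CycleProbability(p_cv, source_window_days=28.0),
                   allcause_mortality=CycleProbability(p_all, source_window_days=28.0))
    return ModelInputs(control=ai, active=ai, discontinuation=None, life_table=life_table)


def _clean_spec(**kw):
    base = dict(discount_annual=0.0, utilities=(1.0, 1.0, 1.0, 1.0),
                age_decrement_per_year=0.0, event_disutilities={},
                ae_disutilities_on=False)
    base.update(kw)
    return ModelSpec(**base)


# -- step_cohort -------------------------------------------------------------


def test_step_no_mortality_identity():
    occ = np.array([0.25, 0.25, 0.25, 0.25, 0, 0])
    assert np.allclose(step_cohort(occ, IDENTITY, 0.0, 0.0), occ)


def test_step_certain_cv_death_absorbs_all_alive():
    occ = np.array([0.25, 0.25, 0.25, 0.25, 0, 0])
    out = step_cohort(occ, IDENTITY, 1.0, 0.0)
    assert out[4] == pytest.approx(1.0)
    assert np.allclose(out[:4], 0.0)


def test_step_hand_arithmetic():
    occ = np.array([1.0, 0, 0, 0, 0, 0])
    out = step_cohort(occ, IDENTITY, 0.1, 0.1)
    assert np.allclose(out, [0.8, 0, 0, 0, 0.1, 0.1])


def test_step_rejects_bad_inputs():
    with pytest.raises(EngineError):
        step_cohort(np.array([0.5, 0, 0, 0, 0, 0]), IDENTITY, 0.0, 0.0)
    with pytest.raises(ValueError):
        step_cohort(np.array([1.0, 0, 0, 0, 0, 0]), np.full((4, 4), 0.3), 0.0, 0.0)
    with pytest.raises(EngineError):
        step_cohort(np.array([1.0, 0, 0, 0, 0, 0]), IDENTITY, 0.7, 0.7)


# -- mortality schedule ------------------------------------------------------


def test_life_table_cap_takes_minimum(life_table):
    spec = ModelSpec(horizon_years=1.0)
    # model-implied non-CV far below the cap: kept
    low = build_mortality_schedule(CycleProbability(0.0, source_window_days=28),
                                   CycleProbability(0.001, source_window_days=28),
                                   life_table, spec)[1]
    assert np.allclose(low, 0.001)
    # model-implied far above: capped at the life-table value
    high = build_mortality_schedule(CycleProbability(0.0, source_window_days=28),
                                    CycleProbability(0.5, source_window_days=28),
                                    life_table, spec)[1]
    cap = life_table.per_cycle_noncv_probability(72, spec.male_fraction, 28.0)
    assert np.allclose(high, cap)
    assert cap < 0.5


def test_life_table_cv_deletion_arithmetic():
    import pandas as pd
    from hfmarkov.lifetable import LifeTable
    rows = []
    for sex in ("male", "female"):
        for age in range(70, 76):
            rows.append({"age": age, "sex": sex,
                         "qx": 0.05 if age < 75 else 1.0, "cv_fraction": 0.4})
    lt = LifeTable(pd.DataFrame(rows))
    assert lt.annual_noncv_probability(72, 0.5) == pytest.approx(0.03)


def test_noncv_is_allcause_minus_cv_remainder():
    spec = ModelSpec(horizon_years=1.0)
    p_cv, p_ncv = build_mortality_schedule(
        CycleProbability(0.002, source_window_days=28),
        CycleProbability(0.0075, source_window_days=28), None, spec)
    assert np.allclose(p_cv, 0.002)
    assert np.allclose(p_ncv, 0.0055)
    # all-cause below CV floors the remainder at zero
    _, floored = build_mortality_schedule(
        CycleProbability(0.01, source_window_days=28),
        CycleProbability(0.004, source_window_days=28), None, spec)
    assert np.allclose(floored, 0.0)


# -- run_cohort closed forms -------------------------------------------------


def test_constant_hazard_geometric_series_limit():
    spec = _clean_spec(horizon_years=250.0)
    trace = run_cohort(spec, _const_inputs(p_all=0.01), arm="control")
    expected = (28 / 365.25) * (1 / 0.01 - 0.5)
    assert trace.ly == pytest.approx(expected, abs=1e-9)


def test_zero_mortality_ly_equals_qaly_equals_horizon():
    spec = _clean_spec(horizon_years=2.0)
    trace = run_cohort(spec, _const_inputs(), arm="control")
    horizon = spec.n_cycles * spec.cycle_years
    assert trace.ly == pytest.approx(horizon, rel=1e-12)
    assert trace.qaly == pytest.approx(trace.ly, rel=1e-12)


def test_discounting_strictly_reduces_ly():
    inputs = _const_inputs(p_all=0.005)
    t0 = run_cohort(_clean_spec(), inputs, arm="control")
    t35 = run_cohort(_clean_spec(discount_annual=0.035), inputs, arm="control")
    assert t0.ly == pytest.approx(t0.ly_discounted)
    assert t35.ly_discounted < t35.ly
    assert t35.ly == pytest.approx(t0.ly)


def test_discounted_matches_independent_geometric_sum():
    """Discounted LY equals sum_t delta * v^t * (S_t + S_{t+1})/2 computed
    from scratch for a constant hazard with no cap."""
    p, d = 0.004, 0.035
    spec = _clean_spec(discount_annual=d, horizon_years=28.0)
    trace = run_cohort(spec, _const_inputs(p_all=p), arm="control")
    n, dy = spec.n_cycles, spec.cycle_years
    S = (1 - p) ** np.arange(n + 1)
    v = (1 + d) ** (-(np.arange(n) * dy))
    expected = np.sum(dy * v * 0.5 * (S[:-1] + S[1:]))
    assert trace.ly_discounted == pytest.approx(expected, abs=1e-12)


# -- events and QALY accrual -------------------------------------------------


def test_expected_events_linearity_and_degeneracy():
    m = EventRateModel.from_rate(10.0, "HHF", "control")
    spec = ModelSpec()
    r = float(m.expected_per_cycle(72.0, spec.male_fraction, spec.race_mix))
    assert expected_events(0.0, m, 72.0, spec) == 0.0
    assert expected_events(0.5, m, 72.0, spec) == pytest.approx(0.5 * r)


def test_positive_age_coefficient_gives_increasing_rates():
    m = EventRateModel.from_rate(10.0, "HHF", "control", age=0.025)
    spec = _clean_spec(horizon_years=5.0)
    ai = ArmInputs(transition=IDENTITY, event_models={"HHF": m},
                   cv_mortality=CycleProbability(0.0, source_window_days=28),
                   allcause_mortality=CycleProbability(0.0, source_window_days=28))
    trace = run_cohort(spec, ModelInputs(control=ai, active=ai), arm="control")
    per_cycle = trace.df["events_HHF"].to_numpy()
    assert np.all(np.diff(per_cycle) > 0)  # alive mass constant, rate rising


def test_age_decrement_hand_arithmetic():
    """With utility 1 and decrement -0.0051/yr, the per-cycle utility weight
    10 years in is lower by 0.051."""
    spec = _clean_spec(age_decrement_per_year=-0.0051, horizon_years=15.0)
    trace = run_cohort(spec, _const_inputs(), arm="control")
    dy = spec.cycle_years
    k = int(round(10.0 / dy))
    t_k = trace.df.loc[k, "time_years"]
    per_cycle_utility = trace.df.loc[k, "qaly"] / dy
    expected = 1.0 - 0.0051 * (t_k + dy / 2)  # trapezoid midpoint
    assert per_cycle_utility == pytest.approx(expected, rel=1e-10)
    assert 1.0 - 0.0051 * 10 == pytest.approx(0.949)


def test_event_disutility_is_one_off_per_expected_event():
    m = EventRateModel.from_rate(10.0, "HHF", "control")
    ai = ArmInputs(transition=IDENTITY, event_models={"HHF": m},
                   cv_mortality=CycleProbability(0.0, source_window_days=28),
                   allcause_mortality=CycleProbability(0.0, source_window_days=28))
    inputs = ModelInputs(control=ai, active=ai)
    base = run_cohort(_clean_spec(horizon_years=3.0), inputs, arm="control")
    with_dis = run_cohort(_clean_spec(horizon_years=3.0,
                                      event_disutilities={"HHF": 0.05}),
                          inputs, arm="control")
    lost = base.qaly - with_dis.qaly
    assert lost == pytest.approx(0.05 * base.total_events("HHF"), rel=1e-12)


def test_accrue_qaly_reproduces_run(fitted):
    trace = fitted.run(arm="control")
    re = accrue_qaly(trace)
    assert re.qaly == pytest.approx(trace.qaly, rel=1e-10)
    assert re.qaly_discounted == pytest.approx(trace.qaly_discounted, rel=1e-10)
    halved = accrue_qaly(trace, utilities=tuple(u / 2 for u in trace.spec.utilities),
                         event_disutilities={}, ae_disutilities={})
    assert halved.qaly < trace.qaly


# -- full-trace invariants ---------------------------------------------------


def test_trace_invariants_over_full_horizon(fitted):
    for arm in ("control", "active"):
        trace = fitted.run(arm=arm)
        df = trace.df
        assert len(df) == 366  # 28 years of 28-day cycles
        mass = df[OCC_COLS].sum(axis=1)
        assert np.max(np.abs(mass - 1.0)) < 1e-12
        for col in ("occ_CV_death", "occ_nonCV_death"):
            assert np.all(np.diff(df[col]) >= -1e-15)  # absorbing
        for col in ("ly", "ly_disc", "qaly"):
            assert np.all(df[col] >= 0)
        assert trace.ly_discounted <= trace.ly
        assert trace.qaly <= trace.ly  # utilities <= 1
        assert trace.qaly_discounted <= trace.ly_discounted


def test_active_arm_blends_to_control_after_discontinuation(fitted):
    """With an immediate-discontinuation curve the active arm reproduces
    control-arm mortality."""
    import dataclasses
    inputs = fitted.inputs
    instant = CycleProbability(1.0, source_window_days=28.0)
    blended = dataclasses.replace(inputs, discontinuation=instant)
    active = run_cohort(fitted.spec, blended, arm="active")
    control = run_cohort(fitted.spec, blended, arm="control")
    # after cycle 0 the active cohort carries control risks; survival curves
    # coincide except for the first-cycle active contribution
    a = active.df["p_cv"].to_numpy()[1:]
    c = control.df["p_cv"].to_numpy()[1:]
    assert np.allclose(a, c, rtol=1e-12)


def test_on_treatment_fraction_conventions():
    t = np.array([0.0, 1.0, 2.0])
    assert np.allclose(on_treatment_fraction(None, t, 28.0), 1.0)
    p = CycleProbability(0.05, source_window_days=28.0)
    frac = on_treatment_fraction(p, t, 28.0)
    assert np.allclose(frac, (1 - 0.05) ** (t * 365.25 / 28))
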