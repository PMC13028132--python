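"""Cohort state-transition engine.

Six states: four alive KCCQ-TSS quartile states (Q1 worst .. Q4 best) plus
absorbing CV-death and non-CV-death states.  The cohort advances in 28-day
cycles over a 28-year horizon (366 cycles).  Each cycle, deaths are applied
first (competing-risk style, probabilities taken as given), survivors then
redistribute among the KCCQ states by a 30-day transition matrix mapped
one-to-one onto the model cycle.  Non-CV mortality is the all-cause minus
CV remainder, capped by the CV-deleted life-table probability at the
cohort's attained (integer) age.

Recurrent HHF/UHFV expectations come from log-linear per-cycle rate models
evaluated at the cohort's attained age and fixed sex/race mix, multiplied
by the half-cycle-corrected alive mass.  Life years and QALYs accrue with
trapezoidal half-cycle correction and annual discounting from time zero
(an optional first-year-exempt dialect covers comparator conventions).
An active-arm run blends active and control risk sets by the on-treatment
fraction implied by the discontinuation curve: after stopping therapy,
patients carry control-arm risks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .estimation import (
    DAYS_PER_YEAR,
    CycleProbability,
    EventRateModel,
    SurvivalFit,
    TransitionMatrix,
)
from .lifetable import LifeTable
from .synthetic import DEFAULT_KCCQ_MIX, DEFAULT_RACE_MIX

STATES = ("Q1", "Q2", "Q3", "Q4", "CV_death", "nonCV_death")
ALIVE = slice(0, 4)

MortalitySource = Union[SurvivalFit, CycleProbability, float, None]


class EngineError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Structural settings of the cohort model.

    Utilities are per KCCQ state (Q1..Q4); ``age_decrement_per_year`` is the
    utility change per year of attained age beyond baseline (default
    -0.0051).  Event disutilities are one-off QALY decrements per expected
    HHF/UHFV occurrence; AE disutilities apply per expected adverse event.
    ``hf_event_disutility_excluded_before_years`` suppresses HF-event
    disutilities for cycles starting before that time (a comparator-model
    convention; 0 disables the exclusion).
    """

    start_age: float = 72.0
    male_fraction: float = 0.545
    race_mix: dict = field(default_factory=lambda: dict(DEFAULT_RACE_MIX))
    start_occupancy: tuple = DEFAULT_KCCQ_MIX
    cycle_days: float = 28.0
    horizon_years: float = 28.0
    discount_annual: float = 0.035
    discount_first_year_exempt: bool = False
    utilities: tuple = (0.640, 0.740, 0.810, 0.870)
    age_decrement_per_year: float = -0.0051
    event_disutilities: dict = field(default_factory=lambda: {"HHF": 0.042, "UHFV": 0.015})
    ae_disutilities: dict = field(default_factory=lambda: {"hyperkalaemia": 0.002, "other_ae": 0.002})
    ae_disutilities_on: bool = True
    hf_event_disutility_excluded_before_years: float = 0.0

    def __post_init__(self):
        if abs(sum(self.start_occupancy) - 1.0) > 1e-9:
            raise ValueError("start_occupancy must sum to 1")
        if any(not -1.0 <= u <= 1.0 for u in self.utilities):
            raise ValueError("utilities must lie in [-1, 1]")
        if self.horizon_years * DAYS_PER_YEAR < self.cycle_days:
            raise ValueError("horizon shorter than one cycle")

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / DAYS_PER_YEAR

    @property
    def n_cycles(self) -> int:
        return int(np.ceil(self.horizon_years * DAYS_PER_YEAR / self.cycle_days - 1e-9))

    def replace(self, **kwargs) -> "ModelSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass
class ArmInputs:
    """Fitted inputs for one treatment arm."""

    transition: TransitionMatrix
    event_models: Mapping[str, EventRateModel]
    cv_mortality: MortalitySource
    allcause_mortality: MortalitySource
    ae_probabilities: Mapping[str, CycleProbability] = field(default_factory=dict)


@dataclass
class ModelInputs:
    """All fitted components feeding a two-arm model run."""

    control: ArmInputs
    active: ArmInputs
    discontinuation: MortalitySource = None
    life_table: Optional[LifeTable] = None


# ---------------------------------------------------------------------------
# per-cycle probability plumbing
# ---------------------------------------------------------------------------


def _per_cycle_probability(source: MortalitySource, t_years: np.ndarray,
                           cycle_days: float) -> np.ndarray:
    """Per-cycle event probability at each cycle-start time."""
    t_years = np.asarray(t_years, dtype=float)
    if source is None:
        return np.zeros_like(t_years)
    if isinstance(source, SurvivalFit):
        return source.per_cycle_probability(t_years, cycle_days / DAYS_PER_YEAR)
    if isinstance(source, CycleProbability):
        return np.full_like(t_years, source.for_cycle(cycle_days))
    if isinstance(source, (int, float)):
        if not 0.0 <= source <= 1.0:
            raise ValueError("constant probability outside [0, 1]")
        return np.full_like(t_years, float(source))
    raise TypeError(f"unsupported mortality source {type(source)!r}")


def on_treatment_fraction(discontinuation: MortalitySource, t_years: np.ndarray,
                          cycle_days: float) -> np.ndarray:
    """Fraction of the active cohort still on therapy at each cycle start."""
    t_years = np.asarray(t_years, dtype=float)
    if discontinuation is None:
        return np.ones_like(t_years)
    if isinstance(discontinuation, SurvivalFit):
        return discontinuation.survival(t_years)
    if isinstance(discontinuation, CycleProbability):
        p = discontinuation.for_cycle(cycle_days)
        cycles = t_years * DAYS_PER_YEAR / cycle_days
        return (1.0 - p) ** cycles
    if isinstance(discontinuation, (int, float)) and float(discontinuation) == 0.0:
        return np.ones_like(t_years)
    raise TypeError(f"unsupported discontinuation source {type(discontinuation)!r}")


def build_mortality_schedule(cv: MortalitySource, allcause: MortalitySource,
                             life_table: Optional[LifeTable], spec: ModelSpec,
                             n_cycles: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle (p_cv, p_noncv) with the life-table cap applied.

    Model-implied non-CV probability is the all-cause minus CV remainder
    (floored at 0); the cap is the CV-deleted life-table probability at the
    integer attained age, converted to the cycle length.
    """
    n_cycles = spec.n_cycles if n_cycles is None else n_cycles
    t_years = np.arange(n_cycles) * spec.cycle_years
    p_cv = _per_cycle_probability(cv, t_years, spec.cycle_days)
    p_ac = _per_cycle_probability(allcause, t_years, spec.cycle_days)
    p_ncv = np.clip(p_ac - p_cv, 0.0, 1.0)
    if life_table is not None:
        ages = np.floor(spec.start_age + t_years).astype(int)
        cap = np.array([life_table.per_cycle_noncv_probability(a, spec.male_fraction,
                                                               spec.cycle_days)
                        for a in ages])
        p_ncv = np.minimum(p_ncv, cap)
    if np.any(p_cv + p_ncv > 1.0 + 1e-12):
        raise EngineError("p_cv + p_noncv exceeds 1 in some cycle")
    return p_cv, p_ncv


def step_cohort(occupancy: np.ndarray, transition: TransitionMatrix | np.ndarray,
                p_cv: float, p_noncv: float) -> np.ndarray:
    """Advance the 6-state occupancy vector by one cycle.

    Deaths are applied to every alive state first; survivors then move among
    KCCQ states by the (row-stochastic) transition matrix.
    """
    occ = np.asarray(occupancy, dtype=float)
    if occ.shape != (6,):
        raise ValueError("occupancy must have 6 entries")
    if np.any(occ < -1e-12):
        raise ValueError("negative occupancy")
    if abs(occ.sum() - 1.0) > 1e-9:
        raise EngineError("occupancy does not sum to 1")
    matrix = transition.matrix if isinstance(transition, TransitionMatrix) else np.asarray(transition)
    if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix not row-stochastic")
    if p_cv + p_noncv > 1.0 + 1e-12:
        raise EngineError("death probabilities exceed 1")
    alive = occ[ALIVE]
    new = np.empty(6)
    new[ALIVE] = (alive * (1.0 - p_cv - p_noncv)) @ matrix
    new[4] = occ[4] + alive.sum() * p_cv
    new[5] = occ[5] + alive.sum() * p_noncv
    return new


def expected_events(alive_mass: float, model: EventRateModel, cohort_age: float,
                    spec: ModelSpec) -> float:
    """Expected event count in one cycle for the given alive mass."""
    if alive_mass < 0:
        raise ValueError("negative alive mass")
    rate = float(model.expected_per_cycle(cohort_age, spec.male_fraction,
                                          spec.race_mix, cycle_days=spec.cycle_days))
    if rate < 0:
        raise EngineError("negative event rate")
    return alive_mass * rate


# ---------------------------------------------------------------------------
# trace
# ---------------------------------------------------------------------------


class CohortTrace:
    """Per-cycle occupancy, expected events, and LY/QALY accumulators.

    ``df`` has one row per cycle with cycle-start occupancy, per-cycle
    half-cycle-corrected expected events, and discounted/undiscounted LY and
    QALY contributions.
    """

    def __init__(self, df: pd.DataFrame, spec: ModelSpec, arm: str):
        self.df = df
        self.spec = spec
        self.arm = arm

    def total(self, quantity: str, discounted: bool = False) -> float:
        col = f"{quantity}_disc" if discounted else quantity
        return float(self.df[col].sum())

    @property
    def ly(self) -> float:
        return self.total("ly")

    @property
    def ly_discounted(self) -> float:
        return self.total("ly", discounted=True)

    @property
    def qaly(self) -> float:
        return self.total("qaly")

    @property
    def qaly_discounted(self) -> float:
        return self.total("qaly", discounted=True)

    def total_events(self, event_type: str) -> float:
        return float(self.df[f"events_{event_type}"].sum())

    def total_deaths(self, cause: str = "CV") -> float:
        col = "occ_CV_death" if cause == "CV" else "occ_nonCV_death"
        return float(self.df[col].iloc[-1] + self.df[f"d_{cause}"].iloc[-1])

    def cumulative_at(self, column: str, at_days: float) -> float:
        """Cumulative per-cycle quantity linearly interpolated to ``at_days``.

        Used to read a 29-month on-treatment window off a 32-cycle run.
        """
        delta = self.spec.cycle_days
        values = self.df[column].to_numpy()
        k = at_days / delta
        full = int(np.floor(k))
        if full >= len(values):
            return float(values.sum())
        return float(values[:full].sum() + (k - full) * values[full])

    def to_csv(self, path):
        self.df.to_csv(path, index=False)


def run_cohort(spec: ModelSpec, inputs: ModelInputs, arm: str = "control") -> CohortTrace:
    """Run the cohort model for one arm and return its trace.

    The active arm blends active and control per-cycle risks (mortality,
    event rates, KCCQ transitions, AE probabilities) by the on-treatment
    fraction from the discontinuation curve.
    """
    if arm not in ("active", "control"):
        raise ValueError("arm must be 'active' or 'control'")
    n = spec.n_cycles
    dy = spec.cycle_years
    t_years = np.arange(n) * dy
    age_t = spec.start_age + t_years

    def arm_schedules(ai: ArmInputs):
        p_cv, p_ncv = build_mortality_schedule(ai.cv_mortality, ai.allcause_mortality,
                                               inputs.life_table, spec, n_cycles=n)
        rates = {e: np.asarray(m.expected_per_cycle(age_t, spec.male_fraction, spec.race_mix,
                                                    cycle_days=spec.cycle_days), dtype=float)
                 for e, m in ai.event_models.items()}
        aes = {name: cp.for_cycle(spec.cycle_days) for name, cp in ai.ae_probabilities.items()}
        return p_cv, p_ncv, rates, ai.transition.matrix, aes

    c_cv, c_ncv, c_rates, c_T, c_aes = arm_schedules(inputs.control)
    if arm == "control":
        w = np.zeros(n)  # weight on active risk set
        a_cv, a_ncv, a_rates, a_T, a_aes = c_cv, c_ncv, c_rates, c_T, c_aes
    else:
        a_cv, a_ncv, a_rates, a_T, a_aes = arm_schedules(inputs.active)
        w = on_treatment_fraction(inputs.discontinuation, t_years, spec.cycle_days)

    event_types = sorted(set(c_rates) | set(a_rates))
    ae_types = sorted(set(c_aes) | set(a_aes))
    d = spec.discount_annual
    if spec.discount_first_year_exempt:
        disc = (1.0 + d) ** (-np.maximum(t_years - 1.0, 0.0))
    else:
        disc = (1.0 + d) ** (-t_years)

    occ = np.zeros(6)
    occ[ALIVE] = np.asarray(spec.start_occupancy, dtype=float)
    rows = []
    utilities = np.asarray(spec.utilities, dtype=float)
    for t in range(n):
        wt = w[t]
        p_cv = wt * a_cv[t] + (1 - wt) * c_cv[t]
        p_ncv = wt * a_ncv[t] + (1 - wt) * c_ncv[t]
        T = wt * a_T + (1 - wt) * c_T
        occ_next = step_cohort(occ, T, p_cv, p_ncv)
        if abs(occ_next.sum() - 1.0) > 1e-9:
            raise EngineError(f"occupancy leak at cycle {t}")

        alive0, alive1 = occ[ALIVE].sum(), occ_next[ALIVE].sum()
        mid = 0.5 * (alive0 + alive1)
        row = {"cycle": t, "time_years": t_years[t], "age": age_t[t],
               "p_cv": p_cv, "p_noncv": p_ncv, "on_treatment": wt}
        for s, name in enumerate(STATES):
            row[f"occ_{name}"] = occ[s]
        row["d_CV"] = occ_next[4] - occ[4]
        row["d_nonCV"] = occ_next[5] - occ[5]

        for e in event_types:
            r = wt * a_rates.get(e, np.zeros(n))[t] + (1 - wt) * c_rates.get(e, np.zeros(n))[t]
            row[f"events_{e}"] = mid * r
        for name in ae_types:
            p_ae = wt * a_aes.get(name, 0.0) + (1 - wt) * c_aes.get(name, 0.0)
            row[f"ae_{name}"] = mid * p_ae

        # utility-weighted occupancy at cycle start and end (trapezoid)
        decr0 = spec.age_decrement_per_year * t_years[t]
        decr1 = spec.age_decrement_per_year * (t_years[t] + dy)
        uw0 = float(occ[ALIVE] @ (utilities + decr0))
        uw1 = float(occ_next[ALIVE] @ (utilities + decr1))
        qaly = dy * 0.5 * (uw0 + uw1)
        if t_years[t] >= spec.hf_event_disutility_excluded_before_years:
            qaly -= sum(row.get(f"events_{e}", 0.0) * spec.event_disutilities.get(e, 0.0)
                        for e in event_types)
        if spec.ae_disutilities_on:
            qaly -= sum(row.get(f"ae_{name}", 0.0) * spec.ae_disutilities.get(name, 0.0)
                        for name in ae_types)

        row["ly"] = dy * mid
        row["ly_disc"] = row["ly"] * disc[t]
        row["qaly"] = qaly
        row["qaly_disc"] = qaly * disc[t]
        rows.append(row)
        occ = occ_next

    df = pd.DataFrame(rows)
    # final-state bookkeeping: store terminal occupancy on the last row
    for s, name in enumerate(STATES):
        df.loc[df.index[-1], f"final_{name}"] = occ[s]
    return CohortTrace(df, spec, arm)


def accrue_qaly(trace: CohortTrace, utilities=None, age_decrement_per_year=None,
                event_disutilities=None, ae_disutilities=None) -> CohortTrace:
    """Re-accrue QALYs on an existing trace under different utility inputs.

    Occupancy, events and discount factors are reused; only the QALY columns
    change.  Returns a new trace.
    """
    spec = trace.spec
    utilities = np.asarray(spec.utilities if utilities is None else utilities, dtype=float)
    if np.any(np.abs(utilities) > 1.0):
        raise ValueError("utilities must lie in [-1, 1]")
    decr = spec.age_decrement_per_year if age_decrement_per_year is None else age_decrement_per_year
    ed = dict(spec.event_disutilities if event_disutilities is None else event_disutilities)
    ad = dict(spec.ae_disutilities if ae_disutilities is None else ae_disutilities)

    df = trace.df.copy()
    dy = spec.cycle_years
    occ_cols = [f"occ_{s}" for s in STATES[:4]]
    occ = df[occ_cols].to_numpy()
    occ_end = np.vstack([occ[1:], df.iloc[[-1]][[f"final_{s}" for s in STATES[:4]]].to_numpy()])
    t0 = df["time_years"].to_numpy()
    uw0 = occ @ utilities + occ.sum(axis=1) * decr * t0
    uw1 = occ_end @ utilities + occ_end.sum(axis=1) * decr * (t0 + dy)
    qaly = dy * 0.5 * (uw0 + uw1)
    mask = t0 >= spec.hf_event_disutility_excluded_before_years
    for e, dis in ed.items():
        col = f"events_{e}"
        if col in df:
            qaly -= np.where(mask, df[col].to_numpy() * dis, 0.0)
    if spec.ae_disutilities_on:
        for name, dis in ad.items():
            col = f"ae_{name}"
            if col in df:
                qaly -= df[col].to_numpy() * dis
    disc = np.where(df["ly"].to_numpy() != 0,
                    df["ly_disc"].to_numpy() / np.where(df["ly"] != 0, df["ly"], 1.0), 1.0)
    df["qaly"] = qaly
    df["qaly_disc"] = qaly * disc
    return CohortTrace(df, spec, trace.arm)
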