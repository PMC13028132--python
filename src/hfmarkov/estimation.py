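"""Estimation of model inputs from patient-level trial data.

Four families of inputs feed the cohort engine:

* parametric survival fits (time to CV death, all-cause death, or treatment
  discontinuation), selected among six distributional families by AIC/BIC;
* generalised estimating equations for recurrent HHF/UHFV counts per
  28-day cycle (Poisson family, log link, exchangeable working correlation,
  log-exposure offset), with baseline age (continuous), sex and race as
  covariates;
* 30-day KCCQ quartile-to-quartile transition matrices (row-normalised
  observed moves);
* conversions of published rates/proportions to per-cycle probabilities
  under a constant-hazard assumption.

Survival fits are performed by lifelines; the Gompertz family, which
lifelines does not ship, is provided as a custom parametric fitter.  GEE
fits are performed by statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import (
    ExponentialFitter,
    GeneralizedGammaFitter,
    LogLogisticFitter,
    LogNormalFitter,
    WeibullFitter,
)
from lifelines.fitters import ParametricUnivariateFitter

from .kccq import assign_quartile

DAYS_PER_YEAR = 365.25
MONTH_DAYS = DAYS_PER_YEAR / 12.0

RACE_LEVELS = ("White", "Asian", "Black", "Other")
SEX_LEVELS = ("male", "female")


class EstimationError(RuntimeError):
    """Raised when an input-estimation step cannot produce a usable fit."""


# ---------------------------------------------------------------------------
# Parametric survival
# ---------------------------------------------------------------------------


class GompertzFitter(ParametricUnivariateFitter):
    """Gompertz survival model with increasing hazard.

    Hazard h(t) = lambda * exp(gamma * t); cumulative hazard
    H(t) = lambda/gamma * (exp(gamma t) - 1).  Both parameters are
    constrained positive, which restricts the family to the
    increasing-hazard branch appropriate for mortality in an elderly
    cohort.
    """

    _fitted_parameter_names = ["lambda_", "gamma_"]
    _bounds = [(1e-9, None), (1e-9, None)]

    def _cumulative_hazard(self, params, times):
        lambda_, gamma_ = params
        return (lambda_ / gamma_) * np.expm1(gamma_ * times)


SURVIVAL_FAMILIES: Mapping[str, type] = {
    "exponential": ExponentialFitter,
    "weibull": WeibullFitter,
    "lognormal": LogNormalFitter,
    "loglogistic": LogLogisticFitter,
    "gompertz": GompertzFitter,
    "generalised_gamma": GeneralizedGammaFitter,
}


@dataclass
class SurvivalFit:
    """A fitted parametric time-to-event model on the year scale.

    ``survival(t)`` takes time in years from baseline.  AIC and BIC obey
    the usual identities (AIC = -2 ll + 2k, BIC = -2 ll + k ln n with
    n the number of subjects).
    """

    family: str
    endpoint: str
    parameters: dict
    log_likelihood: float
    aic: float
    bic: float
    n: int
    n_events: int
    _fitter: object = field(repr=False, default=None)

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)

    def survival(self, t_years) -> np.ndarray:
        """S(t) evaluated from the stored parameters.

        Closed forms are used where available so that perturbing
        ``parameters`` (e.g. in probabilistic sensitivity analysis)
        propagates to the curve; the generalised gamma falls back to the
        underlying fitter.
        """
        t = np.clip(np.atleast_1d(np.asarray(t_years, dtype=float)), 1e-12, None)
        p = self.parameters
        if self.family == "exponential":
            return np.exp(-t / p["lambda_"])
        if self.family == "weibull":
            return np.exp(-((t / p["lambda_"]) ** p["rho_"]))
        if self.family == "lognormal":
            from scipy.stats import norm
            return 1.0 - norm.cdf((np.log(t) - p["mu_"]) / p["sigma_"])
        if self.family == "loglogistic":
            return 1.0 / (1.0 + (t / p["alpha_"]) ** p["beta_"])
        if self.family == "gompertz":
            return np.exp(-(p["lambda_"] / p["gamma_"]) * np.expm1(p["gamma_"] * t))
        s = self._fitter.survival_function_at_times(t)
        return np.asarray(s, dtype=float)

    def per_cycle_probability(self, t_start_years, cycle_years) -> np.ndarray:
        """Conditional probability of the event within the next cycle."""
        t0 = np.atleast_1d(np.asarray(t_start_years, dtype=float))
        s0 = self.survival(t0)
        s1 = self.survival(t0 + cycle_years)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(s0 > 0, 1.0 - s1 / np.where(s0 > 0, s0, 1.0), 1.0)
        return np.clip(p, 0.0, 1.0)


def fit_parametric_survival(
    durations,
    event_observed,
    family: str,
    endpoint: str = "",
    time_unit: str = "days",
) -> SurvivalFit:
    """Maximum-likelihood fit of one parametric family to censored times.

    Parameters
    ----------
    durations : array-like
        Time to event or censoring (strictly positive).
    event_observed : array-like of bool/int
        1 where the endpoint occurred, 0 where censored.
    family : str
        One of ``SURVIVAL_FAMILIES``.
    time_unit : {"days", "years"}
        Unit of ``durations``; fits are carried out in years.
    """
    if family not in SURVIVAL_FAMILIES:
        raise ValueError(f"unknown survival family {family!r}")
    t = np.asarray(durations, dtype=float)
    e = np.asarray(event_observed, dtype=bool)
    if t.size == 0:
        raise EstimationError("no observations")
    if np.any(t < 0):
        raise ValueError("negative durations are not permitted")
    if not e.any():
        raise EstimationError(f"all observations censored for {endpoint or family}")
    if time_unit == "days":
        t = t / DAYS_PER_YEAR
    elif time_unit != "years":
        raise ValueError("time_unit must be 'days' or 'years'")
    t = np.clip(t, 1e-8, None)

    if family == "exponential" and t.size < 2:
        # closed-form MLE; optimiser-backed fitters need more than one row
        d, total = float(e.sum()), float(t.sum())
        rate = d / total
        ll = d * np.log(rate) - rate * total
        return SurvivalFit(family="exponential", endpoint=endpoint,
                           parameters={"lambda_": 1.0 / rate},
                           log_likelihood=ll, aic=-2.0 * ll + 2.0,
                           bic=-2.0 * ll + np.log(t.size), n=int(t.size),
                           n_events=int(e.sum()))

    fitter = SURVIVAL_FAMILIES[family]()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fitter.fit(t, event_observed=e)
        except Exception as exc:  # convergence failures surface as one error type
            raise EstimationError(f"{family} fit failed for {endpoint}: {exc}") from exc

    params = {name: float(getattr(fitter, name)) for name in fitter._fitted_parameter_names}
    ll = float(fitter.log_likelihood_)
    k = len(params)
    n = int(t.size)
    return SurvivalFit(
        family=family,
        endpoint=endpoint,
        parameters=params,
        log_likelihood=ll,
        aic=-2.0 * ll + 2.0 * k,
        bic=-2.0 * ll + k * np.log(n),
        n=n,
        n_events=int(e.sum()),
        _fitter=fitter,
    )


def fit_all_families(
    durations, event_observed, endpoint: str = "", time_unit: str = "days",
    families: Sequence[str] = tuple(SURVIVAL_FAMILIES),
) -> list[SurvivalFit]:
    """Fit every requested family, silently dropping ones that fail."""
    fits = []
    for fam in families:
        try:
            fits.append(fit_parametric_survival(durations, event_observed, fam,
                                                endpoint=endpoint, time_unit=time_unit))
        except EstimationError as exc:
            warnings.warn(f"skipping {fam}: {exc}")
    if not fits:
        raise EstimationError(f"no survival family could be fitted for {endpoint}")
    return fits


def select_best_fit(fits: Sequence[SurvivalFit], criterion: str = "AIC") -> SurvivalFit:
    """Return the fit minimising AIC or BIC.

    Ties within 2 information-criterion units are broken in favour of the
    family with fewer parameters (then the lower criterion value).
    """
    if not fits:
        raise ValueError("no fits supplied")
    endpoints = {f.endpoint for f in fits}
    if len(endpoints) > 1:
        raise ValueError(f"fits mix endpoints: {sorted(endpoints)}")
    if criterion.upper() == "AIC":
        value = lambda f: f.aic  # noqa: E731
    elif criterion.upper() == "BIC":
        value = lambda f: f.bic  # noqa: E731
    else:
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    best = min(value(f) for f in fits)
    contenders = [f for f in fits if value(f) <= best + 2.0]
    return min(contenders, key=lambda f: (f.n_parameters, value(f)))


# ---------------------------------------------------------------------------
# Per-cycle probability conversions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CycleProbability:
    """A constant per-cycle event probability and its provenance.

    ``source_window_days`` records the cycle length the probability refers
    to, so it can be re-expressed on a different cycle grid via the
    constant-hazard transform.
    """

    value: float
    source_quantity: str = "probability"
    source_window_days: float = 28.0

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"probability {self.value} outside [0, 1]")
        if self.source_window_days <= 0:
            raise ValueError("source window must be positive")

    def for_cycle(self, cycle_days: float) -> float:
        """Re-express on a ``cycle_days`` grid assuming a constant hazard."""
        if cycle_days == self.source_window_days:
            return self.value
        if self.value >= 1.0:
            return 1.0
        return 1.0 - (1.0 - self.value) ** (cycle_days / self.source_window_days)


def rate_to_cycle_probability(rate_per_100py: float, cycle_days: float = MONTH_DAYS) -> CycleProbability:
    """Convert an event rate per 100 person-years to a per-cycle probability.

    Uses the constant-hazard transform p = 1 - exp(-(rate/100) * cycle_years);
    e.g. 3.56 per 100 person-years over a 1-month cycle gives 0.0030 (4 dp).
    """
    if rate_per_100py < 0:
        raise ValueError("rate must be non-negative")
    if cycle_days <= 0:
        raise ValueError("cycle length must be positive")
    p = 1.0 - np.exp(-(rate_per_100py / 100.0) * (cycle_days / DAYS_PER_YEAR))
    return CycleProbability(float(p), source_quantity="rate", source_window_days=cycle_days)


def proportion_to_cycle_probability(
    proportion: float, followup_days: float, cycle_days: float = 28.0
) -> CycleProbability:
    """Convert a cumulative trial proportion to a per-cycle probability.

    Assumes constant risk: p = 1 - (1 - proportion)^(cycle/followup), so that
    compounding p over followup/cycle cycles recovers the proportion.
    """
    if not 0.0 <= proportion < 1.0:
        raise ValueError("proportion must lie in [0, 1)")
    if cycle_days <= 0 or followup_days < cycle_days:
        raise ValueError("need followup >= cycle length > 0")
    p = 1.0 - (1.0 - proportion) ** (cycle_days / followup_days)
    return CycleProbability(float(p), source_quantity="proportion", source_window_days=cycle_days)


# ---------------------------------------------------------------------------
# KCCQ transition matrices
# ---------------------------------------------------------------------------


@dataclass
class TransitionMatrix:
    """Row-stochastic 4x4 matrix of 30-day KCCQ quartile transitions."""

    matrix: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("transition matrix must be 4x4")
        if np.any(m < 0):
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        self.matrix = m

    @classmethod
    def identity(cls) -> "TransitionMatrix":
        return cls(np.eye(4))


def estimate_transition_matrix(kccq_panel: pd.DataFrame, patient_col: str = "patient_id",
                               time_col: str = "time_days", score_col: str = "score") -> TransitionMatrix:
    """Estimate the 30-day quartile transition matrix from longitudinal KCCQ data.

    ``kccq_panel`` holds one row per assessment.  Consecutive assessments of
    the same patient contribute one observed move; rows are normalised
    counts.  A quartile never observed as an origin keeps an identity row
    (with a warning).
    """
    if kccq_panel.empty:
        raise ValueError("empty KCCQ panel")
    df = kccq_panel.sort_values([patient_col, time_col])
    q = assign_quartile(df[score_col].to_numpy())
    pid = df[patient_col].to_numpy()
    same = pid[1:] == pid[:-1]
    src, dst = q[:-1][same], q[1:][same]
    counts = np.zeros((4, 4))
    np.add.at(counts, (src, dst), 1.0)
    matrix = np.eye(4)
    for i in range(4):
        total = counts[i].sum()
        if total > 0:
            matrix[i] = counts[i] / total
        else:
            warnings.warn(f"no observed transitions out of Q{i + 1}; identity row used")
    return TransitionMatrix(matrix, counts=counts)


# ---------------------------------------------------------------------------
# Recurrent-event (GEE) models
# ---------------------------------------------------------------------------


@dataclass
class EventRateModel:
    """Log-linear per-cycle expected event count given age, sex and race.

    ``coefficients`` maps {intercept, age, sex_male, race_Asian, race_Black,
    race_Other} to values on the log scale; the intercept refers to a
    female, White subject at age 0 over one ``cycle_days`` cycle.  Age is a
    continuous predictor, so the predicted rate changes as a cohort ages.
    """

    event_type: str
    arm: str
    coefficients: dict
    cycle_days: float = 28.0
    zero_rate: bool = False
    stderr: dict | None = None
    working_correlation: str = "exchangeable"

    _RACE_KEYS = {r: f"race_{r}" for r in RACE_LEVELS if r != "White"}

    def linear_predictor(self, age: float, male: float, race_mix: Mapping[str, float]) -> float:
        c = self.coefficients
        lp = c.get("intercept", 0.0) + c.get("age", 0.0) * age + c.get("sex_male", 0.0) * male
        for race, key in self._RACE_KEYS.items():
            lp += c.get(key, 0.0) * race_mix.get(race, 0.0)
        return lp

    def per_cycle_rate(self, age, sex: str, race: str, cycle_days: float | None = None) -> np.ndarray:
        """Expected event count per cycle for one covariate cell."""
        if self.zero_rate:
            return np.zeros_like(np.asarray(age, dtype=float))
        c = self.coefficients
        age = np.asarray(age, dtype=float)
        lp = c.get("intercept", 0.0) + c.get("age", 0.0) * age
        if sex == "male":
            lp = lp + c.get("sex_male", 0.0)
        if race != "White":
            lp = lp + c.get(f"race_{race}", 0.0)
        scale = 1.0 if cycle_days is None else cycle_days / self.cycle_days
        return np.exp(lp) * scale

    def per_cycle_rates(self, age, male, race, cycle_days: float | None = None) -> np.ndarray:
        """Vectorised per-subject rates: ``age`` float array, ``male`` 0/1
        array, ``race`` array of level labels."""
        age = np.asarray(age, dtype=float)
        if self.zero_rate:
            return np.zeros_like(age)
        c = self.coefficients
        lp = c.get("intercept", 0.0) + c.get("age", 0.0) * age
        lp = lp + c.get("sex_male", 0.0) * np.asarray(male, dtype=float)
        race = np.asarray(race)
        for r, key in self._RACE_KEYS.items():
            coef = c.get(key, 0.0)
            if coef:
                lp = lp + coef * (race == r)
        scale = 1.0 if cycle_days is None else cycle_days / self.cycle_days
        return np.exp(lp) * scale

    def expected_per_cycle(self, age, male_fraction: float, race_mix: Mapping[str, float],
                           cycle_days: float | None = None) -> np.ndarray:
        """Cohort-expected count per cycle, averaging over sex x race cells."""
        if self.zero_rate:
            return np.zeros_like(np.asarray(age, dtype=float))
        c = self.coefficients
        age = np.asarray(age, dtype=float)
        base = np.exp(c.get("intercept", 0.0) + c.get("age", 0.0) * age)
        sex_factor = male_fraction * np.exp(c.get("sex_male", 0.0)) + (1.0 - male_fraction)
        race_factor = sum(
            race_mix.get(r, 0.0) * np.exp(c.get(f"race_{r}", 0.0)) if r != "White"
            else race_mix.get(r, 0.0)
            for r in RACE_LEVELS
        )
        scale = 1.0 if cycle_days is None else cycle_days / self.cycle_days
        return base * sex_factor * race_factor * scale

    @classmethod
    def from_rate(cls, rate_per_100py: float, event_type: str, arm: str,
                  age: float = 0.0, sex_male: float = 0.0, race: Mapping[str, float] | None = None,
                  ref_age: float = 72.0, ref_male_fraction: float = 0.545,
                  ref_race_mix: Mapping[str, float] | None = None,
                  cycle_days: float = 28.0) -> "EventRateModel":
        """Build a model whose cohort-expected rate at the reference covariate
        mix equals ``rate_per_100py`` (events per 100 person-years)."""
        if rate_per_100py < 0:
            raise ValueError("rate must be non-negative")
        if rate_per_100py == 0:
            return cls(event_type, arm, {"intercept": -np.inf}, cycle_days=cycle_days, zero_rate=True)
        race = dict(race or {})
        coeffs = {"intercept": 0.0, "age": age, "sex_male": sex_male}
        for r in RACE_LEVELS:
            if r != "White":
                coeffs[f"race_{r}"] = race.get(r, 0.0)
        if ref_race_mix is None:
            ref_race_mix = {"White": 1.0}
        probe = cls(event_type, arm, coeffs, cycle_days=cycle_days)
        base = float(probe.expected_per_cycle(ref_age, ref_male_fraction, ref_race_mix))
        target = (rate_per_100py / 100.0) * (cycle_days / DAYS_PER_YEAR)
        coeffs["intercept"] = float(np.log(target) - np.log(base))
        return cls(event_type, arm, coeffs, cycle_days=cycle_days)


def build_cycle_panel(baseline: pd.DataFrame, events: pd.DataFrame, event_type: str,
                      arm: str | None = None, cycle_days: float = 28.0) -> pd.DataFrame:
    """Expand patient records into one row per subject per 28-day cycle.

    Columns: patient_id, cycle, age (attained, years), male, race dummies,
    count (events of ``event_type`` in the cycle), exposure_days.  Exposure
    ends at death or censoring; zero-exposure rows are dropped.
    """
    sub = baseline if arm is None else baseline[baseline["arm"] == arm]
    if sub.empty:
        raise EstimationError(f"no subjects in arm {arm!r}")
    death = sub["death_time"].fillna(np.inf).to_numpy(dtype=float)
    end = np.minimum(sub["censor_time"].to_numpy(dtype=float), death)
    n_cycles = np.maximum(np.ceil(end / cycle_days), 1).astype(int)

    pid = np.repeat(sub["patient_id"].to_numpy(), n_cycles)
    cyc = np.concatenate([np.arange(k) for k in n_cycles])
    start = cyc * cycle_days
    stop = np.minimum(start + cycle_days, np.repeat(end, n_cycles))
    exposure = stop - start

    age0 = np.repeat(sub["age_baseline"].to_numpy(dtype=float), n_cycles)
    male = np.repeat((sub["sex"] == "male").to_numpy(), n_cycles).astype(float)
    race = np.repeat(sub["race"].to_numpy(), n_cycles)

    panel = pd.DataFrame({
        "patient_id": pid,
        "cycle": cyc,
        "age": age0 + start / DAYS_PER_YEAR,
        "male": male,
        "race": race,
        "exposure_days": exposure,
    })
    ev = events[events["event_type"] == event_type]
    if arm is not None:
        ev = ev[ev["patient_id"].isin(set(sub["patient_id"]))]
    if len(ev):
        key = pd.MultiIndex.from_arrays(
            [ev["patient_id"], (ev["time_days"] // cycle_days).astype(int)])
        counts = key.value_counts()
        panel_key = pd.MultiIndex.from_arrays([panel["patient_id"], panel["cycle"]])
        panel["count"] = counts.reindex(panel_key, fill_value=0).to_numpy()
    else:
        panel["count"] = 0
    panel = panel[panel["exposure_days"] > 0].reset_index(drop=True)
    if (panel["count"] < 0).any():
        raise ValueError("negative event counts")
    return panel


def fit_event_gee(baseline: pd.DataFrame, events: pd.DataFrame, event_type: str, arm: str,
                  cycle_days: float = 28.0,
                  covariates: Sequence[str] = ("age", "sex", "race"),
                  working_correlation: str = "exchangeable") -> EventRateModel:
    """Fit the per-cycle recurrent-event GEE for one event type and arm.

    Poisson family, log link, exchangeable working correlation across each
    subject's cycles, with offset log(exposure/cycle) so coefficients are on
    the per-full-cycle scale.  Covariates: attained age (continuous, years),
    male sex, race contrasts versus White.  A race level absent from the data
    is dropped with a warning (its coefficient treated as 0).
    """
    panel = build_cycle_panel(baseline, events, event_type, arm=arm, cycle_days=cycle_days)
    if panel["exposure_days"].sum() <= 0:
        raise EstimationError("zero total exposure")
    if panel["count"].sum() == 0:
        warnings.warn(f"no {event_type} events in arm {arm}; returning zero-rate model")
        return EventRateModel(event_type, arm, {"intercept": -np.inf},
                              cycle_days=cycle_days, zero_rate=True)

    cols = {"intercept": np.ones(len(panel))}
    if "age" in covariates:
        cols["age"] = panel["age"].to_numpy()
    if "sex" in covariates:
        cols["sex_male"] = panel["male"].to_numpy()
    if "race" in covariates:
        for race in RACE_LEVELS:
            if race == "White":
                continue
            ind = (panel["race"] == race).to_numpy(dtype=float)
            if ind.sum() > 0:
                cols[f"race_{race}"] = ind
            else:
                warnings.warn(f"race level {race!r} absent; contrast dropped")
    exog = pd.DataFrame(cols)
    offset = np.log(panel["exposure_days"].to_numpy() / cycle_days)
    structs = {"exchangeable": sm.cov_struct.Exchangeable,
               "independence": sm.cov_struct.Independence}
    if working_correlation not in structs:
        raise ValueError("working_correlation must be 'exchangeable' or 'independence'")
    model = sm.GEE(panel["count"].to_numpy(), exog, groups=panel["patient_id"].to_numpy(),
                   family=sm.families.Poisson(), cov_struct=structs[working_correlation](),
                   offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100)
    coeffs = {k: float(v) for k, v in zip(exog.columns, res.params)}
    stderr = {k: float(v) for k, v in zip(exog.columns, res.bse)}
    return EventRateModel(event_type, arm, coeffs, cycle_days=cycle_days, stderr=stderr,
                          working_correlation=working_correlation)
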