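"""Synthetic two-arm HF trial generator.

Produces patient-level data with the statistical structure the cohort model
assumes: baseline covariates (truncated-normal age, sex, race, KCCQ-TSS
quartile occupancy), recurrent HHF/UHFV events from per-cycle log-linear
rate models with a continuous age effect, cause-specific CV/non-CV death
times under first-event-wins competing risks, log-normal treatment
discontinuation, and a 30-day KCCQ panel evolving by a monthly quartile
transition matrix.  The real trial informing the model is confidential, so
every estimation and validation stage in this package is exercised against
this generator instead.

Default parameters describe a contemporary HFmr/pEF population: mean age 72
(SD 10, truncated to 40-97), 54.5% male, and event/mortality magnitudes such
that a ~3000-per-arm trial followed for 29 months yields event counts of the
order seen in recent phase 3 HF trials.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .estimation import DAYS_PER_YEAR, EventRateModel, RACE_LEVELS
from .kccq import KCCQ_BOUNDS, assign_quartile, quartile_occupancy

ARMS = ("active", "control")
EVENT_TYPES = ("HHF", "UHFV")
CAUSES = ("CV", "nonCV")

#: Default race mix (shares of White/Asian/Black/Other).
DEFAULT_RACE_MIX = {"White": 0.78, "Asian": 0.15, "Black": 0.02, "Other": 0.05}

#: Baseline KCCQ quartile occupancy (Q1..Q4).
DEFAULT_KCCQ_MIX = (0.2395, 0.2615, 0.2455, 0.2535)

#: Monthly KCCQ quartile transition matrix (rows: from-state Q1..Q4).
DEFAULT_KCCQ_MATRIX = np.array([
    [0.850, 0.120, 0.020, 0.010],
    [0.080, 0.800, 0.100, 0.020],
    [0.010, 0.090, 0.820, 0.080],
    [0.005, 0.015, 0.100, 0.880],
])


def default_event_models(race_mix: Mapping[str, float] | None = None) -> dict:
    """True recurrent-event rate models, one per (event type, arm).

    Rates are events per 100 person-years at the reference covariate mix
    (age 72, 54.5% male, default race mix); the positive age coefficient on
    HHF/UHFV drives the model's age sensitivity.
    """
    mix = dict(race_mix or DEFAULT_RACE_MIX)
    kw = dict(ref_age=72.0, ref_male_fraction=0.545, ref_race_mix=mix)
    return {
        ("HHF", "control"): EventRateModel.from_rate(10.5, "HHF", "control",
                                                     age=0.025, sex_male=0.10, **kw),
        ("HHF", "active"): EventRateModel.from_rate(7.35, "HHF", "active",
                                                    age=0.025, sex_male=0.10, **kw),
        ("UHFV", "control"): EventRateModel.from_rate(1.85, "UHFV", "control",
                                                      age=0.015, sex_male=0.05, **kw),
        ("UHFV", "active"): EventRateModel.from_rate(1.00, "UHFV", "active",
                                                     age=0.015, sex_male=0.05, **kw),
    }


def default_mortality() -> dict:
    """True cause-specific hazards per (cause, arm), as (family, *params).

    Exponential rates are per year; CV mortality carries the treatment
    effect, non-CV mortality does not.
    """
    return {
        ("CV", "control"): ("exponential", 0.027),
        ("CV", "active"): ("exponential", 0.023),
        ("nonCV", "control"): ("exponential", 0.016),
        ("nonCV", "active"): ("exponential", 0.016),
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic trial.

    ``true_mortality`` and ``true_discontinuation`` are hazard specs:
    ("exponential", rate_per_year), ("weibull", scale_years, shape) or
    ("lognormal", median_years, sigma).  Default follow-up is 29 months,
    the on-treatment window used for external validation.
    """

    n_per_arm: int = 3000
    seed: int = 7
    age_mean: float = 72.0
    age_sd: float = 10.0
    age_bounds: tuple = (40.0, 97.0)
    male_fraction: float = 0.545
    race_mix: dict = field(default_factory=lambda: dict(DEFAULT_RACE_MIX))
    kccq_quartile_mix: tuple = DEFAULT_KCCQ_MIX
    true_event_models: dict = field(default_factory=default_event_models)
    true_mortality: dict = field(default_factory=default_mortality)
    true_discontinuation: tuple = ("lognormal", 28.0 / 12.0, 1.1)
    kccq_monthly_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_KCCQ_MATRIX.copy())
    followup_days: float = 29 * DAYS_PER_YEAR / 12.0
    cycle_days: float = 28.0
    kccq_interval_days: float = 30.0

    def __post_init__(self):
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")
        if abs(sum(self.race_mix.values()) - 1.0) > 1e-9:
            raise ValueError("race_mix must sum to 1")
        if abs(sum(self.kccq_quartile_mix) - 1.0) > 1e-9:
            raise ValueError("kccq_quartile_mix must sum to 1")
        if np.any(np.asarray(list(self.race_mix.values())) < 0):
            raise ValueError("race probabilities must be non-negative")

    def to_yaml(self, path):
        d = dataclasses.asdict(self)
        d["kccq_monthly_matrix"] = np.asarray(self.kccq_monthly_matrix).tolist()
        d["true_event_models"] = {
            f"{e}/{a}": m.coefficients for (e, a), m in self.true_event_models.items()}
        d["true_mortality"] = {f"{c}/{a}": list(v) for (c, a), v in self.true_mortality.items()}
        d["true_discontinuation"] = list(self.true_discontinuation)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class PatientRecord:
    """One synthetic trial subject."""

    patient_id: str
    arm: str
    age_baseline: float
    sex: str
    race: str
    kccq_baseline: float
    kccq_panel: list          # [(assessment_time_days, score), ...]
    events: list              # [(time_days, event_type), ...]
    death: Optional[tuple]    # (time_days, cause) or None
    discontinuation_time: Optional[float]
    censor_time: float


class Trial:
    """Container for one generated trial: baseline, events and KCCQ panels.

    Behaves as a sequence of :class:`PatientRecord`; internally the data
    live in three tidy DataFrames (``baseline``, ``events``, ``kccq``).
    """

    def __init__(self, baseline: pd.DataFrame, events: pd.DataFrame,
                 kccq: pd.DataFrame, config: GeneratorConfig):
        self.baseline = baseline
        self.events = events
        self.kccq = kccq
        self.config = config

    def __len__(self) -> int:
        return len(self.baseline)

    def __iter__(self):
        return iter(self.to_records())

    def to_records(self) -> list[PatientRecord]:
        ev_by_pid = {pid: g for pid, g in self.events.groupby("patient_id")}
        kc_by_pid = {pid: g for pid, g in self.kccq.groupby("patient_id")}
        records = []
        for row in self.baseline.itertuples(index=False):
            ev = ev_by_pid.get(row.patient_id)
            kc = kc_by_pid.get(row.patient_id)
            death = None
            if np.isfinite(row.death_time):
                death = (float(row.death_time), row.death_cause)
            disc = None if not np.isfinite(row.discontinuation_time) else float(row.discontinuation_time)
            records.append(PatientRecord(
                patient_id=row.patient_id, arm=row.arm,
                age_baseline=float(row.age_baseline), sex=row.sex, race=row.race,
                kccq_baseline=float(row.kccq_baseline),
                kccq_panel=[] if kc is None else list(zip(kc["time_days"], kc["score"])),
                events=[] if ev is None else list(zip(ev["time_days"], ev["event_type"])),
                death=death, discontinuation_time=disc,
                censor_time=float(row.censor_time)))
        return records

    def write_csv(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.baseline.to_csv(directory / "baseline.csv", index=False)
        self.events.to_csv(directory / "events.csv", index=False)
        self.kccq.to_csv(directory / "kccq.csv", index=False)

    @classmethod
    def read_csv(cls, directory, config: GeneratorConfig | None = None) -> "Trial":
        directory = Path(directory)
        return cls(pd.read_csv(directory / "baseline.csv"),
                   pd.read_csv(directory / "events.csv"),
                   pd.read_csv(directory / "kccq.csv"),
                   config or GeneratorConfig())


def _sample_event_times(rng: np.random.Generator, spec: tuple, n: int) -> np.ndarray:
    """Draw times (days) from a hazard spec in years."""
    family = spec[0]
    if family == "exponential":
        rate = spec[1]
        if rate <= 0:
            return np.full(n, np.inf)
        return rng.exponential(1.0 / rate, size=n) * DAYS_PER_YEAR
    if family == "weibull":
        scale_years, shape = spec[1], spec[2]
        return scale_years * rng.weibull(shape, size=n) * DAYS_PER_YEAR
    if family == "lognormal":
        median_years, sigma = spec[1], spec[2]
        return np.exp(rng.normal(np.log(median_years), sigma, size=n)) * DAYS_PER_YEAR
    raise ValueError(f"unknown hazard family {family!r}")


def _uniform_in_band(rng: np.random.Generator, quartile: np.ndarray) -> np.ndarray:
    lo = np.asarray(KCCQ_BOUNDS)[quartile]
    hi = np.asarray(KCCQ_BOUNDS)[quartile + 1]
    return lo + rng.random(quartile.size) * (hi - lo)


def _step_quartile(rng: np.random.Generator, state: np.ndarray, cum: np.ndarray) -> np.ndarray:
    u = rng.random(state.size)
    return (u[:, None] > cum[state]).sum(axis=1).astype(np.int64)


def generate_trial(config: GeneratorConfig) -> Trial:
    """Generate one two-arm trial; byte-identical for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_per_arm
    frames_base, frames_ev, frames_kc = [], [], []

    for arm in ARMS:
        # --- baseline covariates -----------------------------------------
        lo, hi = config.age_bounds
        a = (lo - config.age_mean) / config.age_sd
        b = (hi - config.age_mean) / config.age_sd
        age = stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                                  size=n, random_state=rng)
        sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
        race_levels = list(config.race_mix)
        race = rng.choice(race_levels, size=n, p=[config.race_mix[r] for r in race_levels])
        q0 = rng.choice(4, size=n, p=np.asarray(config.kccq_quartile_mix))
        kccq0 = _uniform_in_band(rng, q0)

        # --- death (first-event-wins competing risks) --------------------
        t_cv = _sample_event_times(rng, config.true_mortality[("CV", arm)], n)
        t_ncv = _sample_event_times(rng, config.true_mortality[("nonCV", arm)], n)
        t_death = np.minimum(t_cv, t_ncv)
        cause = np.where(t_cv <= t_ncv, "CV", "nonCV")
        censor = np.full(n, float(config.followup_days))
        died = t_death <= censor
        death_time = np.where(died, t_death, np.inf)

        # --- treatment discontinuation (active arm only) ------------------
        if arm == "active":
            t_disc = _sample_event_times(rng, config.true_discontinuation, n)
            disc_time = np.where(t_disc < np.minimum(death_time, censor), t_disc, np.inf)
        else:
            disc_time = np.full(n, np.inf)

        pid = np.array([f"{arm[0].upper()}{i:06d}" for i in range(n)])

        # --- recurrent events, piecewise-constant rate per cycle ----------
        end = np.minimum(death_time, censor)
        n_cycles = int(np.ceil(config.followup_days / config.cycle_days))
        ev_pid, ev_time, ev_type = [], [], []
        models = config.true_event_models
        for k in range(n_cycles):
            start = k * config.cycle_days
            stop = start + config.cycle_days
            exposure = np.clip(np.minimum(end, stop) - start, 0.0, None)
            at_risk = exposure > 0
            if not at_risk.any():
                break
            age_k = age + start / DAYS_PER_YEAR
            on_soc = disc_time <= start  # switched to control risks
            for event_type in EVENT_TYPES:
                m_own = models[(event_type, arm)]
                m_soc = models[(event_type, "control")]
                lam = np.zeros(n)
                male01 = (sex == "male").astype(float)
                for model, mask in ((m_own, ~on_soc), (m_soc, on_soc)):
                    idx = mask & at_risk
                    if idx.any():
                        lam[idx] = model.per_cycle_rates(age_k[idx], male01[idx], race[idx])
                mean = lam * exposure / config.cycle_days
                counts = rng.poisson(mean)
                total = int(counts.sum())
                if total:
                    reps = np.repeat(np.arange(n), counts)
                    times = start + rng.random(total) * np.repeat(exposure, counts)
                    ev_pid.append(pid[reps])
                    ev_time.append(times)
                    ev_type.append(np.full(total, event_type, dtype=object))

        # --- KCCQ panel every 30 days -------------------------------------
        cum = config.kccq_monthly_matrix.cumsum(axis=1)
        max_assess = int(np.floor(config.followup_days / config.kccq_interval_days)) + 1
        state = q0.copy()
        kc_pid, kc_time, kc_score = [pid.copy()], [np.zeros(n)], [kccq0.copy()]
        for j in range(1, max_assess):
            t_j = j * config.kccq_interval_days
            state = _step_quartile(rng, state, cum)
            alive = end > t_j
            if not alive.any():
                break
            score = _uniform_in_band(rng, state)
            kc_pid.append(pid[alive])
            kc_time.append(np.full(int(alive.sum()), t_j))
            kc_score.append(score[alive])

        frames_base.append(pd.DataFrame({
            "patient_id": pid, "arm": arm, "age_baseline": age, "sex": sex,
            "race": race, "kccq_baseline": kccq0,
            "death_time": np.where(died, t_death, np.nan),
            "death_cause": np.where(died, cause, ""),
            "discontinuation_time": np.where(np.isfinite(disc_time), disc_time, np.nan),
            "censor_time": censor,
        }))
        if ev_pid:
            frames_ev.append(pd.DataFrame({
                "patient_id": np.concatenate(ev_pid),
                "time_days": np.concatenate(ev_time),
                "event_type": np.concatenate(ev_type),
            }))
        frames_kc.append(pd.DataFrame({
            "patient_id": np.concatenate(kc_pid),
            "time_days": np.concatenate(kc_time),
            "score": np.concatenate(kc_score),
        }))

    baseline = pd.concat(frames_base, ignore_index=True)
    baseline["death_time"] = baseline["death_time"].astype(float)
    if frames_ev:
        events = pd.concat(frames_ev, ignore_index=True)
        events = events.sort_values(["patient_id", "time_days"], kind="mergesort").reset_index(drop=True)
    else:
        events = pd.DataFrame({"patient_id": pd.Series(dtype=object),
                               "time_days": pd.Series(dtype=float),
                               "event_type": pd.Series(dtype=object)})
    kccq = pd.concat(frames_kc, ignore_index=True)
    kccq = kccq.sort_values(["patient_id", "time_days"], kind="mergesort").reset_index(drop=True)
    return Trial(baseline, events, kccq, config)


def summarize_baseline(data) -> dict:
    """Baseline summary: mean age, sex/race shares, KCCQ quartile occupancy.

    ``data`` may be a :class:`Trial`, a baseline DataFrame, or a sequence of
    :class:`PatientRecord`.
    """
    if isinstance(data, Trial):
        df = data.baseline
    elif isinstance(data, pd.DataFrame):
        df = data
    else:
        records = list(data)
        if not records:
            raise ValueError("empty record collection")
        df = pd.DataFrame({
            "age_baseline": [r.age_baseline for r in records],
            "sex": [r.sex for r in records],
            "race": [r.race for r in records],
            "kccq_baseline": [r.kccq_baseline for r in records],
        })
    if df.empty:
        raise ValueError("empty baseline data")
    occ = quartile_occupancy(df["kccq_baseline"].to_numpy())
    race_shares = df["race"].value_counts(normalize=True)
    return {
        "n": int(len(df)),
        "mean_age": float(df["age_baseline"].mean()),
        "male_fraction": float((df["sex"] == "male").mean()),
        "race_shares": {r: float(race_shares.get(r, 0.0)) for r in RACE_LEVELS},
        "kccq_occupancy": occ,
    }
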