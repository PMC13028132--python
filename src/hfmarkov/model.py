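"""Model/Results facade over the estimation and engine layers.

:class:`HFCohortModel` is built from patient-level trial data (tidy
baseline/events/KCCQ DataFrames or a generated :class:`~.synthetic.Trial`);
``fit()`` estimates every model input — per-arm parametric survival curves
for CV and all-cause death with AIC/BIC selection, a discontinuation curve,
per-arm recurrent-event GEEs and KCCQ transition matrices — and returns an
:class:`HFCohortResults` carrying the fitted inputs, fit diagnostics and a
``summary()`` table.  Cohort runs, external validation, scenario
re-configuration and sensitivity analyses hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import uncertainty as unc
from .engine import ArmInputs, CohortTrace, ModelInputs, ModelSpec, run_cohort
from .estimation import (
    SURVIVAL_FAMILIES,
    CycleProbability,
    EstimationError,
    SurvivalFit,
    fit_all_families,
    fit_event_gee,
    estimate_transition_matrix,
    proportion_to_cycle_probability,
    select_best_fit,
)
from .lifetable import LifeTable, make_synthetic_life_table
from .scenarios import apply_cohen_settings, apply_external_validation_settings
from .validation import age_sensitivity, cross_validation_table, run_external_validation


class HFCohortModel:
    """Cohort state-transition model bound to patient-level trial data.

    Parameters
    ----------
    baseline, events, kccq : DataFrame
        Tidy trial tables: one row per subject (columns patient_id, arm,
        age_baseline, sex, race, kccq_baseline, death_time, death_cause,
        discontinuation_time, censor_time); one row per dated event
        (patient_id, time_days, event_type); one row per KCCQ assessment
        (patient_id, time_days, score).
    life_table : LifeTable, optional
        Background-mortality cap; a synthetic Gompertz-Makeham table is
        used when omitted.
    spec : ModelSpec, optional
        Structural settings; defaults describe the base case (28-day
        cycles, 28-year horizon, 3.5% discounting).
    """

    def __init__(self, baseline: pd.DataFrame, events: pd.DataFrame,
                 kccq: pd.DataFrame, life_table: Optional[LifeTable] = None,
                 spec: Optional[ModelSpec] = None):
        self.baseline = baseline
        self.events = events
        self.kccq = kccq
        self.life_table = life_table or make_synthetic_life_table()
        self.spec = spec or ModelSpec()

    @classmethod
    def from_trial(cls, trial, **kwargs) -> "HFCohortModel":
        return cls(trial.baseline, trial.events, trial.kccq, **kwargs)

    @classmethod
    def from_csv(cls, directory, **kwargs) -> "HFCohortModel":
        from .synthetic import Trial
        return cls.from_trial(Trial.read_csv(directory), **kwargs)

    # -- estimation --------------------------------------------------------

    def fit(self, families: Sequence[str] = tuple(SURVIVAL_FAMILIES),
            criterion: str = "AIC",
            ae_proportions: Mapping[str, Mapping[str, float]] | None = None,
            ) -> "HFCohortResults":
        """Estimate all model inputs from the bound trial data.

        ``ae_proportions`` optionally maps AE name -> {arm: observed trial
        proportion}; proportions are converted to per-cycle probabilities
        over the trial's median follow-up.
        """
        fit_tables: dict = {}
        arm_inputs: dict = {}
        followup = float(self.baseline["censor_time"].median())

        for arm in ("control", "active"):
            sub = self.baseline[self.baseline["arm"] == arm]
            end = np.minimum(sub["censor_time"],
                             sub["death_time"].fillna(np.inf)).to_numpy(float)

            cv = self._select(end, (sub["death_cause"] == "CV").to_numpy(),
                              f"CV_death[{arm}]", families, criterion, fit_tables)
            ac = self._select(end, sub["death_time"].notna().to_numpy(),
                              f"all_cause_death[{arm}]", families, criterion, fit_tables)
            transition = estimate_transition_matrix(
                self.kccq[self.kccq["patient_id"].isin(set(sub["patient_id"]))])
            event_models = {e: fit_event_gee(self.baseline, self.events, e, arm,
                                             cycle_days=self.spec.cycle_days)
                            for e in ("HHF", "UHFV")}
            aes = {}
            for name, by_arm in (ae_proportions or {}).items():
                if arm in by_arm:
                    aes[name] = proportion_to_cycle_probability(
                        by_arm[arm], followup, self.spec.cycle_days)
            arm_inputs[arm] = ArmInputs(transition=transition, event_models=event_models,
                                        cv_mortality=cv, allcause_mortality=ac,
                                        ae_probabilities=aes)

        active = self.baseline[self.baseline["arm"] == "active"]
        disc_time = active["discontinuation_time"]
        end_active = np.minimum(active["censor_time"],
                                active["death_time"].fillna(np.inf)).to_numpy(float)
        observed = disc_time.notna().to_numpy()
        durations = np.where(observed, disc_time.fillna(0.0).to_numpy(float), end_active)
        try:
            disc_fit = self._select(durations, observed, "discontinuation",
                                    families, criterion, fit_tables)
        except EstimationError:
            disc_fit = None

        inputs = ModelInputs(control=arm_inputs["control"], active=arm_inputs["active"],
                             discontinuation=disc_fit, life_table=self.life_table)
        return HFCohortResults(model=self, spec=self.spec, inputs=inputs,
                               fit_tables=fit_tables)

    def _select(self, durations, observed, endpoint, families, criterion, fit_tables):
        fits = fit_all_families(durations, observed, endpoint=endpoint, families=families)
        best = select_best_fit(fits, criterion=criterion)
        table = pd.DataFrame(
            [{"family": f.family, "n_params": f.n_parameters,
              "log_likelihood": f.log_likelihood, "aic": f.aic, "bic": f.bic,
              "selected": f.family == best.family}
             for f in fits]).sort_values("aic").reset_index(drop=True)
        fit_tables[endpoint] = table
        return best


@dataclass
class HFCohortResults:
    """Fitted inputs plus everything that runs on top of them."""

    model: HFCohortModel
    spec: ModelSpec
    inputs: ModelInputs
    fit_tables: dict = field(default_factory=dict)

    # -- runs --------------------------------------------------------------

    def run(self, arm: str = "control", spec: Optional[ModelSpec] = None,
            inputs: Optional[ModelInputs] = None) -> CohortTrace:
        return run_cohort(spec or self.spec, inputs or self.inputs, arm=arm)

    def run_cohen_adjusted(self, arm: str = "control", **cohen_constants) -> CohortTrace:
        spec, inputs = apply_cohen_settings(self.spec, self.inputs, **cohen_constants)
        return run_cohort(spec, inputs, arm=arm)

    def cross_validation(self, cohen_constants: Mapping, arm: str = "control") -> pd.DataFrame:
        traces = {
            "base_case": self.run(arm=arm),
            "cohen_adjusted": self.run_cohen_adjusted(arm=arm, **cohen_constants),
        }
        return cross_validation_table(traces)

    # -- validation --------------------------------------------------------

    def external_validation(self, trial_counts, arm_n, age: float = 72.0,
                            window_months: float = 29.0) -> dict:
        return run_external_validation(self.spec, self.inputs, trial_counts,
                                       arm_n, age=age, window_months=window_months)

    def age_sensitivity(self, trial_counts, arm_n,
                        ages: Sequence[float] = (62.0, 72.0, 82.0),
                        window_months: float = 29.0) -> dict:
        return age_sensitivity(self.spec, self.inputs, trial_counts, arm_n,
                               ages=ages, window_months=window_months)

    # -- uncertainty -------------------------------------------------------

    def run_dsa(self, distributions, outcome_fn) -> pd.DataFrame:
        return unc.run_dsa(self.spec, self.inputs, distributions, outcome_fn)

    def run_psa(self, distributions, outcome_fn, n_iter: int = 1000,
                seed: int = 0, **kwargs) -> unc.PsaResult:
        return unc.run_psa(self.spec, self.inputs, distributions, outcome_fn,
                           n_iter=n_iter, seed=seed, **kwargs)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the selected fits and GEE coefficients."""
        lines = ["Heart-failure cohort model: fitted inputs",
                 "=" * 58]
        for endpoint, table in self.fit_tables.items():
            sel = table[table["selected"]].iloc[0] if "selected" in table else table.iloc[0]
            lines.append(f"{endpoint:<28s} selected {sel['family']:<18s} "
                         f"AIC {sel['aic']:10.2f}  BIC {sel['bic']:10.2f}")
        lines.append("-" * 58)
        for arm in ("control", "active"):
            ai = getattr(self.inputs, arm)
            for e, m in ai.event_models.items():
                if m.zero_rate:
                    lines.append(f"GEE {e:<5s}[{arm}]  zero-rate (no events)")
                    continue
                coef = ", ".join(f"{k}={v:+.4f}" for k, v in m.coefficients.items())
                lines.append(f"GEE {e:<5s}[{arm}]  {coef}")
        lines.append("-" * 58)
        disc = self.inputs.discontinuation
        if isinstance(disc, SurvivalFit):
            lines.append(f"discontinuation: {disc.family} "
                         f"(AIC {disc.aic:.2f}, n_events {disc.n_events})")
        else:
            lines.append(f"discontinuation: {disc!r}")
        return "\n".join(lines)
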