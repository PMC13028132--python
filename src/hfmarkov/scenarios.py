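"""Scenario adapters: comparator-aligned and external-validation settings.

Two reconfigurations of the base-case model are supported:

* ``apply_cohen_settings`` aligns the model with a published US
  SGLT-2i model that uses 1-month cycles, constant per-cycle mortality,
  HF-event and discontinuation probabilities, a 3% annual discount rate,
  no AE disutilities, HF-event disutilities only after the first year, and
  no discounting within the first year.  The constant rates are that
  model's inputs and must be supplied by the caller; nothing is defaulted.
* ``apply_external_validation_settings`` prepares an on-treatment
  comparison against trial event counts: discontinuation zeroed, a
  29-month undiscounted half-cycle-corrected window, and a configurable
  start age (the published sensitivity sweeps 62-82 years).

Adapters return modified copies; the input spec/inputs are never mutated,
and only the documented fields differ.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .engine import ArmInputs, ModelInputs, ModelSpec
from .estimation import MONTH_DAYS, CycleProbability, EventRateModel, rate_to_cycle_probability

logger = logging.getLogger(__name__)

#: Length of the on-treatment external-validation window, months.
EXTERNAL_VALIDATION_MONTHS = 29.0


@dataclass
class ScenarioConfig:
    """Declarative description of a model scenario."""

    name: str = "base_case"
    mortality_mode: str = "parametric"      # parametric | constant
    event_mode: str = "gee"                 # gee | constant
    discontinuation_mode: str = "parametric"  # parametric | constant | zero
    discount_annual: float = 0.035
    ae_disutilities_on: bool = True
    event_disutility_first_year_excluded: bool = False
    window_months: Optional[float] = None   # None = full horizon
    start_age: Optional[float] = None
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mortality_mode == "constant" and "cv_rate_per_100py" not in self.overrides:
            if self.name == "cohen_adjusted":
                raise ValueError("constant mortality mode needs rate overrides")


def apply_cohen_settings(spec: ModelSpec, inputs: ModelInputs, *,
                         cv_rate_per_100py: float,
                         allcause_rate_per_100py: float,
                         hf_event_rates_per_100py: Mapping,
                         discontinuation_monthly_probability: float,
                         utilities: tuple | None = None,
                         event_disutilities: Mapping[str, float] | None = None,
                         ) -> tuple[ModelSpec, ModelInputs]:
    """Reconfigure the model to the comparator's constant-rate settings.

    ``hf_event_rates_per_100py`` maps event type (or (event, arm)) to the
    constant rate.  The CV rate is converted to a monthly probability
    (3.56/100PY -> 0.0030); all-cause mortality is converted the same way
    and remains capped by the life table.  All constants are required:
    they are comparator inputs, not quantities this model can supply.
    """
    for name, val in (("cv_rate_per_100py", cv_rate_per_100py),
                      ("allcause_rate_per_100py", allcause_rate_per_100py)):
        if val is None or val < 0:
            raise ValueError(f"{name} must be a non-negative number")

    new_spec = spec.replace(
        cycle_days=MONTH_DAYS,
        discount_annual=0.03,
        ae_disutilities_on=False,
        hf_event_disutility_excluded_before_years=1.0,
        discount_first_year_exempt=True,
        **({"utilities": tuple(utilities)} if utilities is not None else {}),
        **({"event_disutilities": dict(event_disutilities)}
           if event_disutilities is not None else {}),
    )

    p_cv = rate_to_cycle_probability(cv_rate_per_100py, MONTH_DAYS)
    p_ac = rate_to_cycle_probability(allcause_rate_per_100py, MONTH_DAYS)
    disc = CycleProbability(discontinuation_monthly_probability,
                            source_quantity="probability", source_window_days=MONTH_DAYS)

    def constant_models(arm: str) -> dict:
        models = {}
        for key, rate in hf_event_rates_per_100py.items():
            if isinstance(key, tuple):
                event, key_arm = key
                if key_arm != arm:
                    continue
            else:
                event = key
            models[event] = EventRateModel.from_rate(rate, event, arm,
                                                     cycle_days=MONTH_DAYS)
        if not models:
            raise ValueError(f"no constant HF event rates supplied for arm {arm!r}")
        return models

    def adapt(ai: ArmInputs, arm: str) -> ArmInputs:
        return dataclasses.replace(ai, cv_mortality=p_cv, allcause_mortality=p_ac,
                                   event_models=constant_models(arm))

    new_inputs = ModelInputs(control=adapt(inputs.control, "control"),
                             active=adapt(inputs.active, "active"),
                             discontinuation=disc,
                             life_table=inputs.life_table)
    return new_spec, new_inputs


def apply_external_validation_settings(spec: ModelSpec, inputs: ModelInputs,
                                       age: float) -> tuple[ModelSpec, ModelInputs]:
    """Prepare the on-treatment external-validation configuration.

    Discontinuation is set to zero (required for an on-treatment
    comparison; it does not affect the control arm), the horizon becomes
    29 months, outputs are undiscounted, and the start age is set to
    ``age``.  Ages outside the published 62-82 sweep are allowed with a
    warning.
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    if not 62.0 <= age <= 82.0:
        warnings.warn(f"start age {age} outside the 62-82 sensitivity range")
    new_spec = spec.replace(
        start_age=float(age),
        horizon_years=EXTERNAL_VALIDATION_MONTHS / 12.0,
        discount_annual=0.0,
        discount_first_year_exempt=False,
    )
    if inputs.discontinuation is not None:
        logger.info("external validation: discontinuation curve present in inputs "
                    "is ignored (set to zero for the on-treatment comparison)")
    new_inputs = dataclasses.replace(inputs, discontinuation=None)
    return new_spec, new_inputs
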