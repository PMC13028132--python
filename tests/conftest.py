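import numpy as np
import pandas as pd
import pytest

import hfmarkov as hm
from hfmarkov.engine import ArmInputs, ModelInputs, ModelSpec
from hfmarkov.estimation import CycleProbability, TransitionMatrix
from hfmarkov.synthetic import DEFAULT_KCCQ_MATRIX, default_event_models


@pytest.fixture(scope="session")
def small_trial():
    """An 800-per-arm trial under the default study conditions."""
    return hm.generate_trial(hm.GeneratorConfig(n_per_arm=800, seed=7))


@pytest.fixture(scope="session")
def fitted(small_trial):
    """Fitted Model/Results pair on the small trial (all six families)."""
    model = hm.HFCohortModel.from_trial(small_trial)
    return model.fit()


@pytest.fixture(scope="session")
def life_table():
    return hm.make_synthetic_life_table()


@pytest.fixture()
def base_spec():
    return ModelSpec()


@pytest.fixture(scope="session")
def true_inputs(life_table):
    """Engine inputs built from the generator's true parameters (no
    estimation noise): constant per-cycle mortality matching the default
    exponential hazards, the true event-rate models, and the default KCCQ
    matrix."""
    def cycle_p(rate_per_year):
        return CycleProbability(1.0 - np.exp(-rate_per_year * 28 / 365.25),
                                source_window_days=28.0)

    models = default_event_models()
    T = TransitionMatrix(DEFAULT_KCCQ_MATRIX)
    control = ArmInputs(transition=T,
                        event_models={e: m for (e, a), m in models.items() if a == "control"},
                        cv_mortality=cycle_p(0.027),
                        allcause_mortality=cycle_p(0.027 + 0.016))
    active = ArmInputs(transition=T,
                       event_models={e: m for (e, a), m in models.items() if a == "active"},
                       cv_mortality=cycle_p(0.023),
                       allcause_mortality=cycle_p(0.023 + 0.016))
    return ModelInputs(control=control, active=active,
                       discontinuation=None, life_table=life_table)


#: Observed on-treatment trial counts used for external-validation tests
#: (CV deaths / total HHF / total UHFV per arm, and arm sizes).
TRIAL_COUNTS = {
    "CV_deaths": {"active": 161, "control": 188, "incremental": -27},
    "HHF": {"active": 505, "control": 724, "incremental": -219},
    "UHFV": {"active": 68, "control": 129, "incremental": -61},
}
ARM_N = {"active": 3003, "control": 2998}


@pytest.fixture(scope="session")
def trial_counts():
    return TRIAL_COUNTS


@pytest.fixture(scope="session")
def arm_n():
    return ARM_N
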