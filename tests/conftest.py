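import dataclasses

import numpy as np
import pytest

from eposim import (
    ConstantDosePolicy,
    DoseEvent,
    ModelConstants,
    SessionConfig,
    hb_true,
    initial_state,
    patient_from_seed,
    run_session,
    step_day,
)


@pytest.fixture(scope="session")
def constants():
    return ModelConstants().validate()


@pytest.fixture(scope="session")
def quiet_constants(constants):
    """Noise-free variant for deterministic trajectory checks."""
    return dataclasses.replace(constants, noise_amplitude=0.0)


@pytest.fixture
def patient(constants):
    return patient_from_seed(1, constants)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


def simulate_constant_weekly(patient, constants, dose, half_life, n_days):
    """Drive the engine with a constant weekly dose; return (state, hb trace)."""
    state = initial_state(patient, constants, half_life)
    trace = []
    for day in range(n_days):
        doses = [DoseEvent(day=day, amount=dose)] if (day % 7 == 0 and dose > 0) else []
        step_day(state, doses, patient, constants)
        trace.append(hb_true(state, constants))
    return state, np.asarray(trace)


def quick_session(constants, half_life=24.0, interval="weekly", mode="B", seed=0,
                  patient_seed=1, policy=None):
    pat = patient_from_seed(patient_seed, constants)
    cfg = SessionConfig(half_life=half_life, interval=interval, mode=mode,
                        seed=seed, constants=constants)
    if policy is None:
        policy = ConstantDosePolicy(6000.0, monthly_scale=(interval == "monthly"))
    return run_session(cfg, pat, policy)
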