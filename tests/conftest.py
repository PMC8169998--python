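"""Shared fixtures: synthetic sessions are expensive, so build them once."""

import numpy as np
import pytest

from perturbwalk import (
    GaitModelParams,
    PerturbationResponseParams,
    PerturbationSchedule,
    compute_mos_series,
    generate_perturbation_session,
    generate_unperturbed_trial,
)


@pytest.fixture(scope="session")
def params():
    return GaitModelParams(seed=42)


@pytest.fixture(scope="session")
def noiseless_params(params):
    return params.noiseless()


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_params):
    """Steady 1.3 m/s walking, no stochastic components."""
    return generate_unperturbed_trial(noiseless_params, 1.3, 40.0)


@pytest.fixture(scope="session")
def noisy_trial(params):
    """Default-noise walking trial (1 mm markers, lognormal step params)."""
    return generate_unperturbed_trial(params, 1.3, 60.0)


@pytest.fixture(scope="session")
def noiseless_pert_session(noiseless_params):
    """Ten-perturbation protocol, noiseless, short 30-40 s gaps."""
    resp = PerturbationResponseParams(response_sd=0.0)
    sched = PerturbationSchedule.standard(seed=3, lead_in=40.0, gap_range=(31.5, 40.0))
    return generate_perturbation_session(noiseless_params, resp, sched)


@pytest.fixture(scope="session")
def noiseless_trial_mos(noiseless_trial):
    return compute_mos_series(
        noiseless_trial.markers, forces=noiseless_trial.forces.as_dict()
    )


@pytest.fixture(scope="session")
def pert_session_mos(noiseless_pert_session):
    s = noiseless_pert_session
    return compute_mos_series(s.markers, forces=s.forces.as_dict())
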