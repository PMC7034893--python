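"""Shared fixtures: a cohort-typical model and one full twin experiment.

The twin experiment (generate a synthetic patient, calibrate it end to end)
is the most expensive object in the suite, so it is computed once per
session and shared by the calibration and acceptance tests.
"""

import warnings

import pytest
from hypothesis import settings

settings.register_profile("repro", deadline=None, derandomize=True, database=None)
settings.load_profile("repro")

from fontan0d.circulation import VenousLawParams, WindkesselParams
from fontan0d.simulator import HeartCirculationModel, run_to_periodic
from fontan0d.synthetic import TruthSpec, twin_experiment
from fontan0d.ventricle import (
    ActivationTiming,
    ActiveLawParams,
    PassiveLawParams,
    reference_geometry,
)

MMHG = 133.322


def make_default_model(**active_kw) -> HeartCirculationModel:
    """Cohort-typical single-ventricle model (resting state)."""
    geom = reference_geometry(76e-6, 0.038, 0.5, 1050.0)
    wk = WindkesselParams.with_proximal_rc(Rp=0.19e8, Rd=1.25e8, Cd=2.00e-8)
    venous = VenousLawParams(
        Veff=20.0 * MMHG * (2.00e-8 + 3.70e-8),  # MSFP 20 mmHg
        Cve=3.70e-8,
        Patr_amp=2.4 * MMHG,
    )
    return HeartCirculationModel(
        geom=geom,
        passive=PassiveLawParams(stiffness_scale=1.1),
        active=ActiveLawParams(sigma0=28e3, **active_kw),
        timing=ActivationTiming(T0=60.0 / 70.0),
        wk=wk,
        venous=venous,
    )


@pytest.fixture(scope="session")
def default_model():
    return make_default_model()


@pytest.fixture(scope="session")
def rest_result(default_model):
    """Converged resting closed loop of the default model."""
    res = run_to_periodic(default_model, max_beats=60)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def twin():
    """One noiseless twin experiment on the default truth."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return twin_experiment(TruthSpec())


@pytest.fixture(scope="session")
def synthetic_record(twin):
    return twin["record"]
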