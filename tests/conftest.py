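"""Shared fixtures: the reference model and its (expensive) derived objects."""

from __future__ import annotations

import numpy as np
import pytest

from terpclock import (
    concentration_sensitivities,
    jacobian,
    reference_fixture,
    solve_steady_state,
)
from terpclock.circadian import LightSchedule, daily_amplitude, simulate
from terpclock.sensitivity import aggregate_flux_sensitivities

#: Published Model A steady-state concentrations (mM).
PUBLISHED_STEADY = {
    "HMGCoA_cyt": 0.983,
    "MVA_cyt": 3.5e-5,
    "MVP_cyt": 3.98e-4,
    "MVPP_cyt": 3.36e-5,
    "IPP_cyt": 0.109,
    "IPP_pl": 0.0801,
    "DMAPP_cyt": 0.136,
    "DMAPP_pl": 0.124,
    "DXP": 0.0133,
    "MEP": 1.15e-3,
    "CDPME": 1.11e-4,
    "CDPMEP": 0.0920,
    "MEcPP": 0.657,
    "HMBPP": 3.52e-4,
}

#: Published steady-state Jacobian eigenvalues (all real).
PUBLISHED_EIGENVALUES = [
    -928.693, -891.953, -872.862, -272.249, -83.721, -78.084, -16.974,
    -11.845, -6.668, -2.011, -0.913, -0.545, -0.110, -0.031,
]


@pytest.fixture(scope="session")
def ref():
    return reference_fixture()


@pytest.fixture(scope="session")
def params(ref):
    return ref.params


@pytest.fixture(scope="session")
def inputs(ref):
    return ref.inputs


@pytest.fixture(scope="session")
def steady(params, inputs):
    return solve_steady_state(params, inputs)


@pytest.fixture(scope="session")
def ref_jacobian(steady, params, inputs):
    return jacobian(steady, params, inputs)


@pytest.fixture(scope="session")
def conc_sens(params, inputs, steady):
    return concentration_sensitivities(params, inputs, steady=steady)


@pytest.fixture(scope="session")
def flux_sens(params, inputs, steady):
    return aggregate_flux_sensitivities(params, inputs, steady=steady)


@pytest.fixture(scope="session")
def circadian_amplitudes(params, inputs):
    """Day-10 amplitude summaries for the variant/dusk pairs the circadian
    analyses assert on; computed once per session."""
    from terpclock.circadian import exchange_knockout

    cases = {}

    def add(key, variant, dusk, p=None):
        traj = simulate(
            variant, p if p is not None else params, inputs,
            LightSchedule(dusk=dusk), n_days=10,
        )
        cases[key] = daily_amplitude(traj, 10)

    for dusk in (0.5, 3.0, 9.0, 12.0, 15.0, 21.0, 23.5):
        add(("E", dusk), "E", dusk)
    add(("B", 21.0), "B", 21.0)
    add(("C", 12.0), "C", 12.0)
    for dusk in (6.0, 12.0, 18.0):
        add(("D", dusk), "D", dusk)
    add(("E-ko", 12.0), "E", 12.0, p=exchange_knockout(params))
    return cases
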