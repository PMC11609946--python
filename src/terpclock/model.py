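"""Rate laws, circadian forcing and the ODE right-hand side.

The joint model tracks 14 dependent metabolites: the mevalonate (MVA)
pathway intermediates and cytosolic IPP/DMAPP, and the methylerythritol
4-phosphate (MEP) pathway intermediates and plastidic IPP/DMAPP.  Reaction
rates r1..r23 follow the saturating formalism

    v = V * s / (s + Km * (1 + sum_i x_i/Ki_i))

with apparent saturation (V), binding (Km) and inhibition (Ki) constants;
exchange steps (r8, r9, r22, r23) are first order and the lumped downstream
consumption steps (r20, r21) are bilinear in IPP and DMAPP.

Circadian forcing enters through a smooth light function L(t) in [0, 1]
(tanh dawn/dusk transitions) acting, depending on the regulatory wiring, on
substrate availability, on the pathway Vmax values (anti-phasic between MVA
and MEP) and on the IPP/DMAPP consumption constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import (
    MEP_VMAX,
    MVA_VMAX,
    IndependentInputs,
    ParameterSet,
)

__all__ = [
    "STATE_NAMES",
    "FLUX_NAMES",
    "N_STATES",
    "N_FLUXES",
    "STOICHIOMETRY",
    "LightSchedule",
    "RegulatoryWiring",
    "VARIANTS",
    "make_variant",
    "light_level",
    "modulated_parameters",
    "compute_fluxes",
    "flux_state_jacobian",
    "rhs",
]

STATE_NAMES: tuple[str, ...] = (
    "HMGCoA_cyt", "MVA_cyt", "MVP_cyt", "MVPP_cyt",
    "IPP_cyt", "IPP_pl", "DMAPP_cyt", "DMAPP_pl",
    "DXP", "MEP", "CDPME", "CDPMEP", "MEcPP", "HMBPP",
)
N_STATES = len(STATE_NAMES)

FLUX_NAMES: tuple[str, ...] = tuple(f"r{i}" for i in range(1, 24))
N_FLUXES = len(FLUX_NAMES)

# Net stoichiometric matrix (states x fluxes).  The lumped consumption steps
# drain 4 IPP + 2 DMAPP per r20 event (cytosol) and 3 IPP + 1 DMAPP per r21
# event (plastid).
STOICHIOMETRY = np.zeros((N_STATES, N_FLUXES))
_S = {n: i for i, n in enumerate(STATE_NAMES)}
_R = {n: i for i, n in enumerate(FLUX_NAMES)}


def _st(state: str, flux: str, coef: float) -> None:
    STOICHIOMETRY[_S[state], _R[flux]] = coef


_st("HMGCoA_cyt", "r1", 1); _st("HMGCoA_cyt", "r2", -1)
_st("MVA_cyt", "r2", 1); _st("MVA_cyt", "r3", -1)
_st("MVP_cyt", "r3", 1); _st("MVP_cyt", "r4", -1)
_st("MVPP_cyt", "r4", 1); _st("MVPP_cyt", "r5", -1)
_st("IPP_cyt", "r5", 1); _st("IPP_cyt", "r7", 1); _st("IPP_cyt", "r9", 1)
_st("IPP_cyt", "r6", -1); _st("IPP_cyt", "r8", -1); _st("IPP_cyt", "r20", -4)
_st("IPP_pl", "r8", 1); _st("IPP_pl", "r16", 1); _st("IPP_pl", "r19", 1)
_st("IPP_pl", "r9", -1); _st("IPP_pl", "r18", -1); _st("IPP_pl", "r21", -3)
_st("DMAPP_cyt", "r6", 1); _st("DMAPP_cyt", "r23", 1)
_st("DMAPP_cyt", "r7", -1); _st("DMAPP_cyt", "r20", -2); _st("DMAPP_cyt", "r22", -1)
_st("DMAPP_pl", "r17", 1); _st("DMAPP_pl", "r18", 1); _st("DMAPP_pl", "r22", 1)
_st("DMAPP_pl", "r19", -1); _st("DMAPP_pl", "r21", -1); _st("DMAPP_pl", "r23", -1)
_st("DXP", "r10", 1); _st("DXP", "r11", -1)
_st("MEP", "r11", 1); _st("MEP", "r12", -1)
_st("CDPME", "r12", 1); _st("CDPME", "r13", -1)
_st("CDPMEP", "r13", 1); _st("CDPMEP", "r14", -1)
_st("MEcPP", "r14", 1); _st("MEcPP", "r15", -1)
_st("HMBPP", "r15", 1); _st("HMBPP", "r16", -1); _st("HMBPP", "r17", -1)
STOICHIOMETRY.setflags(write=False)


@dataclass(frozen=True)
class LightSchedule:
    """Periodic day/night light schedule.

    ``dawn`` and ``dusk`` are the sunrise/sunset times within one period;
    ``dusk`` acts as a proxy for latitude and season (daylight hours per
    day).  ``T`` is the twilight steepness: small T approaches a square
    wave, larger T a sinusoid-like transition.
    """

    period: float = 24.0
    dawn: float = 0.0
    dusk: float = 12.0
    T: float = 1.0

    def __post_init__(self) -> None:
        if not (self.period > 0 and math.isfinite(self.period)):
            raise ValueError("period must be positive and finite")
        if not (0.0 <= self.dawn <= self.dusk <= self.period):
            raise ValueError(
                f"schedule requires 0 <= dawn <= dusk <= period, got "
                f"dawn={self.dawn}, dusk={self.dusk}, period={self.period}"
            )
        if not (self.T > 0):
            raise ValueError("twilight steepness T must be positive")


@dataclass(frozen=True)
class RegulatoryWiring:
    """Which circadian regulation modules are active.

    substrate    -- light scales substrate availability (acetoacetyl-CoA and
                    pyruvate follow L(t) around their homeostatic values)
    expression   -- anti-phasic gene expression: MVA-side Vmax scale with
                    1-L(t), MEP-side Vmax with L(t)
    consumption  -- downstream IPP/DMAPP usage (k1, k1p) scales with L(t)
    """

    substrate: bool = False
    expression: bool = False
    consumption: bool = False

    @property
    def any_active(self) -> bool:
        return self.substrate or self.expression or self.consumption


VARIANTS: dict[str, RegulatoryWiring] = {
    "A": RegulatoryWiring(False, False, False),
    "B": RegulatoryWiring(True, False, False),
    "C": RegulatoryWiring(False, True, False),
    "D": RegulatoryWiring(False, False, True),
    "BC": RegulatoryWiring(True, True, False),
    "BD": RegulatoryWiring(True, False, True),
    "CD": RegulatoryWiring(False, True, True),
    "E": RegulatoryWiring(True, True, True),
}


def make_variant(name: str) -> RegulatoryWiring:
    """Regulatory wiring for a named model variant (A, B, C, D, BC, BD, CD, E)."""
    try:
        return VARIANTS[name.upper()]
    except KeyError:
        raise ValueError(
            f"unknown model variant {name!r}; valid names: {', '.join(VARIANTS)}"
        ) from None


def light_level(t, schedule: LightSchedule = LightSchedule()):
    """Light intensity L(t) in [0, 1].

    Smooth periodic day/night profile: a rising tanh front at dawn, a
    falling one at dusk, and a rising front at the period boundary so the
    profile wraps continuously.  Accepts scalars or arrays.  The time
    argument is wrapped into [0, period) before evaluation, which is
    mathematically identical to the Floor-based form and avoids
    large-argument overflow.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("light_level requires finite time values")
    tau = t - schedule.period * np.floor(t / schedule.period)
    T = schedule.T
    val = 0.5 * (
        (1 + np.tanh((tau - schedule.dawn) / T))
        - (1 + np.tanh((tau - schedule.dusk) / T))
        + (1 + np.tanh((tau - schedule.period) / T))
    )
    return float(val) if val.ndim == 0 else val


def modulated_parameters(
    t: float,
    params: ParameterSet,
    inputs: IndependentInputs,
    schedule: LightSchedule,
    wiring: RegulatoryWiring,
) -> tuple[ParameterSet, IndependentInputs]:
    """Apply the active circadian regulation modules at time ``t``.

    Returns the effective parameter set and inputs; Km and Ki constants are
    never modulated.  With no module active the basal objects are returned
    unchanged (Model A).
    """
    if not wiring.any_active:
        return params, inputs
    L = light_level(t, schedule)
    if wiring.substrate:
        inputs = inputs.replace(
            acetoacetylCoA=L * inputs.acCoA_H,
            pyruvate=L * inputs.pyruvate_H,
        )
    changes: dict[str, float] = {}
    if wiring.expression:
        for name in MVA_VMAX:
            changes[name] = (1.0 - L) * getattr(params, name)
        for name in MEP_VMAX:
            changes[name] = L * getattr(params, name)
    if wiring.consumption:
        changes["k1"] = L * params.k1
        changes["k1p"] = L * params.k1p
    if changes:
        params = params.replace(**changes)
    return params, inputs


def _sat(V, s, Km, inhib=0.0):
    """Saturating rate V*s/(s + Km*(1+inhib))."""
    return V * s / (s + Km * (1.0 + inhib))


def compute_fluxes(
    state: np.ndarray, params: ParameterSet, inputs: IndependentInputs
) -> np.ndarray:
    """The 23 reaction rates r1..r23 at a given state (mM/h).

    The DXP synthase step (r10) saturates in G3P with product inhibition by
    plastidic IPP/DMAPP, carrying a normalized pyruvate factor
    (pyruvate/pyruvate_H, equal to 1 at basal conditions) through which the
    circadian substrate wiring acts.  The mevalonate kinase step (r3)
    carries the constant downstream inhibition load ``theta`` in addition to
    MVP feedback.  Enzyme-activity symbols are dimensionless and absorbed
    into the Vmax values.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (N_STATES,):
        raise ValueError(f"state must have shape ({N_STATES},), got {x.shape}")
    if np.any(x < 0):
        raise ValueError("negative concentration in state")
    (HMG, MVA, MVP, MVPP, IPPc, IPPpl, DMAPPc, DMAPPpl,
     DXP, MEP, CDPME, CDPMEP, MEcPP, HMBPP) = x
    p = params
    r = np.empty(N_FLUXES)
    r[_R["r1"]] = _sat(p.Vmax1, inputs.acetoacetylCoA, p.Km1, HMG / p.Ki1)
    r[_R["r2"]] = _sat(p.Vmax2, HMG, p.Km2, MVA / p.Ki2)
    r[_R["r3"]] = _sat(p.Vmax3, MVA, p.Km3, MVP / p.Ki31 + inputs.theta)
    r[_R["r4"]] = _sat(p.Vmax4, MVP, p.Km4, MVPP / p.Ki4)
    r[_R["r5"]] = _sat(p.Vmax5, MVPP, p.Km5)
    r[_R["r6"]] = _sat(p.Vmax6, IPPc, p.Km6, DMAPPc / p.Ki6)
    r[_R["r7"]] = _sat(p.Vmax7, DMAPPc, p.Km7)
    r[_R["r8"]] = p.k2 * IPPc
    r[_R["r9"]] = p.k3 * IPPpl
    r[_R["r10"]] = (inputs.pyruvate / inputs.pyruvate_H) * _sat(
        p.Vmax8, inputs.G3P, p.Km8, IPPpl / p.Ki81 + DMAPPpl / p.Ki82
    )
    r[_R["r11"]] = _sat(p.Vmax9, DXP, p.Km9)
    r[_R["r12"]] = _sat(p.Vmax10, MEP, p.Km10)
    r[_R["r13"]] = _sat(p.Vmax11, CDPME, p.Km11)
    r[_R["r14"]] = _sat(p.Vmax12, CDPMEP, p.Km12)
    r[_R["r15"]] = _sat(p.Vmax13, MEcPP, p.Km13)
    r[_R["r16"]] = _sat(p.Vmax14, HMBPP, p.Km14)
    r[_R["r17"]] = _sat(p.Vmax14p, HMBPP, p.Km14p)
    r[_R["r18"]] = _sat(p.Vmax6pl, IPPpl, p.Km6pl, DMAPPpl / p.Ki6pl)
    r[_R["r19"]] = _sat(p.Vmax7pl, DMAPPpl, p.Km7pl)
    r[_R["r20"]] = p.k1 * IPPc * DMAPPc
    r[_R["r21"]] = p.k1p * IPPpl * DMAPPpl
    r[_R["r22"]] = p.k2p * DMAPPc
    r[_R["r23"]] = p.k3p * DMAPPpl
    return r


def _dsat(V, s, Km, inhib=0.0):
    """(dv/ds, dv/d(inhib-sum)) for the saturating rate law."""
    Keff = Km * (1.0 + inhib)
    den = (s + Keff) ** 2
    return V * Keff / den, -V * s * Km / den


def flux_state_jacobian(
    state: np.ndarray, params: ParameterSet, inputs: IndependentInputs
) -> np.ndarray:
    """Analytic partial derivatives dr_i/dx_j (23 x 14)."""
    x = np.asarray(state, dtype=float)
    (HMG, MVA, MVP, MVPP, IPPc, IPPpl, DMAPPc, DMAPPpl,
     DXP, MEP, CDPME, CDPMEP, MEcPP, HMBPP) = x
    p = params
    D = np.zeros((N_FLUXES, N_STATES))

    def put(flux, sub, V, s, Km, inhibs=()):
        """inhibs: sequence of (state_name, Ki)."""
        load = sum(x[_S[n]] / Ki for n, Ki in inhibs)
        ds, dinh = _dsat(V, s, Km, load)
        if sub is not None:
            D[_R[flux], _S[sub]] += ds
        for n, Ki in inhibs:
            D[_R[flux], _S[n]] += dinh / Ki

    # r1: substrate is fixed acetoacetyl-CoA; only HMG feedback varies
    load1 = HMG / p.Ki1
    _, dinh1 = _dsat(p.Vmax1, inputs.acetoacetylCoA, p.Km1, load1)
    D[_R["r1"], _S["HMGCoA_cyt"]] = dinh1 / p.Ki1
    put("r2", "HMGCoA_cyt", p.Vmax2, HMG, p.Km2, [("MVA_cyt", p.Ki2)])
    # r3 carries the constant theta load in addition to MVP feedback
    load3 = MVP / p.Ki31 + inputs.theta
    ds3, dinh3 = _dsat(p.Vmax3, MVA, p.Km3, load3)
    D[_R["r3"], _S["MVA_cyt"]] = ds3
    D[_R["r3"], _S["MVP_cyt"]] = dinh3 / p.Ki31
    put("r4", "MVP_cyt", p.Vmax4, MVP, p.Km4, [("MVPP_cyt", p.Ki4)])
    put("r5", "MVPP_cyt", p.Vmax5, MVPP, p.Km5)
    put("r6", "IPP_cyt", p.Vmax6, IPPc, p.Km6, [("DMAPP_cyt", p.Ki6)])
    put("r7", "DMAPP_cyt", p.Vmax7, DMAPPc, p.Km7)
    D[_R["r8"], _S["IPP_cyt"]] = p.k2
    D[_R["r9"], _S["IPP_pl"]] = p.k3
    # r10: substrate is fixed G3P; IPP_pl/DMAPP_pl feedback varies
    load10 = IPPpl / p.Ki81 + DMAPPpl / p.Ki82
    pyr_fac = inputs.pyruvate / inputs.pyruvate_H
    _, dinh10 = _dsat(pyr_fac * p.Vmax8, inputs.G3P, p.Km8, load10)
    D[_R["r10"], _S["IPP_pl"]] = dinh10 / p.Ki81
    D[_R["r10"], _S["DMAPP_pl"]] = dinh10 / p.Ki82
    put("r11", "DXP", p.Vmax9, DXP, p.Km9)
    put("r12", "MEP", p.Vmax10, MEP, p.Km10)
    put("r13", "CDPME", p.Vmax11, CDPME, p.Km11)
    put("r14", "CDPMEP", p.Vmax12, CDPMEP, p.Km12)
    put("r15", "MEcPP", p.Vmax13, MEcPP, p.Km13)
    put("r16", "HMBPP", p.Vmax14, HMBPP, p.Km14)
    put("r17", "HMBPP", p.Vmax14p, HMBPP, p.Km14p)
    put("r18", "IPP_pl", p.Vmax6pl, IPPpl, p.Km6pl, [("DMAPP_pl", p.Ki6pl)])
    put("r19", "DMAPP_pl", p.Vmax7pl, DMAPPpl, p.Km7pl)
    D[_R["r20"], _S["IPP_cyt"]] = p.k1 * DMAPPc
    D[_R["r20"], _S["DMAPP_cyt"]] = p.k1 * IPPc
    D[_R["r21"], _S["IPP_pl"]] = p.k1p * DMAPPpl
    D[_R["r21"], _S["DMAPP_pl"]] = p.k1p * IPPpl
    D[_R["r22"], _S["DMAPP_cyt"]] = p.k2p
    D[_R["r23"], _S["DMAPP_pl"]] = p.k3p
    return D


def rhs(
    t: float,
    state: np.ndarray,
    params: ParameterSet,
    inputs: IndependentInputs,
    schedule: LightSchedule = LightSchedule(),
    wiring: RegulatoryWiring = VARIANTS["A"],
) -> np.ndarray:
    """Time derivative of the 14 metabolite concentrations (mM/h)."""
    p_eff, inp_eff = modulated_parameters(t, params, inputs, schedule, wiring)
    # integrators may probe slightly negative values; rates are evaluated at
    # the clipped state, which preserves non-negativity of trajectories
    x = np.maximum(np.asarray(state, dtype=float), 0.0)
    return STOICHIOMETRY @ compute_fluxes(x, p_eff, inp_eff)
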