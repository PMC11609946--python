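"""Steady state, Jacobian, eigenvalues, and consumption-constant calibration.

The autonomous (constant-light-free) model has a unique positive steady
state in the physiological regime.  It is found by integrating the stiff
ODEs from a positive initial guess until the dynamics are slow, then
polishing with a damped Newton iteration on the algebraic system rhs(x)=0.
Stability is assessed from the eigenvalues of the analytic Jacobian.

The lumped IPP/DMAPP consumption constants (k1, k1p) are under-determined
by the published kinetics; ``calibrate_consumption`` fixes them by least
squares against the published steady-state IPP/DMAPP pools and reports the
irreducible balance residual rather than hiding it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import eig

from .model import (
    N_STATES,
    STATE_NAMES,
    STOICHIOMETRY,
    compute_fluxes,
    flux_state_jacobian,
)
from .params import IndependentInputs, ParameterSet

__all__ = [
    "EigenReport",
    "SteadyStateError",
    "newton_solve",
    "solve_steady_state",
    "jacobian",
    "eigen_report",
    "calibrate_consumption",
    "chain_oracle",
    "PUBLISHED_POOLS",
]


class SteadyStateError(RuntimeError):
    """Raised when the steady-state solver fails to converge."""


#: Published steady-state IPP/DMAPP pools (mM) used as calibration inputs.
PUBLISHED_POOLS: dict[str, float] = {
    "IPP_cyt": 0.109,
    "IPP_pl": 0.0801,
    "DMAPP_cyt": 0.136,
    "DMAPP_pl": 0.124,
}

#: Remaining published steady-state concentrations (mM), used to assemble
#: the full published state for calibration residual evaluation.
PUBLISHED_STATE_OTHER: dict[str, float] = {
    "HMGCoA_cyt": 0.983, "MVA_cyt": 3.5e-5, "MVP_cyt": 3.98e-4,
    "MVPP_cyt": 3.36e-5, "DXP": 0.0133, "MEP": 1.15e-3, "CDPME": 1.11e-4,
    "CDPMEP": 0.0920, "MEcPP": 0.657, "HMBPP": 3.52e-4,
}


def _rhs(x, params, inputs):
    return STOICHIOMETRY @ compute_fluxes(np.maximum(x, 0.0), params, inputs)


def jacobian(
    state: np.ndarray, params: ParameterSet, inputs: IndependentInputs
) -> np.ndarray:
    """Analytic Jacobian d(rhs_i)/d(x_j) of the autonomous system (14 x 14)."""
    return STOICHIOMETRY @ flux_state_jacobian(state, params, inputs)


def newton_solve(
    f,
    jac,
    x0: np.ndarray,
    tol: float = 1e-13,
    max_iter: int = 60,
    require_nonnegative: bool = True,
) -> np.ndarray:
    """Damped Newton iteration on f(x)=0 with 0.5-factor backtracking.

    Generic over the residual and Jacobian callables so the same machinery
    drives both the full 14-species model and the closed-form toy chains
    used as oracles.  Raises :class:`SteadyStateError` if the iteration
    stalls, diverges, or (when required) leaves the non-negative orthant.
    """
    x = np.asarray(x0, dtype=float).copy()
    fx = f(x)
    norm = np.max(np.abs(fx))
    for _ in range(max_iter):
        if norm < tol:
            break
        J = jac(x)
        try:
            step = np.linalg.solve(J, -fx)
        except np.linalg.LinAlgError as exc:
            raise SteadyStateError(f"singular Jacobian during Newton: {exc}") from exc
        lam = 1.0
        while lam > 1e-8:
            x_new = x + lam * step
            if not require_nonnegative or np.all(x_new >= 0):
                f_new = f(x_new)
                if np.max(np.abs(f_new)) < norm:
                    break
            lam *= 0.5
        else:
            raise SteadyStateError(
                f"Newton backtracking stalled at residual {norm:.3e}"
            )
        x, fx = x_new, f_new
        norm = np.max(np.abs(fx))
    else:
        raise SteadyStateError(
            f"Newton did not converge in {max_iter} iterations "
            f"(residual {norm:.3e})"
        )
    return x


def solve_steady_state(
    params: ParameterSet,
    inputs: IndependentInputs,
    x0: np.ndarray | None = None,
    t_integrate: float = 2000.0,
    newton_tol: float = 1e-13,
    max_newton: int = 60,
) -> np.ndarray:
    """Positive steady state of the autonomous (Model A) system.

    Tries a damped Newton iteration directly from ``x0`` when one is
    supplied; otherwise (or if direct Newton fails) integrates the stiff
    ODEs from a positive guess (1e-3 mM for every species) until the
    dynamics are slow and then polishes with Newton.  Raises
    :class:`SteadyStateError` with the residual norm on failure.
    """
    f = lambda y: _rhs(y, params, inputs)
    jac_ = lambda y: jacobian(y, params, inputs)
    if x0 is not None:
        try:
            return newton_solve(f, jac_, x0, tol=newton_tol, max_iter=max_newton)
        except SteadyStateError:
            pass  # fall back to relaxation from the default guess
    x = np.full(N_STATES, 1e-3)
    sol = solve_ivp(
        lambda t, y: f(y),
        (0.0, t_integrate), x, method="LSODA", rtol=1e-10, atol=1e-14,
    )
    if not sol.success:
        raise SteadyStateError(f"relaxation integration failed: {sol.message}")
    x = np.maximum(sol.y[:, -1], 0.0)
    x = newton_solve(f, jac_, x, tol=newton_tol, max_iter=max_newton)
    if np.any(x < 0):
        raise SteadyStateError("steady state left the non-negative orthant")
    return x


@dataclass(frozen=True)
class EigenReport:
    """Eigenvalues of the steady-state Jacobian with a stability verdict."""

    eigenvalues: np.ndarray  # complex, in eigensolver order
    stable: bool
    dominant_timescale: float  # 1/|slowest decaying mode|, hours

    @property
    def real_parts_sorted(self) -> np.ndarray:
        """Real parts, fastest (most negative) first."""
        return np.sort(self.eigenvalues.real)


def eigen_report(J: np.ndarray) -> EigenReport:
    """Eigen-decomposition and linear stability of a Jacobian."""
    J = np.asarray(J, dtype=float)
    if J.shape != (N_STATES, N_STATES):
        raise ValueError(f"expected a {N_STATES}x{N_STATES} Jacobian, got {J.shape}")
    ev = eig(J, right=False)
    max_re = float(np.max(ev.real))
    stable = max_re < 0.0
    negatives = ev.real[ev.real < 0]
    dom = float(1.0 / np.abs(negatives.max())) if negatives.size else np.inf
    return EigenReport(eigenvalues=ev, stable=stable, dominant_timescale=dom)


@dataclass(frozen=True)
class CalibrationResult:
    k1: float
    k1p: float
    residuals: dict[str, float]  # pool-balance residuals at the target pools, mM/h
    residual_norm: float
    clipped: bool


def calibrate_consumption(
    params: ParameterSet,
    inputs: IndependentInputs,
    target_pools: dict[str, float] | None = None,
    clip_floor: float = 1e-6,
) -> CalibrationResult:
    """Least-squares k1, k1p from the IPP/DMAPP balances at target pools.

    The four IPP/DMAPP steady-state balance residuals, evaluated at the
    published pools with the remaining metabolites at their published
    values, are linear in k1 (cytosolic rows) and k1p (plastidic rows), so
    the problem decouples into two scalar least-squares fits.  A negative
    optimum (which occurs when the DMAPP exchange constants are at their
    published values -- the published pools then cannot balance) is clipped
    to ``clip_floor`` with a warning.  The residuals at the optimum are
    returned so irreducible inconsistency stays visible.
    """
    pools = dict(PUBLISHED_POOLS if target_pools is None else target_pools)
    state = np.array(
        [
            pools.get(n, PUBLISHED_STATE_OTHER.get(n))
            for n in STATE_NAMES
        ],
        dtype=float,
    )
    rows = {n: STATE_NAMES.index(n) for n in PUBLISHED_POOLS}

    f0 = _rhs(state, params.replace(k1=0.0, k1p=0.0), inputs)
    f1 = _rhs(state, params.replace(k1=1.0, k1p=1.0), inputs)
    slope = f0 - f1  # residual decrease per unit k

    def fit(row_names):
        idx = [rows[n] for n in row_names]
        a = f0[idx]
        b = slope[idx]
        return float(a @ b / (b @ b))

    k1 = fit(["IPP_cyt", "DMAPP_cyt"])
    k1p = fit(["IPP_pl", "DMAPP_pl"])
    clipped = False
    if k1 <= 0 or k1p <= 0:
        warnings.warn(
            "calibrated consumption constant non-positive "
            f"(k1={k1:.4g}, k1p={k1p:.4g}); clipping -- the target pools "
            "cannot balance under the current exchange constants",
            stacklevel=2,
        )
        k1 = max(k1, clip_floor)
        k1p = max(k1p, clip_floor)
        clipped = True

    res = _rhs(state, params.replace(k1=k1, k1p=k1p), inputs)
    residuals = {n: float(res[rows[n]]) for n in PUBLISHED_POOLS}
    return CalibrationResult(
        k1=k1,
        k1p=k1p,
        residuals=residuals,
        residual_norm=float(np.linalg.norm(list(residuals.values()))),
        clipped=clipped,
    )


def chain_oracle(
    flux: float,
    steps: list[tuple[float, float]] | list[tuple[float, float, float]],
) -> np.ndarray:
    """Closed-form steady state of an unbranched saturating chain.

    Each step is ``(Vmax, Km)`` or ``(Vmax, Km, inhibition_load)`` where the
    load is the constant sum of x/Ki inhibition terms entering that step's
    effective binding constant.  At steady state every step carries ``flux``
    and its substrate concentration inverts the saturating rate law:

        X = Keff * f / (1 - f),   f = flux / Vmax,  Keff = Km * (1 + load).

    Rejects flux >= any step's Vmax (no finite steady state).  Used as an
    independent oracle for the full Newton solver on unbranched pathway
    segments.
    """
    if flux < 0:
        raise ValueError("flux must be non-negative")
    out = np.empty(len(steps))
    for i, step in enumerate(steps):
        V, Km, *rest = step
        load = rest[0] if rest else 0.0
        if flux >= V:
            raise ValueError(
                f"flux {flux} >= Vmax {V} at step {i}: no finite steady state"
            )
        f = flux / V
        out[i] = Km * (1.0 + load) * f / (1.0 - f)
    return out
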