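"""Logarithmic (metabolic-control) sensitivity analyses.

Three local sensitivity analyses around the Model A steady state:

* steady-state concentration sensitivities S(X, p) = dlogX/dlogp, by
  implicit differentiation of rhs(x(p), p) = 0 (dx/dp = -J^-1 df/dp);
* aggregate input/output flux sensitivities: for each metabolite the
  stoichiometry-weighted sum of its producing (or consuming) reaction
  rates, differentiated with respect to each parameter with all
  concentrations held fixed at the steady state;
* eigenvalue sensitivities dlog(lambda)/dlogp, by central differences on
  re-solved steady states with eigenvalue matching by eigenvector overlap.

A sensitivity with respect to a parameter whose value is exactly zero is
zero by the logarithmic convention S = (p/X) dX/dp.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import FLUX_NAMES, N_STATES, STATE_NAMES, STOICHIOMETRY, compute_fluxes
from .params import PARAM_NAMES, IndependentInputs, ParameterSet
from .steady_state import _rhs, eigen_report, jacobian, solve_steady_state

__all__ = [
    "concentration_sensitivities",
    "aggregate_flux_sensitivities",
    "eigenvalue_sensitivities",
    "summarize_threshold",
]


def _dfdp(x, params, inputs, name, rel_step=1e-6):
    """Central-difference d(rhs)/d(param) at fixed state."""
    p0 = getattr(params, name)
    h = rel_step * p0
    fp = _rhs(x, params.replace(**{name: p0 + h}), inputs)
    fm = _rhs(x, params.replace(**{name: p0 - h}), inputs)
    return (fp - fm) / (2 * h)


def concentration_sensitivities(
    params: ParameterSet,
    inputs: IndependentInputs,
    steady: np.ndarray | None = None,
) -> pd.DataFrame:
    """All 14 x 52 logarithmic steady-state concentration sensitivities.

    Rows: (target, parameter, sensitivity), kind tag ``concentration``.
    Raises if the Jacobian is singular (non-hyperbolic steady state).
    """
    x = solve_steady_state(params, inputs) if steady is None else steady
    J = jacobian(x, params, inputs)
    # one LU factorization reused for all 52 parameter directions
    import scipy.linalg as sla

    lu = sla.lu_factor(J)
    rows = []
    for name in PARAM_NAMES:
        p0 = getattr(params, name)
        if p0 == 0.0:
            sens = np.zeros(N_STATES)
        else:
            dxdp = sla.lu_solve(lu, -_dfdp(x, params, inputs, name))
            sens = dxdp * p0 / x
        for i, target in enumerate(STATE_NAMES):
            rows.append((target, name, sens[i]))
    df = pd.DataFrame(rows, columns=["target", "parameter", "sensitivity"])
    df["kind"] = "concentration"
    return df


def _aggregate_fluxes(x, params, inputs):
    """Stoichiometry-weighted production and consumption sums per metabolite."""
    r = compute_fluxes(x, params, inputs)
    pos = np.where(STOICHIOMETRY > 0, STOICHIOMETRY, 0.0) @ r
    neg = np.where(STOICHIOMETRY < 0, -STOICHIOMETRY, 0.0) @ r
    return pos, neg


def aggregate_flux_sensitivities(
    params: ParameterSet,
    inputs: IndependentInputs,
    steady: np.ndarray | None = None,
    rel_step: float = 1e-6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Logarithmic sensitivities of aggregate input and output fluxes.

    Partial derivatives of the flux sums with concentrations held fixed at
    the steady state.  A metabolite whose aggregate flux is zero gets NaN
    rows (undefined log-derivative) rather than being dropped.
    """
    x = solve_steady_state(params, inputs) if steady is None else steady
    pos0, neg0 = _aggregate_fluxes(x, params, inputs)
    tables: dict[str, list] = {"positive_flux": [], "negative_flux": []}
    for name in PARAM_NAMES:
        p0 = getattr(params, name)
        if p0 == 0.0:
            spos = np.zeros(N_STATES)
            sneg = np.zeros(N_STATES)
        else:
            h = rel_step * p0
            pp, np_ = _aggregate_fluxes(x, params.replace(**{name: p0 + h}), inputs)
            pm, nm = _aggregate_fluxes(x, params.replace(**{name: p0 - h}), inputs)
            dlogp = np.log(p0 + h) - np.log(p0 - h)
            with np.errstate(divide="ignore", invalid="ignore"):
                spos = (np.log(pp) - np.log(pm)) / dlogp
                sneg = (np.log(np_) - np.log(nm)) / dlogp
            spos[pos0 == 0.0] = np.nan
            sneg[neg0 == 0.0] = np.nan
        for i, target in enumerate(STATE_NAMES):
            tables["positive_flux"].append((target, name, spos[i]))
            tables["negative_flux"].append((target, name, sneg[i]))
    out = []
    for kind in ("positive_flux", "negative_flux"):
        df = pd.DataFrame(tables[kind], columns=["target", "parameter", "sensitivity"])
        df["kind"] = kind
        out.append(df)
    return out[0], out[1]


def eigenvalue_sensitivities(
    params: ParameterSet,
    inputs: IndependentInputs,
    rel_step: float = 1e-5,
    parameters: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """dlog(lambda)/dlogp by central differences with eigenvector matching.

    For each parameter the steady state is re-solved at p*(1 +/- step), the
    perturbed eigenvalues are matched to the reference ones by maximal
    eigenvector overlap, and the logarithmic derivative is formed.  Rows
    where the matching is ambiguous (duplicate assignment, a symptom of an
    eigenvalue crossing within the step) are flagged unreliable.
    """
    import scipy.linalg as sla

    names = PARAM_NAMES if parameters is None else tuple(parameters)
    x0 = solve_steady_state(params, inputs)
    J0 = jacobian(x0, params, inputs)
    w0, v0 = sla.eig(J0)
    order = np.argsort(w0.real)
    w0, v0 = w0[order], v0[:, order]

    def matched_eigs(p):
        x = solve_steady_state(p, inputs, x0=x0)
        w, v = sla.eig(jacobian(x, p, inputs))
        overlap = np.abs(v0.conj().T @ v)  # rows: reference, cols: perturbed
        assign = overlap.argmax(axis=1)
        ok = len(set(assign.tolist())) == len(assign)
        return w[assign], ok

    rows = []
    for name in names:
        p0 = getattr(params, name)
        if p0 == 0.0:
            for i in range(N_STATES):
                rows.append((f"EV{i + 1}", name, 0.0, True))
            continue
        wp, okp = matched_eigs(params.replace(**{name: p0 * (1 + rel_step)}))
        wm, okm = matched_eigs(params.replace(**{name: p0 * (1 - rel_step)}))
        dlogp = np.log1p(rel_step) - np.log1p(-rel_step)
        sens = (wp.real - wm.real) / (w0.real * dlogp)
        reliable = okp and okm
        for i in range(N_STATES):
            rows.append((f"EV{i + 1}", name, float(sens[i]), reliable))
    df = pd.DataFrame(rows, columns=["target", "parameter", "sensitivity", "reliable"])
    df["kind"] = "eigenvalue"
    return df


def summarize_threshold(
    table: pd.DataFrame, threshold: float
) -> tuple[int, int, float]:
    """(count with |S| > threshold, total rows, max |S|) for a sensitivity table."""
    s = table["sensitivity"].to_numpy(dtype=float)
    finite = np.isfinite(s)
    count = int(np.sum(np.abs(s[finite]) > threshold))
    max_abs = float(np.max(np.abs(s[finite]))) if finite.any() else np.nan
    return count, len(table), max_abs
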