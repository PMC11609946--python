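"""Reference parameterization, randomized perturbations, and toy oracles.

Everything the analyses and tests consume is generated here: the reference
(Model A) parameter set with per-value provenance, log-normally perturbed
parameter ensembles for robustness studies, and unbranched saturating toy
chains whose steady states, Jacobians, eigenvalues and logarithmic
sensitivities all have closed forms (used as independent ground truth for
the numerical machinery).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (
    PARAM_NAMES,
    IndependentInputs,
    ParameterSet,
    reference_inputs,
    reference_parameters,
)

__all__ = [
    "FixtureBundle",
    "reference_fixture",
    "perturbed_parameters",
    "ToyChain",
    "toy_chain_model",
    "DEFAULT_ENSEMBLE",
]

#: Default robustness-ensemble conditions: 100 parameter sets with 10%
#: log-normal spread, fixed seed.
DEFAULT_ENSEMBLE = dict(n=100, sigma=0.1, seed=20241114)


@dataclass(frozen=True)
class FixtureBundle:
    """A parameterization plus per-value provenance notes."""

    params: ParameterSet
    inputs: IndependentInputs
    provenance: dict[str, str]
    seed: int | None = None


def reference_fixture(recalibrate: bool = True) -> FixtureBundle:
    """The reference (Model A) parameterization.

    Published kinetic constants are taken verbatim; the consumption
    constants k1 and k1p are recomputed from the published IPP/DMAPP pools
    by :func:`terpclock.steady_state.calibrate_consumption` (pass
    ``recalibrate=False`` to use the stored values, which are the same
    numbers frozen at package-build time).
    """
    params = reference_parameters()
    inputs = reference_inputs()
    if recalibrate:
        from .steady_state import calibrate_consumption

        cal = calibrate_consumption(params, inputs)
        params = params.replace(k1=cal.k1, k1p=cal.k1p)
    provenance = {name: "printed" for name in PARAM_NAMES}
    for name in ("Vmax14p", "Km14p", "Vmax6pl", "Km6pl", "Ki6pl", "Vmax7pl", "Km7pl"):
        provenance[name] = "derived"  # copies of printed cytosolic/IPP-branch values
    provenance["k1"] = provenance["k1p"] = "calibrated"
    provenance["k2p"] = provenance["k3p"] = "derived"  # zero; see docs/methods.md
    provenance["acetoacetylCoA"] = "derived"  # printed Ac-CoA value
    provenance["theta"] = "derived"  # from the MVK-dominated eigenvalue
    for name in ("G3P", "pyruvate", "acCoA_H", "pyruvate_H"):
        provenance[name] = "printed"
    return FixtureBundle(params=params, inputs=inputs, provenance=provenance)


def perturbed_parameters(
    n: int, sigma: float, seed: int, base: ParameterSet | None = None
) -> list[ParameterSet]:
    """``n`` independent log-normal perturbations of the reference set.

    Each of the 52 parameters is multiplied by exp(N(0, sigma^2));
    parameters that are exactly zero stay zero.  Reproducible for a fixed
    seed; all factors are drawn in one block so the result does not depend
    on iteration order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= sigma <= 1.0):
        raise ValueError("sigma must lie in [0, 1]")
    params = reference_parameters() if base is None else base
    rng = np.random.default_rng(seed)
    factors = np.exp(sigma * rng.standard_normal((n, len(PARAM_NAMES))))
    base_vals = np.array([getattr(params, k) for k in PARAM_NAMES])
    out = []
    for i in range(n):
        vals = base_vals * factors[i]
        out.append(ParameterSet.from_dict(dict(zip(PARAM_NAMES, vals))))
    return out


@dataclass(frozen=True)
class ToyChain:
    """Unbranched saturating chain with constant influx and closed forms.

    ``d x_i / dt = v_{i-1}(x_{i-1}) - v_i(x_i)`` with ``v_0 = flux``
    (constant) and ``v_i = V_i x_i / (x_i + K_i)``.  At steady state each
    step carries ``flux``, so every quantity of interest has a closed form:

    * steady state        X_i = K_i f_i / (1 - f_i),  f_i = flux / V_i
    * Jacobian            lower bidiagonal with diagonal -v_i'(X_i)
    * eigenvalues         the diagonal entries  -V_i K_i / (X_i + K_i)^2
    * S(X_i, V_i) = -1/(1-f_i);  S(X_i, K_i) = 1;  S(X_i, flux) = 1/(1-f_i);
      all cross sensitivities vanish.
    """

    Vmax: np.ndarray
    Km: np.ndarray
    flux: float

    @property
    def n_steps(self) -> int:
        return len(self.Vmax)

    @property
    def f(self) -> np.ndarray:
        return self.flux / self.Vmax

    def rhs(self, x: np.ndarray) -> np.ndarray:
        v = self.Vmax * x / (x + self.Km)
        upstream = np.concatenate(([self.flux], v[:-1]))
        return upstream - v

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        slope = self.Vmax * self.Km / (x + self.Km) ** 2
        J = np.diag(-slope)
        for i in range(1, self.n_steps):
            J[i, i - 1] = slope[i - 1]
        return J

    def steady_state(self) -> np.ndarray:
        return self.Km * self.f / (1.0 - self.f)

    def eigenvalues(self) -> np.ndarray:
        X = self.steady_state()
        return -self.Vmax * self.Km / (X + self.Km) ** 2

    def concentration_sensitivity(self, i: int, which: str) -> float:
        """dlog(X_i)/dlog(p) for p in {'Vmax', 'Km', 'flux'} of step i."""
        fi = self.f[i]
        if which == "Vmax":
            return -1.0 / (1.0 - fi)
        if which == "Km":
            return 1.0
        if which == "flux":
            return 1.0 / (1.0 - fi)
        raise ValueError(f"unknown parameter kind {which!r}")


def toy_chain_model(
    n_steps: int,
    Vmax: list[float] | np.ndarray,
    Km: list[float] | np.ndarray,
    flux: float,
) -> ToyChain:
    """Build a toy chain, validating that a finite steady state exists."""
    Vmax = np.asarray(Vmax, dtype=float)
    Km = np.asarray(Km, dtype=float)
    if len(Vmax) != n_steps or len(Km) != n_steps:
        raise ValueError("Vmax and Km must each have n_steps entries")
    if np.any(Vmax <= 0) or np.any(Km <= 0):
        raise ValueError("Vmax and Km must be positive")
    if flux < 0:
        raise ValueError("flux must be non-negative")
    if np.any(flux >= Vmax):
        raise ValueError("flux must be below every step's Vmax for a finite steady state")
    return ToyChain(Vmax=Vmax, Km=Km, flux=float(flux))
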