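"""Kinetic parameters and fixed pathway inputs.

The model carries 52 kinetic parameters: apparent saturation rate constants
(Vmax), apparent binding constants (Km), apparent inhibition constants (Ki),
lumped IPP/DMAPP consumption constants (k1, k1p) and first-order
cytosol<->plastid exchange constants (k2, k2p, k3, k3p).  The plastidic
isopentenyl-diphosphate isomerase (IDI) and the DMAPP-producing branch of HDR
are distinct named entities (``Vmax6pl``/``Km6pl``/``Ki6pl``,
``Vmax7pl``/``Km7pl``, ``Vmax14p``/``Km14p``) even though their reference
values equal their cytosolic / IPP-branch counterparts.

All concentrations are mM; the time unit is the hour (so Vmax is mM/h and the
circadian period is 24).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

__all__ = [
    "ParameterSet",
    "IndependentInputs",
    "PARAM_NAMES",
    "RATE_SCALE_PARAMS",
    "MVA_VMAX",
    "MEP_VMAX",
    "reference_parameters",
    "reference_inputs",
]


@dataclass(frozen=True)
class ParameterSet:
    """The 52 kinetic parameters of the joint MVA/MEP model.

    All entries must be non-negative; only the consumption and exchange
    constants (k1, k1p, k2, k2p, k3, k3p) may be exactly zero (exchange
    knockouts and the reference wiring use that).
    """

    # MVA pathway (cytosol/peroxisome)
    Vmax1: float
    Km1: float
    Ki1: float
    Vmax2: float
    Km2: float
    Ki2: float
    Vmax3: float
    Km3: float
    Ki31: float
    Ki32: float
    Ki33: float
    Ki34: float
    Ki35: float
    Vmax4: float
    Km4: float
    Ki4: float
    Vmax5: float
    Km5: float
    # cytosolic IDI
    Vmax6: float
    Km6: float
    Ki6: float
    Vmax7: float
    Km7: float
    # MEP pathway (plastid)
    Vmax8: float
    Km8: float
    Ki81: float
    Ki82: float
    Vmax9: float
    Km9: float
    Vmax10: float
    Km10: float
    Vmax11: float
    Km11: float
    Vmax12: float
    Km12: float
    Vmax13: float
    Km13: float
    Vmax14: float
    Km14: float
    Vmax14p: float
    Km14p: float
    # plastidic IDI
    Vmax6pl: float
    Km6pl: float
    Ki6pl: float
    Vmax7pl: float
    Km7pl: float
    # lumped downstream consumption (r20, r21), mM^-1 h^-1
    k1: float
    k1p: float
    # cytosol<->plastid exchange (r8, r22 export; r9, r23 import), h^-1
    k2: float
    k2p: float
    k3: float
    k3p: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v >= 0.0):
                raise ValueError(f"parameter {f.name} must be non-negative, got {v!r}")
            # binding/inhibition constants sit in denominators and must be
            # strictly positive; Vmax and the k's may be exactly zero
            # (knockouts, full-darkness expression modulation)
            if v == 0.0 and f.name.startswith(("Km", "Ki")):
                raise ValueError(f"parameter {f.name} must be strictly positive")

    def replace(self, **changes: float) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ParameterSet":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(d)
        if missing:
            raise KeyError(f"missing parameter(s): {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})


PARAM_NAMES: tuple[str, ...] = tuple(f.name for f in fields(ParameterSet))
assert len(PARAM_NAMES) == 52

#: Parameters carrying a 1/time dimension.  Multiplying all of them by a
#: common factor rescales time: the steady state is unchanged and every
#: Jacobian eigenvalue scales by that factor.
RATE_SCALE_PARAMS: tuple[str, ...] = tuple(
    n for n in PARAM_NAMES if n.startswith("Vmax") or n.startswith("k")
)

#: Vmax groups used by the circadian gene-expression wiring: MVA-side
#: enzymes are day-repressed, MEP-side enzymes day-activated.
MVA_VMAX: tuple[str, ...] = ("Vmax1", "Vmax2", "Vmax3", "Vmax4", "Vmax5", "Vmax6", "Vmax7")
MEP_VMAX: tuple[str, ...] = (
    "Vmax8", "Vmax9", "Vmax10", "Vmax11", "Vmax12", "Vmax13",
    "Vmax14", "Vmax14p", "Vmax6pl", "Vmax7pl",
)


@dataclass(frozen=True)
class IndependentInputs:
    """Fixed (clamped) substrate concentrations and homeostatic references.

    ``acetoacetylCoA``, ``G3P`` and ``pyruvate`` are the pathway substrates
    held constant by upstream metabolism; ``acCoA_H`` and ``pyruvate_H`` are
    the homeostatic reference levels the circadian substrate wiring scales
    from.  ``theta`` is the lumped, constant inhibition load exerted on
    mevalonate kinase by downstream prenyl diphosphates (FPP, GPP, GGPP,
    PhyPP) that are not dynamic variables of this model.
    """

    acetoacetylCoA: float = 0.350
    G3P: float = 0.006
    pyruvate: float = 1.600
    acCoA_H: float = 0.350
    pyruvate_H: float = 1.600
    theta: float = 4.711

    def __post_init__(self) -> None:
        for f in fields(self):
            if not (getattr(self, f.name) >= 0.0):
                raise ValueError(f"input {f.name} must be non-negative")

    def replace(self, **changes: float) -> "IndependentInputs":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# Published kinetic constants (mM, mM/h).  The plastid IDI and the DMAPP
# branch of HDR are initialised to their cytosolic/IPP-branch values.  The
# published consumption constants (2.0e6 / 1.6e4) are inconsistent with the
# published steady-state pools by many orders of magnitude and are replaced
# by the calibrated defaults below (see steady_state.calibrate_consumption
# and docs/methods.md); the DMAPP exchange constants default to zero for the
# same reason, with the published values (k2p=0.1, k3p=1.0) available via
# configuration.
_REFERENCE_VALUES: dict[str, float] = {
    "Vmax1": 0.454, "Km1": 0.043, "Ki1": 0.009,
    "Vmax2": 0.033, "Km2": 0.056, "Ki2": 0.081,
    "Vmax3": 234.4, "Km3": 0.046,
    "Ki31": 0.18, "Ki32": 0.0071, "Ki33": 0.031, "Ki34": 0.049, "Ki35": 0.0036,
    "Vmax4": 27.53, "Km4": 0.35, "Ki4": 0.014,
    "Vmax5": 9.3, "Km5": 0.01,
    "Vmax6": 5.7, "Km6": 0.005, "Ki6": 0.092,
    "Vmax7": 5.7, "Km7": 0.017,
    "Vmax8": 1.22, "Km8": 0.019, "Ki81": 0.065, "Ki82": 0.081,
    "Vmax9": 1.2, "Km9": 0.15,
    "Vmax10": 31.17, "Km10": 0.37,
    "Vmax11": 174.8, "Km11": 0.2,
    "Vmax12": 0.61, "Km12": 0.48,
    "Vmax13": 0.20, "Km13": 0.7,
    "Vmax14": 4.18, "Km14": 0.03,
    "Vmax14p": 4.18, "Km14p": 0.03,
    "Vmax6pl": 5.7, "Km6pl": 0.005, "Ki6pl": 0.092,
    "Vmax7pl": 5.7, "Km7pl": 0.017,
    # calibrated; see steady_state.calibrate_consumption
    "k1": 1.0064379216865678,
    "k1p": 0.6948719388666598,
    "k2": 0.1, "k2p": 0.0,
    "k3": 1.0, "k3p": 0.0,
}


def reference_parameters(**overrides: float) -> ParameterSet:
    """The reference (Model A) parameterization."""
    d = dict(_REFERENCE_VALUES)
    d.update(overrides)
    return ParameterSet.from_dict(d)


def reference_inputs(**overrides: float) -> IndependentInputs:
    """The reference fixed-input concentrations."""
    return IndependentInputs(**overrides)
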