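"""Energy fluxes, forcing functions and stage logic of the hax DEB model.

The organism is described by reserve ``E`` (J), structure ``V`` (cm^3),
maturity ``EH`` (J) and the reproduction buffer ``ER`` (J).  A fixed
fraction ``kappa`` of the mobilized reserve goes to somatic maintenance and
growth, the rest to maturity maintenance plus maturation or reproduction
(the kappa-rule).  Life stages alternate between feeding (larva) and
non-feeding (embryo, pupa, imago); the immature larva (instars L1-L3) grows
as a V1-morph, which accelerates assimilation and conductance by the factor
``sM``; every other stage is an isomorph.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .parameters import CoreParameterSet

__all__ = [
    "Stage",
    "PowerSet",
    "OrganismState",
    "temperature_correction",
    "functional_response",
    "acceleration_factor",
    "compute_fluxes",
]


class Stage(enum.Enum):
    """Life-cycle stage tags."""

    EMBRYO = "embryo"
    L1 = "L1"
    L2 = "L2"
    L3 = "L3"
    L4_PHASE1 = "L4_phase1"
    L4_PHASE2 = "L4_phase2"
    PUPA = "pupa"
    IMAGO = "imago"

    @property
    def feeds(self) -> bool:
        return self in _FEEDING

    @property
    def kappa_rule(self) -> bool:
        """Stages in which mobilized reserve is split by the kappa-rule."""
        return self not in (Stage.L4_PHASE2, Stage.IMAGO)


_FEEDING = {Stage.L1, Stage.L2, Stage.L3, Stage.L4_PHASE1, Stage.L4_PHASE2}


@dataclass(frozen=True)
class PowerSet:
    """Energy fluxes (J/d) of one model evaluation."""

    pA: float   # assimilation
    pC: float   # mobilization
    pS: float   # somatic maintenance
    pG: float   # growth
    pJ: float   # maturity maintenance
    pR: float   # maturation / reproduction


@dataclass
class OrganismState:
    """Instantaneous state of one individual."""

    t: float            # d, age since start of the embryo stage
    E: float            # J, reserve
    V: float            # cm^3, structure
    EH: float           # J, maturity
    ER: float           # J, reproduction buffer
    stage: Stage
    sM: float = 1.0     # -, acceleration factor
    S: float = 1.0      # -, survival probability

    @property
    def L(self) -> float:
        """Structural length V^(1/3) in cm."""
        return self.V ** (1.0 / 3.0)

    @property
    def reserve_density(self) -> float:
        """[E] = E/V in J/cm^3."""
        return self.E / self.V


def temperature_correction(T: float, params: CoreParameterSet) -> float:
    """Arrhenius correction factor cT for metabolic rates at body temperature T.

    Uses the three-parameter upper-bounded form

        cT(T) = exp(TA/Tref - TA/T) * u(Tref) / u(T),
        u(T)  = 1 + exp(TAH/TH - TAH/T),

    normalized so that cT(Tref) = 1.  The denominator damps rates above the
    upper tolerance boundary TH.  Every rate parameter in a flux evaluation
    at temperature T is multiplied by this single factor.
    """
    if not math.isfinite(T):
        raise ValueError(f"body temperature must be finite, got {T!r}")
    if not 273.0 < T < 320.0:
        raise ValueError(
            f"body temperature {T} K outside the simulation validity window (273, 320) K"
        )
    arr = math.exp(params.TA / params.Tref - params.TA / T)
    u = lambda temp: 1.0 + math.exp(params.TAH / params.TH - params.TAH / temp)
    return arr * u(params.Tref) / u(T)


def functional_response(X: float, XK: float) -> float:
    """Holling type II scaled functional response f = X / (XK + X).

    ``X`` is food density and ``XK`` the half-saturation constant; the result
    lies in [0, 1).  Scenario files may set f directly (including values
    above 1 for rich diets), but the Holling map itself never exceeds 1.
    """
    if XK <= 0:
        raise ValueError("half-saturation constant must be positive")
    if X < 0:
        raise ValueError("food density must be non-negative")
    return X / (XK + X)


def acceleration_factor(L: float, Lb: float, Lp: float) -> float:
    """Metabolic acceleration factor sM = max(1, min(L, Lp) / Lb).

    ``Lb`` and ``Lp`` are the structural lengths at birth and puberty.  The
    factor is 1 up to birth, rises linearly with structural length during the
    V1-morphic instars L1-L3 and saturates at Lp/Lb from puberty onwards.
    (Within a life-cycle simulation sM is frozen at its puberty value for all
    later stages, including the pupa whose structure restarts near zero.)
    """
    if Lb <= 0:
        raise ValueError("structural length at birth must be positive")
    if Lp < Lb:
        raise ValueError("Lp must not be smaller than Lb")
    return max(1.0, min(L, Lp) / Lb)


def compute_fluxes(
    state: OrganismState,
    f: float,
    params: CoreParameterSet,
    cT: float = 1.0,
) -> PowerSet:
    """Stage-dependent energy fluxes of the model.

    Feeding stages assimilate ``pA = {pAm} sM f V^(2/3)``.  Kappa-rule stages
    mobilize

        pC = E ([EG] v sM V^(2/3) + [pM] V) / (kappa E + [EG] V)

    and split it as ``pG = kappa pC - pS``, ``pR = (1-kappa) pC - pJ``.  In
    Phase II of the fourth instar mobilization only covers maintenance
    (``pC = pS + pJ``, ``pG = 0``) so assimilated energy accumulates in the
    reserve.  The imago mobilizes ``pC = E v sM V^(-1/3)`` and routes
    everything beyond maintenance to reproduction.  All rate parameters are
    temperature-corrected by the single factor ``cT``.
    """
    if f < 0:
        raise ValueError("scaled functional response must be non-negative")
    tp = params
    V = state.V
    E = state.E
    sM = state.sM
    pAm = tp.pAm * cT
    v = tp.v * cT
    pMc = tp.pM * cT
    kJc = tp.kJ * cT

    pS = pMc * V
    pJ = kJc * state.EH

    stage = state.stage
    if stage.feeds:
        pA = pAm * sM * f * V ** (2.0 / 3.0)
    else:
        pA = 0.0

    if stage is Stage.L4_PHASE2:
        pC = pS + pJ
        pG = 0.0
        pR = 0.0
    elif stage is Stage.IMAGO:
        if V <= 0:
            raise ValueError("imago requires positive structure")
        pC = E * v * sM * V ** (-1.0 / 3.0)
        pG = 0.0
        pR = pC - pS - pJ
    elif isinstance(stage, Stage):
        denom = tp.kappa * E + tp.EG * V
        pC = E * (tp.EG * v * sM * V ** (2.0 / 3.0) + pMc * V) / denom
        pG = tp.kappa * pC - pS
        pR = (1.0 - tp.kappa) * pC - pJ
    else:
        raise ValueError(f"unknown stage tag {stage!r}")

    return PowerSet(pA=pA, pC=pC, pS=pS, pG=pG, pJ=pJ, pR=pR)
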