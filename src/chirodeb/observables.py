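"""Mapping of DEB state variables to measurable quantities.

Physical length uses the shape coefficient ``deltaM`` (alive vs dead
specimens shrink differently, hence two coefficients).  Weights combine the
structure, reserve and reproduction-buffer compartments; the reproduction
buffer is assumed to be pure dry mass, so a growing buffer raises the
dry-weight fraction — the mechanism behind the rising dry-weight percentage
of fourth-instar larvae.

Weight-valued outputs depend on composition coefficients that are not part
of the core parameter set (see :class:`chirodeb.parameters.CompositionParams`);
treat them as order-of-magnitude predictions unless calibrated.
"""

from __future__ import annotations

import pandas as pd

from .core import OrganismState, PowerSet
from .parameters import CompositionParams, CoreParameterSet

__all__ = [
    "physical_length",
    "wet_and_dry_weight",
    "respiration_proxy",
    "append_observables",
]


def physical_length(V: float, deltaM: float) -> float:
    """Physical length Lw = V^(1/3) / deltaM in cm.

    Use ``deltaM1`` for measurements on living animals and ``deltaM2`` for
    dead (preserved) specimens; the smaller dead-specimen coefficient yields
    longer physical lengths for the same structure.
    """
    if deltaM <= 0:
        raise ValueError("shape coefficient must be positive")
    if V < 0:
        raise ValueError("structural volume must be non-negative")
    return V ** (1.0 / 3.0) / deltaM


def wet_and_dry_weight(
    state: OrganismState, comp: CompositionParams = CompositionParams()
) -> tuple[float, float]:
    """Wet and dry weight (g) of an individual.

    Dry weight sums the dry fractions of structure and reserve plus the
    (all-dry) reproduction buffer; wet weight adds water to structure and
    reserve but not to the buffer, so the buffer contributes identically to
    both.
    """
    m_struct_wet = comp.dV_wet * state.V
    m_struct_dry = m_struct_wet * (1.0 - comp.water_fraction_structure)
    m_res_dry = comp.wE_over_muE * state.E
    m_res_wet = m_res_dry / (1.0 - comp.water_fraction_reserve)
    m_buffer = comp.wE_over_muE * state.ER  # dry only
    Wd = m_struct_dry + m_res_dry + m_buffer
    Ww = m_struct_wet + m_res_wet + m_buffer
    return Ww, Wd


def respiration_proxy(powers: PowerSet, coefficient: float = 1.0) -> float:
    """Approximate oxygen-consumption proxy from dissipating fluxes.

    Returns ``coefficient * (pS + pJ)`` — the maintenance (dissipation)
    load, scaled by a single configurable coefficient.  This is an explicit
    approximation: a full respiration prediction requires chemical indices
    and composition coefficients outside the scope of this model, so the
    proxy should only be used for relative comparisons.
    """
    return coefficient * (powers.pS + powers.pJ)


def append_observables(
    trajectory: pd.DataFrame,
    params: CoreParameterSet,
    comp: CompositionParams = CompositionParams(),
) -> pd.DataFrame:
    """Return a copy of a trajectory with measurable columns appended.

    Adds ``length_cm_alive``, ``length_cm_dead``, ``wet_weight_mg`` and
    ``dry_weight_mg``.
    """
    out = trajectory.copy()
    L = out["V_cm3"].to_numpy() ** (1.0 / 3.0)
    out["length_cm_alive"] = L / params.deltaM1
    out["length_cm_dead"] = L / params.deltaM2
    m_struct_wet = comp.dV_wet * out["V_cm3"]
    m_struct_dry = m_struct_wet * (1.0 - comp.water_fraction_structure)
    m_res_dry = comp.wE_over_muE * out["E_J"]
    m_res_wet = m_res_dry / (1.0 - comp.water_fraction_reserve)
    m_buffer = comp.wE_over_muE * out["ER_J"]
    out["wet_weight_mg"] = 1e3 * (m_struct_wet + m_res_wet + m_buffer)
    out["dry_weight_mg"] = 1e3 * (m_struct_dry + m_res_dry + m_buffer)
    return out
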