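"""Species parameter sets for the *Chironomus riparius* DEB model.

All internal quantities use the DEB bookkeeping units: energies in J,
structural volumes in cm^3, lengths in cm, times in d, temperatures in K.
Rate parameters are understood at the reference temperature ``Tref`` and are
corrected to the simulation temperature with a single Arrhenius factor (see
:func:`chirodeb.core.temperature_correction`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "CoreParameterSet",
    "CompositionParams",
    "chironomus_riparius",
    "load_parameters",
    "save_parameters",
]


@dataclass(frozen=True)
class CoreParameterSet:
    """Core DEB parameters of the hax-type life-cycle model.

    Field names follow the standard DEB symbols: ``pAm`` is the
    surface-area-specific maximum assimilation rate {p_Am}, ``v`` the energy
    conductance, ``kappa`` the allocation fraction to soma, ``pM`` the
    volume-specific somatic maintenance [p_M], ``kJ`` the maturity
    maintenance rate coefficient, ``EG`` the volume-specific cost of
    structure [E_G].  Maturity thresholds ``EHb``/``EHp``/``EHe`` gate birth,
    puberty and emergence; ``ERj`` is the reproduction-buffer density that
    switches the fourth instar from Phase I to Phase II, and the maximum
    reserve density ``Em = pAm / v`` is the reserve density that triggers
    pupation.
    """

    # energetics (rates at Tref)
    pAm: float = 203.0        # J / (d cm^2), {p_Am}; multiplied by sM while accelerating
    v: float = 0.007          # cm / d, energy conductance; multiplied by sM
    kappa: float = 0.44       # -, allocation fraction to soma
    pM: float = 145.1         # J / (d cm^3), [p_M]
    kJ: float = 0.036         # 1 / d, maturity maintenance rate coefficient
    EG: float = 4018.0        # J / cm^3, [E_G]
    # maturity / reproduction thresholds
    EHb: float = 0.003        # J, maturity at birth
    EHp: float = 0.277        # J, maturity at puberty
    EHe: float = 1.072        # J, maturity at emergence (pupal track)
    ERj: float = 5323.0       # J / cm^3, reproduction buffer density at pupation
    kappaV: float = 1.1e-6    # -, conversion efficiency structure -> reserve at pupation
    kappaR: float = 0.95      # -, reproduction efficiency (conventional DEB default;
                              #    enters only the egg-number formula)
    # thermal biology
    TA: float = 6420.0        # K, Arrhenius temperature
    TAH: float = 18250.0      # K, Arrhenius temperature at the upper boundary
    TH: float = 309.9         # K, upper boundary of the tolerance range
    Tref: float = 293.15      # K, reference temperature (20 degC)
    # shape
    deltaM1: float = 0.083    # -, shape coefficient, alive measurements
    deltaM2: float = 0.067    # -, shape coefficient, dead measurements
    # Dyar's-law molt constants (partition of the immature larval track)
    s1: float = 2.48          # -, constant for the 1st molt
    s2: float = 2.48          # -, constant for the 2nd molt
    # hazard
    hb: float = 0.02          # 1 / d, background hazard rate
    kstarv: float = 3.09      # 1 / d, starvation killing rate
    # male override
    pAmm: float = 172.3       # J / (d cm^2), male {p_Am}

    def __post_init__(self) -> None:
        positive = (
            "pAm v pM kJ EG EHb EHp EHe ERj kappaV kappaR TA TAH TH Tref "
            "deltaM1 deltaM2 s1 s2 kstarv pAmm"
        ).split()
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        if not 0 < self.kappa < 1:
            raise ValueError("kappa must lie in (0, 1)")
        if not self.kappaV <= 1 or not self.kappaR <= 1:
            raise ValueError("conversion efficiencies must not exceed 1")
        if self.hb < 0:
            raise ValueError("background hazard must be non-negative")
        if not self.EHb < self.EHp:
            raise ValueError("maturity thresholds must satisfy EHb < EHp")

    # ----- derived quantities -------------------------------------------
    @property
    def Em(self) -> float:
        """Maximum reserve density [E_m] = {p_Am}/v in J/cm^3.

        Invariant under acceleration because {p_Am} and v carry the same
        acceleration factor.
        """
        return self.pAm / self.v

    @property
    def maintenance_ratio(self) -> float:
        """k = kJ [E_G] / [p_M], the maturity/somatic maintenance ratio."""
        return self.kJ * self.EG / self.pM

    def for_sex(self, sex: str) -> "CoreParameterSet":
        """Return the parameter set for ``sex`` ('female' or 'male').

        Males share every parameter except the maximum assimilation rate,
        which is replaced by ``pAmm`` (this also lowers [E_m]).
        """
        if sex == "female":
            return self
        if sex == "male":
            return dataclasses.replace(self, pAm=self.pAmm)
        raise ValueError(f"unknown sex {sex!r}")

    def replace(self, **kwargs: float) -> "CoreParameterSet":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class CompositionParams:
    """Conversion coefficients between DEB state variables and weights.

    These coefficients are not part of the core parameter set and follow
    common DEB practice; weight-valued outputs are sensitive to them and
    should be treated as order-of-magnitude predictions unless the
    coefficients have been calibrated against weight data for the population
    at hand.

    Dry mass of reserve and reproduction buffer is ``wE_over_muE`` grams per
    joule (the default combines a reserve chemical potential of 550 kJ/C-mol
    with a C-mol weight of 23.9 g).  Structure has wet specific density
    ``dV_wet`` and a water fraction ``water_fraction_structure``; reserve
    carries water fraction ``water_fraction_reserve``.  The reproduction
    buffer is assumed to be pure dry mass (eggs of aquatic insects take up
    water only after laying), so it contributes identically to wet and dry
    weight.
    """

    dV_wet: float = 1.0                   # g / cm^3, wet specific density of structure
    water_fraction_structure: float = 0.83  # -, water fraction of wet structure
    wE_over_muE: float = 4.345e-5         # g / J, dry mass per unit reserve energy
    water_fraction_reserve: float = 0.70  # -, water fraction of wet reserve

    def __post_init__(self) -> None:
        if self.dV_wet <= 0 or self.wE_over_muE <= 0:
            raise ValueError("densities and mass-per-energy must be positive")
        for name in ("water_fraction_structure", "water_fraction_reserve"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in [0, 1)")


_ALIASES = {  # config-file keys -> dataclass fields
    "p_Am": "pAm", "kap": "kappa", "p_M": "pM", "k_J": "kJ", "E_G": "EG",
    "E_Hb": "EHb", "E_Hp": "EHp", "E_He": "EHe", "E_Rj": "ERj",
    "kap_V": "kappaV", "kap_R": "kappaR", "T_A": "TA", "T_AH": "TAH",
    "T_H": "TH", "T_ref": "Tref", "del_M1": "deltaM1", "del_M2": "deltaM2",
    "h_b": "hb", "k_starv": "kstarv", "p_Amm": "pAmm",
}


def chironomus_riparius() -> CoreParameterSet:
    """The packaged *C. riparius* parameter set (reference temperature 20 degC)."""
    path = resources.files("chirodeb").joinpath("species/chironomus_riparius.yaml")
    with resources.as_file(path) as p:
        return load_parameters(p)


def load_parameters(path: str | Path) -> CoreParameterSet:
    """Load a parameter set from a flat key/value YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"parameter file {path} must be a flat mapping")
    fields = {f.name for f in dataclasses.fields(CoreParameterSet)}
    values: dict[str, float] = {}
    for key, val in raw.items():
        name = _ALIASES.get(key, key)
        if name not in fields:
            raise ValueError(f"unknown parameter {key!r} in {path}")
        values[name] = float(val)
    return CoreParameterSet(**values)


def save_parameters(params: CoreParameterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
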