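"""Dissolved gas concentrations from headspace partial pressures.

Henry's law in the solubility form: ``c [mol m^-3] = k × p [Pa]``, with the
constant adjusted for temperature by the van 't Hoff relation and for
salinity by Setchenow salting-out:

    k(T, S) = k_ref × exp(B × (1/T − 1/T_ref)) × 10^(−K_s × S)

where B (K) is the temperature-dependence parameter (≈1700–1900 K for CH4),
K_s (L/mol) the Setchenow coefficient and S (mol/L) the effective salt
concentration. 1 mol m⁻³ equals 1 mM, so dissolved concentrations read
directly in millimolar. A directly supplied, already-adjusted constant can
be used by passing zero adjustment coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp


@dataclass(frozen=True)
class HenryParams:
    """Henry's law parameterization for one gas."""

    k_ref: float  # mol m^-3 Pa^-1 at t_ref
    t_ref: float = 298.15  # K
    vant_hoff_coeff: float = 0.0  # K
    setchenow_coeff: float = 0.0  # L / mol
    salinity_molar: float = 0.0  # mol / L

    def __post_init__(self):
        if self.k_ref <= 0:
            raise ValueError("k_ref must be > 0")
        if self.t_ref <= 0:
            raise ValueError("t_ref must be > 0")


#: CH4 in water: k_ref 1.4e-5 mol m^-3 Pa^-1 at 298.15 K, van 't Hoff 1700 K
#: (widely tabulated values); seawater salting-out left to the caller.
CH4_FRESHWATER = HenryParams(k_ref=1.4e-5, t_ref=298.15, vant_hoff_coeff=1700.0)


def henry_constant_adjusted(p: HenryParams, temperature: float) -> float:
    """Temperature- and salinity-adjusted Henry constant, mol m⁻³ Pa⁻¹."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    k = p.k_ref * exp(p.vant_hoff_coeff * (1.0 / temperature - 1.0 / p.t_ref))
    if p.setchenow_coeff and p.salinity_molar:
        k *= 10.0 ** (-p.setchenow_coeff * p.salinity_molar)
    return k


def dissolved_concentration(k: float, partial_pressure: float) -> float:
    """Equilibrium dissolved concentration in mol m⁻³ (= mM)."""
    if k <= 0:
        raise ValueError("Henry constant must be > 0")
    if partial_pressure < 0:
        raise ValueError("partial pressure must be >= 0")
    return k * partial_pressure
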