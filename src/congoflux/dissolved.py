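"""Dissolved CH₄/N₂O concentrations from vial headspace equilibration.

Stream water (canonically 6 mL) is injected into an N₂-pre-flushed
12 mL vial; after equilibration the headspace mole fraction is measured
and the original in-stream dissolved concentration recovered by a
two-compartment mole balance with Henry's law:

    p        = x_hs · P                      partial pressure [atm]
    n_hs     = p · V_hs / (R·T)              headspace moles
    n_aq     = kH(T) · p · V_w               aqueous moles at equilibrium
    C_stream = (n_hs + n_aq − n_init) / V_w  [mol L⁻¹]

where n_init is whatever analyte the headspace held before equilibration
(zero for N₂-flushed vials) and kH(T) follows a van't Hoff relation
around 298.15 K.  Concentrations are reported per litre on an
element-mass basis (µg C or µg N) by default; a full-molecule basis is
also supported (see the note on the N₂O atmospheric-equilibrium
reference in docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .chamber import R_GAS
from .units import ELEMENT_MASS, MOLECULE_MASS

T_REF = 298.15  # van't Hoff reference temperature [K]


@dataclass(frozen=True)
class SolubilityParams:
    """Henry solubility kH at 298.15 K [mol L⁻¹ atm⁻¹] and van't Hoff coefficient [K]."""

    species: str
    kH_298: float
    vant_hoff: float

    def __post_init__(self) -> None:
        if not self.kH_298 > 0:
            raise ValueError("kH_298 must be > 0")
        if not self.vant_hoff > 0:
            raise ValueError("vant_hoff must be > 0")


#: Sander-compilation-style defaults for freshwater; overrideable in config.
DEFAULT_SOLUBILITY = {
    "CH4": SolubilityParams("CH4", kH_298=1.4e-3, vant_hoff=1750.0),
    "N2O": SolubilityParams("N2O", kH_298=2.4e-2, vant_hoff=2700.0),
}

#: Default atmospheric dry-air mixing ratios [nmol mol⁻¹], circa 2016–2020.
DEFAULT_ATM_PPB = {"CH4": 1870.0, "N2O": 332.0}


@dataclass(frozen=True)
class VialSample:
    """One stream headspace-equilibration record.

    Volumes in mL (water + headspace = vial volume); equilibration
    temperature in K; lab pressure in atm; mole fractions in nmol mol⁻¹
    (ppb).  ``initial_headspace_mole_fraction`` is 0 for N₂-flushed
    vials.
    """

    species: str
    water_volume: float
    headspace_volume: float
    equilibration_temperature: float
    headspace_mole_fraction: float
    lab_pressure: float = 1.0
    initial_headspace_mole_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (self.water_volume > 0 and self.headspace_volume > 0):
            raise ValueError("water and headspace volumes must be > 0 mL")
        if not self.equilibration_temperature > 0:
            raise ValueError("equilibration temperature must be > 0 K")
        if not self.lab_pressure > 0:
            raise ValueError("lab pressure must be > 0 atm")
        if self.headspace_mole_fraction < 0 or self.initial_headspace_mole_fraction < 0:
            raise ValueError("mole fractions must be >= 0 ppb")


@dataclass(frozen=True)
class DissolvedResult:
    """Recovered in-stream concentration, molar and element-mass basis."""

    species: str
    concentration_molar: float  # mol L⁻¹
    concentration_mass: float  # µg element (or molecule) L⁻¹
    basis: str = "element"
    saturation_ratio: float | None = None


def mass_per_mole(species: str, basis: str = "element") -> float:
    """Grams per mole of dissolved gas on the chosen reporting basis."""
    table = {"element": ELEMENT_MASS, "molecule": MOLECULE_MASS}
    try:
        masses = table[basis]
    except KeyError:
        raise ValueError(f"basis must be 'element' or 'molecule', got {basis!r}") from None
    try:
        return masses[species]
    except KeyError:
        raise ValueError(f"unknown species {species!r}") from None


def henry_constant(params: SolubilityParams, temperature: float) -> float:
    """Henry solubility at ``temperature`` [mol L⁻¹ atm⁻¹].

    kH(T) = kH_298 · exp(vant_hoff · (1/T − 1/298.15)); strictly
    decreasing in T.  Temperatures outside (263, 323) K raise an
    extrapolation warning but still evaluate.
    """
    import math

    if not temperature > 0:
        raise ValueError("temperature must be > 0 K")
    if not 263.0 < temperature < 323.0:
        warnings.warn(
            f"Henry's-law extrapolation: T = {temperature} K outside (263, 323) K",
            stacklevel=2,
        )
    return params.kH_298 * math.exp(params.vant_hoff * (1.0 / temperature - 1.0 / T_REF))


def headspace_to_dissolved(
    vial: VialSample,
    params: SolubilityParams | None = None,
    *,
    basis: str = "element",
) -> DissolvedResult:
    """Recover the original dissolved concentration from a vial measurement.

    Raises ``ValueError`` if the mole balance yields a negative
    concentration, which signals inconsistent inputs (e.g. an initial
    headspace richer than the equilibrated one without aqueous uptake to
    explain it).
    """
    if params is None:
        params = DEFAULT_SOLUBILITY[vial.species]
    T = vial.equilibration_temperature
    kH = henry_constant(params, T)
    v_w = vial.water_volume / 1000.0  # mL → L
    v_hs = vial.headspace_volume / 1000.0
    p = vial.headspace_mole_fraction * 1e-9 * vial.lab_pressure
    n_hs = p * v_hs / (R_GAS * T)
    n_aq = kH * p * v_w
    n_init = vial.initial_headspace_mole_fraction * 1e-9 * vial.lab_pressure * v_hs / (R_GAS * T)
    conc = (n_hs + n_aq - n_init) / v_w
    if conc < 0:
        raise ValueError(
            f"recovered concentration is negative ({conc:.3e} mol/L): inconsistent vial inputs"
        )
    mass = conc * mass_per_mole(vial.species, basis) * 1e6  # mol/L → µg/L
    return DissolvedResult(
        species=vial.species, concentration_molar=conc, concentration_mass=mass, basis=basis
    )


def equilibrium_concentration(
    species: str,
    temperature: float,
    atm_mixing_ratio: float | None = None,
    params: SolubilityParams | None = None,
    *,
    basis: str = "element",
) -> float:
    """Dissolved concentration at equilibrium with the atmosphere [µg L⁻¹].

    kH(T) · x_atm · 1 atm, converted to a mass concentration on the
    chosen basis.  This is the dashed reference line against which
    stream samples are judged super- or undersaturated.
    """
    if atm_mixing_ratio is None:
        atm_mixing_ratio = DEFAULT_ATM_PPB[species]
    if atm_mixing_ratio < 0:
        raise ValueError("atmospheric mixing ratio must be >= 0 ppb")
    if params is None:
        params = DEFAULT_SOLUBILITY[species]
    kH = henry_constant(params, temperature)
    return kH * atm_mixing_ratio * 1e-9 * mass_per_mole(species, basis) * 1e6


def saturation_ratio(
    concentration_mass: float,
    species: str,
    stream_temperature: float,
    atm_mixing_ratio: float | None = None,
    params: SolubilityParams | None = None,
    *,
    basis: str = "element",
) -> float:
    """Concentration relative to atmospheric equilibrium; > 1 is supersaturated."""
    eq = equilibrium_concentration(
        species, stream_temperature, atm_mixing_ratio, params, basis=basis
    )
    if eq == 0:
        raise ValueError("equilibrium concentration is zero; saturation ratio undefined")
    return concentration_mass / eq
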