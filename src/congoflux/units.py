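"""Unit conversions between instantaneous area fluxes and annual element-mass fluxes.

Chamber measurements yield fluxes in nmol m⁻² s⁻¹; budgets and
cross-study comparisons are reported as kg of element (C for CH₄, N for
N₂O) per hectare per year.  The conversion is a fixed product of the
element mass carried per mole of gas, the length of the year, and the
m²→ha and g→kg scalings.
"""

from __future__ import annotations

#: Julian year of 365.25 days, in seconds.
SECONDS_PER_YEAR = 3.15576e7

#: Grams of reported element per mole of gas (IUPAC 2021 atomic masses).
#: CH₄ carries one carbon (12.011 g), N₂O two nitrogens (2 × 14.007 g).
ELEMENT_MASS = {"CH4": 12.011, "N2O": 2 * 14.007}

#: Full molecular masses [g mol⁻¹], used for molecule-basis dissolved
#: concentrations.
MOLECULE_MASS = {"CH4": 16.043, "N2O": 44.013}


def _element_mass(species: str, element_mass: float | None) -> float:
    if element_mass is not None:
        return element_mass
    try:
        return ELEMENT_MASS[species]
    except KeyError:
        raise ValueError(f"unknown species {species!r}; expected one of {sorted(ELEMENT_MASS)}") from None


def nmol_to_annual(
    flux: float,
    species: str,
    *,
    element_mass: float | None = None,
    seconds_per_year: float = SECONDS_PER_YEAR,
) -> float:
    """Convert a flux in nmol m⁻² s⁻¹ to kg element ha⁻¹ yr⁻¹.

    The sign is preserved (micrometeorological convention: negative is
    uptake).  ``element_mass`` and ``seconds_per_year`` may be overridden
    for sensitivity checks; defaults are IUPAC masses and a 365.25-day
    year.
    """
    m = _element_mass(species, element_mass)
    # nmol→mol (1e-9) · g/mol · s/yr · m²/ha (1e4) · g→kg (1e-3)
    return flux * 1e-9 * m * seconds_per_year * 1e4 / 1e3


def annual_to_nmol(
    flux: float,
    species: str,
    *,
    element_mass: float | None = None,
    seconds_per_year: float = SECONDS_PER_YEAR,
) -> float:
    """Exact inverse of :func:`nmol_to_annual`."""
    m = _element_mass(species, element_mass)
    return flux / (1e-9 * m * seconds_per_year * 1e4 / 1e3)
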