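"""Static-chamber flux estimation.

A closed chamber of headspace volume V [L] sits on a soil collar of
footprint S [m²] for one hour; headspace air is sampled at fixed times
(canonically 0, 20, 40, 60 min) and analysed for the dry-air mole
fraction of CH₄ or N₂O.  The soil–atmosphere flux follows from the
ordinary-least-squares slope of mole fraction against time and the total
moles of air in the chamber by the ideal gas law:

    n = P·V / (R·T)          (R = 0.08206 L atm K⁻¹ mol⁻¹)
    F = (dx/dt) · n / S      [nmol m⁻² s⁻¹]

Signs follow the micrometeorological convention: negative flux denotes
uptake by the soil.  Fits with R² ≤ 0.95 are flagged (``qc_pass``) but
never discarded — low R² is typically a near-zero flux, and dropping
those records would bias summaries toward high fluxes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Ideal gas constant in chamber-friendly units [L atm K⁻¹ mol⁻¹].
R_GAS = 0.08206

#: Default QC threshold on the time-regression R² (strict ">").
QC_R2_THRESHOLD = 0.95

SPECIES = ("CH4", "N2O")


@dataclass(frozen=True)
class ChamberGeometry:
    """Chamber headspace volume [L] and enclosed soil area [m²].

    ``kind`` distinguishes soil collars ("static") from water-surface
    deployments ("floating"); it does not change the flux formula.
    """

    volume: float
    area: float
    kind: str = "static"

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise ValueError(f"chamber volume must be > 0 L, got {self.volume}")
        if not self.area > 0:
            raise ValueError(f"chamber area must be > 0 m², got {self.area}")
        if self.kind not in ("static", "floating"):
            raise ValueError(f"kind must be 'static' or 'floating', got {self.kind!r}")

    @classmethod
    def from_cylinder(cls, diameter: float, height: float, kind: str = "static") -> "ChamberGeometry":
        """Cylindrical chamber from diameter and height in metres.

        volume = π (d/2)² h (converted to litres), area = π (d/2)².
        """
        if not (diameter > 0 and height > 0):
            raise ValueError("diameter and height must be > 0 m")
        r = diameter / 2.0
        area = math.pi * r * r
        return cls(volume=area * height * 1000.0, area=area, kind=kind)


#: The study's standard soil chamber: d = h = 0.30 m.
DEFAULT_GEOMETRY = ChamberGeometry.from_cylinder(0.30, 0.30)


@dataclass(frozen=True)
class HeadspaceSeries:
    """One chamber closure: sampling times with mole fractions and temperatures.

    times are minutes since closure (strictly increasing, ≥ 2 points),
    mole_fractions are dry-air nmol mol⁻¹ (ppb), temperatures are
    per-time-point headspace temperatures in kelvin, pressure is ambient
    pressure in atm.
    """

    chamber_id: str
    species: str
    times: tuple[float, ...]
    mole_fractions: tuple[float, ...]
    temperatures: tuple[float, ...]
    pressure: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "mole_fractions", tuple(float(x) for x in self.mole_fractions))
        object.__setattr__(self, "temperatures", tuple(float(t) for t in self.temperatures))
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}, got {self.species!r}")
        n = len(self.times)
        if n < 2:
            raise ValueError("a headspace series needs at least 2 time points")
        if len(self.mole_fractions) != n or len(self.temperatures) != n:
            raise ValueError("times, mole_fractions and temperatures must have equal length")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(t <= 0 for t in self.temperatures):
            raise ValueError("temperatures must be > 0 K")
        if any(x < 0 for x in self.mole_fractions):
            raise ValueError("mole fractions must be >= 0")
        if not self.pressure > 0:
            raise ValueError("pressure must be > 0 atm")


@dataclass(frozen=True)
class FluxEstimate:
    """Result of one chamber-closure flux fit.

    flux is nmol m⁻² s⁻¹ (negative = uptake); slope is the fitted
    mole-fraction change rate in nmol mol⁻¹ s⁻¹; qc_pass flags
    r_squared above the QC threshold; retained is always True — low-R²
    records are flagged, not dropped.
    """

    chamber_id: str
    species: str
    flux: float
    slope: float
    r_squared: float
    n_points: int
    qc_pass: bool
    retained: bool = True


def fit_concentration_slope(series: HeadspaceSeries) -> tuple[float, float]:
    """OLS slope of mole fraction vs. time, in nmol mol⁻¹ s⁻¹, with its R².

    The regression runs on minutes (as recorded in the field) and the
    slope is converted to per-second once.  Conventions: a constant
    (zero-variance) series returns slope 0 with R² defined as 0 — such
    closures are genuine zero fluxes and are kept, failing QC; a
    two-point series returns R² = 1 (the fit is exact by construction).
    """
    t = np.asarray(series.times, dtype=float)
    x = np.asarray(series.mole_fractions, dtype=float)
    n = t.size
    tc = t - t.mean()
    xc = x - x.mean()
    sxx = float(tc @ tc)
    if sxx == 0.0:
        raise ValueError("identical time values: slope undefined")
    syy = float(xc @ xc)
    if syy == 0.0:
        return 0.0, 0.0
    slope_per_min = float(tc @ xc) / sxx
    if n == 2:
        r2 = 1.0
    else:
        ss_res = syy - slope_per_min * float(tc @ xc)
        r2 = 1.0 - ss_res / syy
        r2 = min(max(r2, 0.0), 1.0)
    return slope_per_min / 60.0, r2


def chamber_moles(geometry: ChamberGeometry, temperature: float, pressure: float = 1.0) -> float:
    """Total moles of gas in the chamber headspace: n = P·V/(R·T)."""
    if not temperature > 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    if not pressure > 0:
        raise ValueError(f"pressure must be > 0 atm, got {pressure}")
    return pressure * geometry.volume / (R_GAS * temperature)


def compute_flux(
    series: HeadspaceSeries,
    geometry: ChamberGeometry = DEFAULT_GEOMETRY,
    *,
    temperature_mode: str = "mean",
    qc_threshold: float = QC_R2_THRESHOLD,
) -> FluxEstimate:
    """Soil–atmosphere flux of one chamber closure [nmol m⁻² s⁻¹].

    The headspace temperature entering n = PV/RT is the arithmetic mean
    of the per-time-point temperatures (``temperature_mode="mean"``) or
    the closure-start value (``"first"``).
    """
    slope, r2 = fit_concentration_slope(series)
    if temperature_mode == "mean":
        temp = float(np.mean(series.temperatures))
    elif temperature_mode == "first":
        temp = series.temperatures[0]
    else:
        raise ValueError(f"temperature_mode must be 'mean' or 'first', got {temperature_mode!r}")
    n_total = chamber_moles(geometry, temp, series.pressure)
    # slope [nmol mol⁻¹ s⁻¹] × n [mol] = nmol s⁻¹; per unit soil area.
    flux = slope * n_total / geometry.area
    return FluxEstimate(
        chamber_id=series.chamber_id,
        species=series.species,
        flux=flux,
        slope=slope,
        r_squared=r2,
        n_points=len(series.times),
        qc_pass=r2 > qc_threshold,
        retained=True,
    )


def compute_fluxes(
    series_list: Sequence[HeadspaceSeries],
    geometry: ChamberGeometry = DEFAULT_GEOMETRY,
    **kwargs,
) -> list[FluxEstimate]:
    """Vector convenience wrapper over :func:`compute_flux`."""
    return [compute_flux(s, geometry, **kwargs) for s in series_list]
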