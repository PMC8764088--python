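"""Seeded synthetic-data generators for every pipeline input.

Each generator is the exact inverse of its analysis stage at zero
noise, so round-trip tests pin the algebra, and carries the statistical
structure the analysis assumes:

* chamber series — linear headspace accumulation (optionally saturating)
  with additive Gaussian measurement noise;
* flux panels — lognormal fluxes with plot-, chamber-, date- and
  residual-level Gaussian variation on the log scale plus optional
  temperature/WFPS fixed effects;
* stream vials — the two-compartment Henry's-law mole balance solved
  forward for the headspace mole fraction implied by a known dissolved
  concentration;
* isotope pairs — forward two-pool mixing of a background and a source
  δ signature.

Reproducibility: every generator derives its RNG from the user seed plus
a stable per-generator salt, so composed pipelines are reproducible
regardless of call order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chamber import ChamberGeometry, DEFAULT_GEOMETRY, HeadspaceSeries, R_GAS, chamber_moles
from .dissolved import DEFAULT_SOLUBILITY, SolubilityParams, VialSample, henry_constant, mass_per_mole
from .isotopes import IsotopePair

DEFAULT_TIMES = (0.0, 20.0, 40.0, 60.0)


def _rng(seed: int, generator_name: str) -> np.random.Generator:
    """RNG stream salted by generator name for call-order independence."""
    salt = zlib.crc32(generator_name.encode()) % (2**31)
    return np.random.default_rng([salt, seed % (2**31)])


# ---------------------------------------------------------------------------
# chamber headspace series


@dataclass(frozen=True)
class ChamberSimSpec:
    """Forward model of one chamber closure.

    true_flux in nmol m⁻² s⁻¹; noise_sd is additive Gaussian measurement
    noise on each mole fraction [ppb]; curvature, if set, is the
    e-folding time [min] of an exponentially saturating accumulation
    whose initial slope matches the linear one (None = strictly linear).
    """

    true_flux: float
    geometry: ChamberGeometry = DEFAULT_GEOMETRY
    temperature: float = 298.15
    pressure: float = 1.0
    noise_sd: float = 0.0
    curvature: float | None = None
    species: str = "N2O"
    baseline_ppb: float = 330.0
    times: tuple[float, ...] = DEFAULT_TIMES
    chamber_id: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.curvature is not None and self.curvature <= 0:
            raise ValueError("curvature (e-folding time) must be > 0 min")


def generate_chamber_series(spec: ChamberSimSpec) -> HeadspaceSeries:
    """Headspace series whose noise-free OLS flux equals ``spec.true_flux``."""
    rng = _rng(spec.seed, "chamber_series")
    n_total = chamber_moles(spec.geometry, spec.temperature, spec.pressure)
    # flux [nmol m⁻² s⁻¹] → mole-fraction slope [ppb min⁻¹]
    slope_ppb_min = spec.true_flux * spec.geometry.area / n_total * 60.0
    t = np.asarray(spec.times, dtype=float)
    if spec.curvature is None:
        x = spec.baseline_ppb + slope_ppb_min * t
    else:
        tau = spec.curvature
        x = spec.baseline_ppb + slope_ppb_min * tau * (1.0 - np.exp(-t / tau))
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd, size=t.size)
    x = np.maximum(x, 0.0)
    return HeadspaceSeries(
        chamber_id=spec.chamber_id,
        species=spec.species,
        times=tuple(t),
        mole_fractions=tuple(x),
        temperatures=(spec.temperature,) * t.size,
        pressure=spec.pressure,
    )


# ---------------------------------------------------------------------------
# flux panels


@dataclass(frozen=True)
class PanelSimSpec:
    """Forward model of a per-forest-type flux panel.

    ``true_median`` is the geometric-mean flux on the reporting scale
    (its sign must match ``sign_regime``); chamber/date/residual SDs act
    on the log scale.  ``sign_regime="mixed"`` produces fluxes
    exp(N) − shift whose median is ``true_median`` and requires
    ``shift`` > 0 (recoverable with a shifted_log transform at the same
    shift).  β coefficients are log-scale slopes per unit covariate,
    applied around the covariate range midpoints so the median is
    preserved.
    """

    true_median: float
    sd_chamber: float = 0.4
    sd_date: float = 0.3
    sd_residual: float = 0.5
    sd_plot: float = 0.0
    n_chambers: int = 5
    n_plots: int = 1
    n_dates: int = 52
    beta_temp: float = 0.0
    beta_wfps: float = 0.0
    temp_range: tuple[float, float] = (20.0, 28.0)
    wfps_range: tuple[float, float] = (40.0, 90.0)
    sign_regime: str = "positive"
    shift: float = 0.0
    forest_type: str = "lowland"
    site: str = "sim-site"
    units: str = "kg_ha_yr"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sd_chamber, self.sd_date, self.sd_residual, self.sd_plot) < 0:
            raise ValueError("log-scale SDs must be >= 0")
        if min(self.n_chambers, self.n_plots, self.n_dates) < 1:
            raise ValueError("counts must be >= 1")
        if self.sign_regime not in ("positive", "negative", "mixed"):
            raise ValueError("sign_regime must be 'positive', 'negative' or 'mixed'")
        if self.sign_regime == "positive" and self.true_median <= 0:
            raise ValueError("positive regime requires true_median > 0")
        if self.sign_regime == "negative" and self.true_median >= 0:
            raise ValueError("negative regime requires true_median < 0")
        if self.sign_regime == "mixed":
            if self.shift <= 0:
                raise ValueError("mixed sign regime requires shift > 0")
            if self.true_median + self.shift <= 0:
                raise ValueError("mixed regime requires true_median + shift > 0")


def generate_flux_panel(spec: PanelSimSpec) -> pd.DataFrame:
    """Long-format flux panel with the mixed-model variance structure.

    log-scale response: log m + b_plot + b_chamber + b_date +
    β_t(T − T̄) + β_w(W − W̄) + ε, back-transformed per sign regime,
    where m is |true_median| (positive/negative) or
    true_median + shift (mixed).
    """
    rng = _rng(spec.seed, "flux_panel")
    if spec.sign_regime == "mixed":
        log_m = np.log(spec.true_median + spec.shift)
    else:
        log_m = np.log(abs(spec.true_median))

    plots = [f"plot{p}" for p in range(spec.n_plots)]
    chambers = [(p, f"ch{c}") for p in plots for c in range(spec.n_chambers)]
    dates = pd.date_range("2018-01-01", periods=spec.n_dates, freq="7D")

    b_plot = dict(zip(plots, rng.normal(0.0, spec.sd_plot, len(plots))))
    b_chamber = {pc: v for pc, v in zip(chambers, rng.normal(0.0, spec.sd_chamber, len(chambers)))}
    b_date = dict(zip(dates, rng.normal(0.0, spec.sd_date, len(dates))))

    t_mid = 0.5 * (spec.temp_range[0] + spec.temp_range[1])
    w_mid = 0.5 * (spec.wfps_range[0] + spec.wfps_range[1])

    rows = []
    for plot, chamber in chambers:
        for date in dates:
            temp = rng.uniform(*spec.temp_range)
            wfps = rng.uniform(*spec.wfps_range)
            eps = rng.normal(0.0, spec.sd_residual)
            log_val = (
                log_m
                + b_plot[plot]
                + b_chamber[(plot, chamber)]
                + b_date[date]
                + spec.beta_temp * (temp - t_mid)
                + spec.beta_wfps * (wfps - w_mid)
                + eps
            )
            mag = np.exp(log_val)
            if spec.sign_regime == "positive":
                flux = mag
            elif spec.sign_regime == "negative":
                flux = -mag
            else:
                flux = mag - spec.shift
            rows.append(
                {
                    "site": spec.site,
                    "forest_type": spec.forest_type,
                    "plot": plot,
                    "chamber_id": chamber,
                    "date": date.date().isoformat(),
                    "week": int(date.isocalendar().week),
                    "flux": flux,
                    "soil_temperature": temp,
                    "wfps": wfps,
                    "inundated": False,
                    "units": spec.units,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stream vials


def generate_stream_sample(
    true_conc: float,
    species: str = "CH4",
    *,
    water_volume: float = 6.0,
    headspace_volume: float = 6.0,
    temperature: float = 298.15,
    lab_pressure: float = 1.0,
    params: SolubilityParams | None = None,
    basis: str = "element",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> VialSample:
    """Vial measurement implied by a known in-stream concentration.

    ``true_conc`` is µg element (or molecule, per ``basis``) L⁻¹.  The
    two-compartment equilibrium x·P·(V_hs/(RT) + kH·V_w) = n_total is
    solved for the headspace mole fraction; Gaussian noise (ppb) is then
    added to emulate the gas-chromatograph measurement.
    """
    if true_conc < 0:
        raise ValueError("true_conc must be >= 0")
    if params is None:
        params = DEFAULT_SOLUBILITY[species]
    rng = _rng(seed, "stream_sample")
    v_w = water_volume / 1000.0
    v_hs = headspace_volume / 1000.0
    conc_molar = true_conc / (mass_per_mole(species, basis) * 1e6)
    n_total = conc_molar * v_w
    kH = henry_constant(params, temperature)
    x = n_total / (lab_pressure * (v_hs / (R_GAS * temperature) + kH * v_w))  # mole fraction
    x_ppb = x * 1e9
    if noise_sd > 0:
        x_ppb = max(x_ppb + rng.normal(0.0, noise_sd), 0.0)
    return VialSample(
        species=species,
        water_volume=water_volume,
        headspace_volume=headspace_volume,
        equilibration_temperature=temperature,
        headspace_mole_fraction=x_ppb,
        lab_pressure=lab_pressure,
        initial_headspace_mole_fraction=0.0,
    )


# ---------------------------------------------------------------------------
# isotope chamber pairs


@dataclass(frozen=True)
class IsotopeBackground:
    """Ambient chamber air at closure: concentration [ppb] and δ values [‰]."""

    c0: float = 330.0
    d15n: float = 6.3
    d18o: float = 44.4
    d15n_alpha: float = 15.0
    d15n_beta: float = -2.0


@dataclass(frozen=True)
class IsotopeSource:
    """Soil-emitted N₂O δ signature [‰]."""

    d15n: float = -20.0
    d18o: float = 20.0
    d15n_alpha: float = -10.0
    d15n_beta: float = -30.0


def generate_isotope_pairs(
    background: IsotopeBackground = IsotopeBackground(),
    source: IsotopeSource = IsotopeSource(),
    added_amounts: tuple[float, ...] = (10.0, 30.0, 31.0, 100.0),
    *,
    noise_sd_delta: float = 0.0,
    seed: int = 0,
) -> list[IsotopePair]:
    """Forward two-pool mixing for a batch of chamber closures.

    ``added_amounts`` are soil-emitted N₂O increments [ppb]; amounts
    below the 31-ppb validity threshold are deliberately included so the
    filter is exercised downstream.
    """
    if any(a < 0 for a in added_amounts):
        raise ValueError("added amounts must be >= 0 ppb")
    rng = _rng(seed, "isotope_pairs")

    def mixed(d_bg: float, d_src: float, a: float, c_end: float) -> float:
        d = (background.c0 * d_bg + a * d_src) / c_end
        if noise_sd_delta > 0:
            d += rng.normal(0.0, noise_sd_delta)
        return d

    pairs = []
    for i, a in enumerate(added_amounts):
        c_end = background.c0 + a
        pairs.append(
            IsotopePair(
                chamber_id=f"sim{i}",
                c_start=background.c0,
                c_end=c_end,
                d15n_start=background.d15n,
                d15n_end=mixed(background.d15n, source.d15n, a, c_end),
                d18o_start=background.d18o,
                d18o_end=mixed(background.d18o, source.d18o, a, c_end),
                d15n_alpha_start=background.d15n_alpha,
                d15n_alpha_end=mixed(background.d15n_alpha, source.d15n_alpha, a, c_end),
                d15n_beta_start=background.d15n_beta,
                d15n_beta_end=mixed(background.d15n_beta, source.d15n_beta, a, c_end),
            )
        )
    return pairs
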