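# Methods

This note records the models implemented in `congoflux`, the defaults
and why they were chosen, the numerical decisions, and what the
synthetic-data generators do and do not emulate.

## Chamber flux model

One closure yields mole fractions x(t) [nmol mol⁻¹] at times t [min]
(canonically 0, 20, 40, 60). The flux is

F = b · n / S, with b the OLS slope of x on t converted to s⁻¹,
n = P·V/(R·T) the chamber's total gas moles (R = 0.08206
L atm K⁻¹ mol⁻¹) and S the soil area. The regression runs on minutes as
recorded and is converted once, to avoid repeated unit juggling.

Decisions where the procedure is genuinely open:

* **Temperature entering n.** Headspace temperature is recorded at each
  sampling point but n = PV/RT needs a single value; the arithmetic
  mean over the closure is used (configurable to the closure-start
  value via `temperature_mode="first"`). For tropical closures the two
  differ by ≲ 1%.
* **Zero-variance series.** A perfectly constant series has an
  undefined R²; it is reported as R² = 0 with `qc_pass=False` and
  `retained=True`. Such closures are genuine zero fluxes and flagging
  rather than discarding them avoids biasing summaries toward high
  fluxes — the same reason no record is ever dropped on low R².
* **QC threshold.** `qc_pass` is the strict test R² > 0.95,
  configurable.
* **Two-point series** get R² = 1 (the fit is exact by construction);
  fluxes from them should be treated with care but are not blocked.
* **Water vapour.** Mole fractions are treated as dry-air values; no
  dilution correction is applied.
* The default geometry is a d = h = 0.30 m cylinder (V = 21.21 L,
  S = 0.0707 m²); floating chambers use the same formula with their own
  volume and, lacking a standard footprint, require an explicit area
  (the static footprint π·0.15² is the default).

Nonlinear (saturating) flux models are out of scope; the synthetic
generator can produce saturating series precisely so tests can show the
linear fit's behaviour on them (R² drops, flux is underestimated).

## Unit conversions

nmol m⁻² s⁻¹ → kg element ha⁻¹ yr⁻¹ multiplies by 10⁻⁹ mol, the element
mass per mole of gas (CH₄-C 12.011 g, N₂O-N 28.014 g, IUPAC 2021), a
365.25-day year (3.15576 × 10⁷ s) and 10 (m²→ha over g→kg). The year
length is configurable; the 365 vs 365.25 d difference (< 0.07%) is far
below reporting precision. No CO₂-equivalent conversion is provided.

## Dissolved gases

A vial holds V_w water and V_hs headspace at temperature T and pressure
P. At equilibrium the measured headspace mole fraction x gives partial
pressure p = x·P, headspace moles p·V_hs/(R·T) and aqueous moles
kH(T)·p·V_w; subtracting any pre-equilibration headspace analyte (zero
for N₂-flushed vials) and dividing by V_w recovers the in-stream
concentration. kH(T) = kH(298.15 K)·exp(Δ_vH·(1/T − 1/298.15)).

Defaults (all configurable, Sander-compilation style, freshwater, zero
salinity): CH₄ kH = 1.4 × 10⁻³ mol L⁻¹ atm⁻¹, Δ_vH = 1750 K; N₂O
kH = 2.4 × 10⁻² mol L⁻¹ atm⁻¹, Δ_vH = 2700 K. Atmospheric mixing ratios
default to 1870 ppb CH₄ and 332 ppb N₂O (circa the late 2010s).
Temperatures outside 263–323 K trigger an extrapolation warning but
still evaluate. Preservation (ZnCl₂) is assumed perfect.

**Mass basis.** Concentrations are reported per litre as µg of element
(C or N) by default. The CH₄ atmospheric-equilibrium reference at 25 °C
evaluates to 0.031 µg C L⁻¹ (commonly quoted as 0.03). For N₂O the
widely quoted equilibrium reference of ~0.36 µg L⁻¹ is **not**
reproducible on an N-mass basis (which gives ≈ 0.22 µg N L⁻¹ at 25 °C)
but is close to the full-molecule 44 g mol⁻¹ basis (≈ 0.35 µg L⁻¹ at
25 °C, higher in cooler water). Both bases are implemented
(`basis="element" | "molecule"`); the element basis is the package
default for consistency with the flux units, and the discrepancy is
surfaced here rather than silently matched.

Gas-transfer velocities and areal evasion fluxes are out of scope;
the package reports concentrations and saturation ratios only.

## N₂O isotopes

The two-source mixing model treats the end-of-closure headspace as a
mixture of background air and soil-emitted N₂O:
δ_flux = (c_end·δ_end − c_start·δ_start)/(c_end − c_start). The
inversion error grows as 1/ΔN₂O, so signatures with ΔN₂O < 31 ppb are
flagged invalid. The boundary is inclusive on the keep side (valid iff
ΔN₂O ≥ 31 ppb), and invalid records are retained with a reason string
so discard counts are auditable.

Site preference is δ¹⁵Nα − δ¹⁵Nβ. Where per-position δ values are
supplied, the flux SP is computed by applying the mixing model per
position and then differencing — the plausible route when only t₁/t₄
pairs exist; bulk-only inputs yield SP = NaN rather than a guess.

Dissolved-phase δ values measured in an equilibrated vial headspace are
corrected with α_eq = R_headspace/R_dissolved = 0.99925 (¹⁵N) and
0.99894 (¹⁸O): δ_dissolved = ((δ_hs/1000 + 1)/α_eq − 1)·1000.

The (δ¹⁵N, δ¹⁸O) map decomposes points relative to a reduction vector
of slope 2.4 (δ¹⁸O enrichment per δ¹⁵N as denitrifiers reduce N₂O to
N₂), anchored by default at the tropospheric N₂O composition
(δ¹⁵N 6.3‰, δ¹⁸O 44.4‰), both configurable. Endmember rectangles for
nitrification/denitrification ship as **non-normative placeholders**;
real applications must supply literature ranges via config. A point in
exactly one rectangle gets that label, overlapping membership is
"ambiguous", otherwise "outside".

## Flux statistics

Soil-gas fluxes are strongly right-skewed, so central tendencies are
geometric means: REML fits of log flux ~ 1 + (1|plot/chamber) +
(1|date), with the nesting encoded as separate plot and plot:chamber
variance components (plot collapses into the intercept when a panel has
a single plot). The back-transformed intercept estimates the geometric
mean (= median under lognormality); the 95% CI is Wald,
exp(β₀ ± 1.96·SE) — the simplest interval consistent with reporting
"geometric mean [95% CI]".

**Negative fluxes.** The log transform of signed fluxes is undefined
and no convention is canonical, so the caller must choose one of three
explicit strategies: `log_positive` (errors on any non-positive value,
naming the offending rows), `negate_log` (for all-negative uptake
panels; the sign is restored on back-transform, so the geometric mean
of an uptake panel is minus the geometric mean of the magnitudes), and
`shifted_log` with a caller-set shift c for mixed-sign panels (the
pipeline's `auto` mode picks c = |min| + 10% of the range and logs it).
Shifted-log estimates are invariant to translating the panel and
adjusting c accordingly.

Driver models fit log flux ~ soil_temperature + wfps + (1|chamber) by
REML; a single-chamber panel reduces to OLS. Effects are reported raw
and as (exp(β) − 1)·100 % change per unit covariate. Constant
covariates are flagged non-estimable and excluded rather than passed to
a singular design. WFPS comes from volumetric water content as
100·vwc/(1 − BD/PD) with particle density 2.65 g cm⁻³.

R² follows the variance-components decomposition: marginal
R² = σ²_fixed/(σ²_fixed + Σσ²_random + σ²_residual) with σ²_fixed the
variance of the fixed-effect linear predictor over the data, and
conditional R² adds the random components to the numerator.

Raw variability summaries: between-chamber statistics are the sample
variance/SD/CV over per-chamber arithmetic means; intra-annual
statistics are the same over per-ISO-week means, pooling weeks across
sampling years.

**Numerics.** Fits use statsmodels' variance-components formulation
(one all-encompassing group) under REML. The default gradient-based
optimizer is unreliable when a variance component sits on the zero
boundary, so fits use derivative-free Powell (verified against lme4 to
5+ significant figures on benchmark panels) with a BFGS fallback;
non-convergence and singular fits (components at zero) are reported via
flags, never silently dropped. A zero-variance response short-circuits
to the exact degenerate solution. Temporal autocorrelation and gap
filling are out of scope.

## Upscaling

Basin flux = Σ w_t · F_t over lowland (w = 0.906), swamp (0.068) and
montane (0.026), with the swamp estimate first composited as
f·inundated + (1−f)·non-inundated. The inundated fraction is not an
observed quantity here; f = 0.5 is the default because it is the single
value that reconciles the published basin-wide CH₄ and N₂O weighted
averages simultaneously — it is an inference, not a measurement, and is
configurable.

CI bounds combine bound-wise (weighted sum of lower bounds; of upper
bounds). Bound-wise combination reproduces the published basin
intervals from the published per-type intervals at 2-decimal rounding
with one exception: the CH₄ upper bound computes to 25.02 from the
printed per-type values against a printed 25.03 — consistent with the
original combination having used unrounded inputs. An
independent-errors quadrature option exists but is off by default,
since the bound-wise scheme is what the published numbers validate.
Report rounding is half-away-from-zero. Uncertainty in the coverage
weights themselves is not modelled.

## Synthetic-data generators

Each generator inverts its analysis stage exactly at zero noise, which
the tests exploit for round-trip checks:

* `generate_chamber_series` — linear accumulation x(t) = x₀ + b·t from
  a target flux, optional exponential saturation (e-folding time τ,
  initial slope preserved), additive Gaussian ppb noise.
* `generate_flux_panel` — log flux = log m + b_plot + b_chamber +
  b_date + β_T·(T − T̄) + β_W·(W − W̄) + ε with independent Gaussian
  effects; covariates uniform over configurable ranges, centred at the
  range midpoint so m stays the median. Sign regimes: positive,
  negative (uptake; magnitudes lognormal), mixed (exp(N) − shift with
  median m, requiring shift > 0 so a shifted-log fit at the same shift
  round-trips). Defaults — 5 chambers, 52 weekly dates, log-scale SDs
  0.4 (chamber), 0.3 (date), 0.5 (residual) — represent a one-year
  weekly campaign at one site with the spatial/temporal/residual
  spread typical of tropical chamber networks.
* `generate_stream_sample` — solves the vial mole balance forward for
  the headspace mole fraction implied by a known dissolved
  concentration, plus Gaussian ppb noise.
* `generate_isotope_pairs` — forward two-pool mixing; default batches
  include sub-threshold additions so the 31-ppb filter is exercised.

RNG streams are derived from the user seed plus a per-generator salt,
so composing generators is reproducible regardless of call order.

**What they do not emulate** — and hence what passing tests do not
show about field data: seasonality and temporal autocorrelation (dates
are exchangeable), correlated covariates (T and WFPS are independent
uniforms), episodic emission events and heavy tails beyond the
lognormal, instrument drift, chamber relocation, leaks or pressure
artefacts, and preservation losses in vials. Parameter-recovery results
therefore validate the estimators under their own assumptions, not the
field campaign's sampling design.

## Simulation sizes

The recovery studies (tests and `scripts/acceptance.py`) use the
campaign design of 5 chambers × 52 dates with 200 Monte-Carlo
replicates per scenario, enough that the mean recovered geometric mean
is estimated to ~1.5% (Monte-Carlo SE) while a full run stays under a
minute on one CPU. The intercept-exponentiation estimator carries a
small positive Jensen bias of roughly exp(SE²/2) − 1 ≈ 2% at this
design size, visible in the recovery output and well inside the
stated 10% recovery tolerance.
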