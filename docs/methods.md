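# Methods

This note documents the science and the numerical choices behind
`wetlandco2`: what is computed, under which assumptions, what the
synthetic world does and does not emulate, and where the genuinely open
design decisions were made.

## 1. Carbonate speciation (`wetlandco2.carbonate`)

Input pair: pH on the NBS scale and total alkalinity (A_T), with in-situ
temperature, practical salinity, phosphate and silicate. Because [H⁺]
is fixed by the measured pH, the system closes without iteration:
non-carbonate alkalinity (borate, water, phosphate, silicate, minus the
free proton and bisulfate terms) is evaluated at that [H⁺] and
subtracted from A_T; the carbonate species partition the remainder via
K₁, K₂; pCO₂ = [CO₂*]/K₀.

**Constant set and pH-scale bookkeeping.** All proton arithmetic is on
the NBS scale, mirroring how the classic spreadsheet tools handle
NBS-measured pH:

| constant | source | native scale | handling |
|---|---|---|---|
| K₀ | Weiss (1974), volumetric coefficients | — | used directly (mol L⁻¹ atm⁻¹) |
| K₁, K₂ | Cai & Wang (1998), estuarine | NBS | used directly |
| K_B | Dickson (1990b) | total | ×fH (fluoride term omitted, <0.2 %) |
| K_W, K_P1..3, K_Si | Millero (1995) / Yao & Millero | SWS | ×fH |
| K_S | Dickson (1990a) | free | proton-term bookkeeping only |

fH(T,S) = 1.2948 − 2.036×10⁻³·T_K + (4.607×10⁻⁴ − 1.475×10⁻⁶·T_K)·S²
(the GEOSECS factor). fH was fitted for seawater; applying it down to
S = 0 follows the established NBS convention rather than physical
activity theory, and only affects the minor alkalinity terms — K₁/K₂,
which control pCO₂, are native NBS. The estuarine K₁/K₂ formulation is
fitted for roughly S 0–40, T 0.2–35 °C; outside that envelope the code
warns and extrapolates (the field practice it reproduces spans S 0–50).

**Concentration basis** is volumetric (µmol L⁻¹) end-to-end. Constants
published per kg of solution are used as per-litre values; the ≤3 %
density discrepancy at S = 35 (≪1 % at the mostly oligohaline sites) is
far below the 5 % oracle tolerance and cancels partially in pCO₂.

Missing nutrients are filled with the campaign averages (PO₄ 2.84,
Si(OH)₄ 141.91 µmol L⁻¹) and flagged (`measured`/`partial`/`filled`).
A sample whose non-carbonate alkalinity exceeds A_T yields an explicit
invalid result carrying per-term diagnostics, never a silent NaN.
Ammonium and sulfide alkalinity are not modelled (not measured inputs);
no pressure corrections (surface samples); only the pH–A_T input pair
is supported.

**Verification route.** No reference carbonate package is available in
the pinned environment, so the test oracle is an independently coded
solver (tests/_oracle.py): it re-types the constant formulations in a
different algebraic form and solves the *full* alkalinity balance for
DIC by bracketed root-finding instead of decomposing carbonate
alkalinity. Frozen literature anchors (freshwater pK₁ = 6.35,
pK₂ = 10.33 at 25 °C; K₀ ≈ 0.0339 mol L⁻¹ atm⁻¹) pin the constants
themselves. Exact self-consistency (A_T reconstructed from the returned
species to <0.01 µmol L⁻¹) is asserted on a T×S×pH×A_T grid.

## 2. Gas exchange (`wetlandco2.gas_exchange`)

F = kₜ·K₀·ΔpCO₂ with the unit contract cm h⁻¹ ×0.24 → m d⁻¹ and
mol L⁻¹ atm⁻¹ ≡ mmol m⁻³ µatm⁻¹, so F is in mmol m⁻² d⁻¹ (positive =
efflux). kₜ = k₆₀₀·(Sc/600)^(−1/2) exactly.

*Schmidt number*: cubic polynomials in T for the fresh (S=0) and marine
(S=35) endmembers with linear interpolation in salinity — not the full
viscosity/diffusivity route. The endmember polynomials reproduce
Sc(20 °C, fresh) = 600 to a fraction of a percent; the operation is
isolated so a full physical route could be swapped in.

*k₆₀₀ parameterizations* are configuration data (`a + b·U₁₀^c`):

- `lake` (default): 2.07 + 0.215·U₁₀^1.7 — Cole & Caraco (1998).
- `small_water_body`: 0.72·U₁₀ — the Crusius & Wanninkhof (2003)
  low-wind linear lake fit, standing in for sheltered small systems
  (the original small-water-body coefficients were not recoverable
  offline); it lies below the lake curve throughout the study wind
  range, as the sensitivity analysis requires qualitatively.
- `ocean`: 0.39·U₁₀²·(660/600)^½ — Wanninkhof (1992); the *long-term*
  coefficient (0.39, not the steady-wind 0.31) because the inputs are
  daily time-ensemble means.

*Wind height adjustment*: neutral logarithmic profile with a constant
drag coefficient 1.3×10⁻³, one step, no stability iteration — daily
mean winds cannot support stability corrections. Station winds are
daily-averaged per station, adjusted to 10 m, then spatially averaged;
a day with no station data propagates as a gap.

Not modelled: chemical enhancement at high pH, bubble-mediated
transfer, cool-skin effects.

## 3. Temporal integration (`wetlandco2.timeseries`)

Daily values of T, S, A_T, pH and nutrients are piecewise-linear
interpolations of the monthly samples; water pCO₂ is recomputed daily
from the interpolated pair (interpolating the measured quantities, not
their nonlinear derivative). Atmospheric pCO₂ and wind enter as daily
ensemble values.

**Hydroperiod gaps are not missing data.** Declared dry intervals split
a site's year into wet segments; interpolation never bridges a dry
interval, days between a segment's last sample and the next segment
carry no value, and no flux is counted on them. Interpolating across a
dry-down would fabricate fluxes that were never observed.

Annual areal flux = Σ daily mmol / 1000 (mol m⁻² y⁻¹); dry days
contribute zero. Descriptive statistics use moment skewness and **raw
(Pearson) kurtosis** (a normal sample reads ≈3, matching how the
field's summary tables are usually printed) and an IQR by linear
interpolation between order statistics; degenerate inputs (n<2,
constant vectors) are flagged, not silently NaN'd.

## 4. Up-scaling (`wetlandco2.upscaling`)

Scenes are single-band NIR reflectance grids (north-up, square pixels;
plain-text ESRI-ASCII I/O; no rasterio in the environment, so no
GeoTIFF). The multi-date series is normalized against a reference scene
with a symmetric line fit on pseudo-invariant features: slope
sign(cov)·√(var_ref/var_scene), intercept through the means. (This is
the geometric-mean / reduced-major-axis estimator — the symmetric fit
commonly labelled "major-axis regression" in the PIF literature.)
Water = NIR < 0.2, strict; nodata is excluded from both classes. Region
area = pixel-center-in-polygon count × pixel area; daily areas by
linear interpolation between scene dates.

Regional transport: arithmetic mean of member-site daily fluxes
(wet sites only — dry sites are excluded from the mean, since only wet
sites were ever sampled) × water area × 12.011×10⁻³ g mmol⁻¹; annual
sums in Gg C y⁻¹. NPP comparison: areal NPP × region area → Gg C y⁻¹
and its ratio to total transport (flagged undefined if transport ≤ 0).

Not modelled: orthorectification, atmospheric correction, cloud
masking, sub-pixel water fractions, detection limits for very small
ponds.

## 5. The synthetic world (`wetlandco2.synthetic`)

One hydrological year (1 March → 28 February) over 11 site archetypes in
four regions: managed mesohaline ponds (mostly under-saturated; one
with steep managed salinity ramps 0↔~46 within ~5 weeks), semi-permanent
oligohaline ponds and a stream (spring rise to 10³–10⁴ µatm, autumn
drawdown to tens of µatm, winter return to super-saturation), and
temporal marshes (wet only spring carry-over + winter re-flood,
persistently super-saturated). Seasonal pCO₂ curves are log-linear
between control points within the observed envelopes (A_T 1800–6000
µmol L⁻¹, implied pCO₂ ~20–8000 µatm); sample pH is obtained by
root-finding so that the emitted (pH, A_T) pair reproduces the target
pCO₂ at the sampled T, S.

Meteorology: daily regional wind is a lognormal AR(1) around a seasonal
cycle (winter–spring storm maxima coupled to the flooding, calm
summer), clipped to 1.3–7.2 m s⁻¹ with median ≈2.5; stations share the
regional signal with multiplicative noise and report at 2 m following
the log profile; hourly values carry a renormalized diurnal cycle so
daily station means are exact. Atmospheric pCO₂ spans 369–398 µatm
(min late winter, max late summer). Scenes flood a disc per region
whose area follows a piecewise-linear seasonal truth curve; water
pixels sit at 0.05–0.15 reflectance, land 0.28–0.55; each non-reference
scene gets a gain (0.85–1.30) and offset (±0.04) distortion that pushes
pixels across the 0.2 threshold until PIF normalization undoes it.

**Noise is analytical only** (pH σ 0.01, A_T 0.3 %, implied-pCO₂
consistency 2 %, nutrients 30 %): the method's premise is that one
monthly spot sample defines the site state, so spatial patchiness
belongs to the unmodelled real world. One global seed drives three
spawned RNG streams (sites, meteorology, scenes), so partial
regeneration is stable and every output is byte-reproducible.

**What a green recovery test establishes — and what it does not.** The
generator provides two closed-form expectations per quantity: the
*truth-curve* integral (the estimand) and the *pipeline expectation* —
the noise-free value of the estimator itself (truth sampled at the
known monthly schedule, exact pH solve, then the pipeline's own
interpolation and integration). Recovery tests compare the full noisy
pipeline against the pipeline expectation (≤5 %); the gap between the
two expectations — the inherent discretization bias of monthly sampling
on a seasonal cycle spanning two orders of magnitude, which undercuts
log-concave maxima — is asserted separately (<10 % per site, typically
5–7 % for the extreme archetypes). The same bias affects the real
field analysis and is irreducible at monthly cadence. Regional recovery
uses |error| / gross-transport-scale (Σ mean|flux|·area): for
non-cancelling regions this equals relative error, and for the
managed-pond region — whose signed total nearly cancels across member
sites, as in the real system — it is the only well-posed denominator.

The world is scaled down for test runtime: 180×180 scenes at 30 m, max
region water area ~8 km² (not hundreds), so transports are Gg-fractions.
Scaling is linear throughout, so none of the tested invariants depend
on it. The generator does not emulate: spatial heterogeneity within a
water body, sub-daily chemistry, cloud cover or sensor mixing, rainfall
events, or inter-annual variability.

## 6. Known limitations

- NBS-scale arithmetic with the GEOSECS fH at low salinity is a
  convention, not activity theory; the 5 % oracle band absorbs it.
- The small-water-body k₆₀₀ stands in for the (unavailable) original
  small-system coefficients; all three coefficient sets are config.
- Monthly sampling biases annual sums low where the seasonal cycle is
  strongly peaked (quantified above).
- Water areas below ~0.05 km² at 30 m pixels carry >5 % quantization
  noise; the synthetic stream region is kept just above that floor.
- The pipeline currently ingests the synthetic world directly;
  CSV-loading external data uses the same frame schemas
  (`samples.csv`, station-hourly meteorology) but no format validation
  beyond the domain-type invariants.
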