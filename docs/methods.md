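# Methods

## Scope and design

`isofe` is a two-box analog of a 3-D isotope-enabled ocean biogeochemistry
model: a seasonally varying surface mixed layer over a *prescribed*
subsurface reservoir, replicated over a small idealized grid of
independent columns (default 8 longitudes × 3 latitude bands:
subpolar / transition / subtropical; the westernmost column of each band
is "coastal"). There is no lateral transport; downstream and advective
effects are deliberately out of scope, which matters for interpretation
(see *Limitations*).

Every iron reservoir is an exact pair of prognostic tracers (⁵⁶Fe, ⁵⁴Fe);
δ⁵⁶Fe is derived, never stored, against a fixed reference ratio
R_std = 15.698 (IRMM-014). Because δ is a ratio of ratios, all ‰-level
results are invariant to the choice of R_std.

## Process formulation

State per column: dissolved Fe (dFe), nano- and diatom-phytoplankton Fe
and C, small and large particulate Fe, one macronutrient N, mixed-layer
depth (MLD). Units: concentrations µmol m⁻³ (Fe, N), mmol C m⁻³
(biomass), fluxes µmol m⁻² yr⁻¹ at the interface, converted to
volumetric rates by division by MLD.

* **Sources.** Aerosol deposition (dust / anthropogenic / wildfire) from
  the synthetic generator; constant sediment, river and hydrothermal
  inputs. Each source enters dFe at its endmember: dust +0.09 ‰,
  anthropogenic −1.6 ‰ (−4 ‰ sensitivity case), wildfire −0.5 ‰,
  hydrothermal −0.5 ‰, river 0 ‰, sediment −1 ‰ for source depths
  ≤ 400 m and +0.09 ‰ below (step rule; the boundary depth belongs to the
  shallow branch). The sediment flux is gated by min(1, MLD/z_sed) so
  deep winter mixing feels the shelf source most strongly.
* **Speciation.** Fixed total ligand L_T = 1.2 µmol m⁻³ with conditional
  stability K = 100 m³ µmol⁻¹; the free/complexed split solves the
  speciation quadratic exactly (stable root). The isotopic partition
  solves the two-by-two mass balance R_complexed = α_ligand·R_free with
  α_ligand = 1.0006 — no ‰-linearisation — so recombination is exact.
  The fixed ligand pool and the two fixed-rate particle classes stand in
  for the host model's dynamic ligands and variable particle reactivity.
* **Biology.** Quota model per class: growth
  µ = µ_max·light·min(N/(N+k_N), (Q−Q_min)/(Q_max−Q_min)) with
  Q = Fe:C quota in [Q_min, Q_max] = [0.0025, 0.04] µmol Fe (mmol C)⁻¹;
  Fe uptake V = V_max·dFe/(dFe+k_Fe)·(1−Q/Q_max) continues while growth
  is N- or light-limited (*luxury uptake*) until the quota saturates.
  Uptake draws on total dFe with α_uptake = 0.9995 (instantaneous
  flux-ratio convention R_flux = α·R_pool; a per-class α is configurable
  but identical by default). Mortality (linear + quadratic aggregation)
  routes nano → small and diatom → large particles with no fractionation;
  a small seed-stock floor (10⁻³ mmol C m⁻³) prevents extinction.
* **Abiotic removal.** Scavenging k_scav·(particulate Fe)·free-dFe removes
  the *free* (isotopically light) sub-pool; colloidal pumping
  k_coll·complexed-dFe removes the *complexed* (heavy) sub-pool. Both
  carry their sub-pool's δ with no additional kinetic α — the
  fractionation lives entirely in the complexation equilibrium.
  Remineralization returns particulate Fe to dFe at particle δ; export
  removes sinking particles.
* **Physics.** Climatological (exactly periodic) MLD and light cycles per
  latitude archetype; skewed sinusoid with a deep mid-February maximum
  (subpolar 120/25 m, transition 95/35 m, subtropical 70/45 m). On
  deepening, discrete entrainment mixes in subsurface water (dFe at the
  reservoir signature, N, nothing else); shoaling detrains without
  changing concentrations. The subsurface reservoir's base δ⁵⁶Fe is 0 ‰
  and a dust-dissolution increment (30 % of the column's dust Fe,
  1-yr residence over a 200-m layer) is added *at the dust endmember*: in
  the 3-D host the subsurface signature is generated from the same
  (possibly muted) sources, so tagging the increment keeps endmember
  muting meaningful below the mixed layer.

## Numerics

Forward Euler, dt = 1 day, 365-day no-leap calendar; monthly physics
interpolated linearly to days, deposition held constant within each month
(preserves monthly flux budgets). Sinks are limited per pool *and per
isotope* by a proportional factor so no tracer goes negative; when a pool
is fully drained the removed material carries the pool's δ by mass
balance (the same clip rule as `fractionated_flux`). Entrainment and
detrainment are discrete inventory-conserving mixes. Per-pool, per-isotope
budgets close to ≈10⁻¹⁴ relative over a 35-year run (asserted at 10⁻¹⁰).

Step-doubling shows clean first-order convergence (error ratio ≈ 2 per
halving); the absolute dt = 1 d sensitivity of year-end dFe is at the
percent level because bloom timing is the stiff component. The
closed-form Rayleigh distillation is kept as an independent oracle: a
closed uptake-only column reproduces it within 10⁻³ ‰ down to 90 %
drawdown when the per-step removal is a fraction of a percent.

δ output is computed from monthly-mean tracer pairs, so the reported
monthly δ⁵⁶Fe_diss is exactly the δ of the monthly-mean pool.

## Synthetic forcing: what it emulates, what it does not

The generator reproduces the *statistical structure* of the study
conditions, not any observed field: a dust-dominated west→east deposition
gradient (annual means 45 → 3 µmol Fe m⁻² yr⁻¹), anthropogenic iron
concentrated in the west (20 → 2; ≈30 % of total deposition at the
western boundary, with a weaker eastward decay than dust so its *share*
grows eastward), and a small wildfire term (0.4, enhanced to 3.0 in the
south-west; late-summer peak). Dust carries a spring maximum,
anthropogenic a weak winter maximum. Emission shares are dust 0.95 /
anthropogenic 0.035 / wildfire 0.015; solubility differences are implicit
in the deposited-dFe magnitudes. History: zero anthropogenic input before
1880, a linear ramp to 1980, then monthly varying fields
(climatology × mean-one lognormal noise, σ = 0.2, seeded). The spin-up
era (1780–1979) uses the noise-free climatology for natural sources — the
expectation of the 1980–2014 mean — so the pre-industrial forcing is
identical for every seed.

Flux magnitudes are scenario choices pinned to the share constraints
(≈30 % anthropogenic in the west, <20 % wildfire away from the
south-west, 95 % dust at emission); they are not observed values. Band
subsurface conditions (dFe 0.25/0.30/0.55 µmol m⁻³; N 12 000/8 000/1 600
µmol m⁻³) are chosen so the grid spans the four response regimes: an
Fe-limited high-/low-productivity pair (subpolar and eastern transition),
a nutrient-replete high-productivity west-transition column, and a
nitrogen-limited subtropical band. Passing sign tests therefore show the
*mechanisms* behave correctly under these archetypal conditions; they are
not a validation against ocean observations.

## Experiments and attribution

Eleven-run default suite: standard; no-anthro; anthro endmember −4 ‰;
α_uptake = 1; α_ligand = 1; and one endmember-muted (0 ‰, flux untouched)
run per source. Muting and α overrides apply from the start of spin-up so
every counterfactual is fully equilibrated. A source's contribution to
δ⁵⁶Fe_diss is δ_standard − δ_muted; fractionation contributions use the
α = 1 runs; the residual is reported, never redistributed. The
"fractionation share" of the anthropogenic δ decrease uses the run pair
with *both* α set to 1 as the endmember-only pathway (one-at-a-time
variants are available as diagnostics).

Attribution is exactly additive only to first order in δ/1000: with
realistic endmembers (≈1 ‰) the cross terms floor the residual near
10⁻⁴ ‰, which is why the strict 10⁻⁶ ‰ additivity check runs in a
configuration with endmembers scaled into the linear regime, while the
default configuration is checked against the looser 0.05 ‰ (full) and
0.02 ‰ (hydrothermal-excluded) bounds.

## Regime classification

A column is *Fe-limited* when iron is the most limiting factor (argmin of
the quota, nutrient and light terms of the model itself) in ≥ 50 % of
growing-season months (light index ≥ 0.5), over the final 5 simulated
years; *high-productivity* when its growing-season PP exceeds the median
across columns (relative default; absolute override available). The 2×2
rule yields cases 1–4. The luxury-uptake index is the growing-season
ΔFe-uptake per unit ΔPP with a 10⁻³ mmol C m⁻³ d⁻¹ floor. The
"weak/hatched" flag marks columns whose |ΔPP| is confined to the top
productivity quartile of months.

## Known limitations

* **No lateral transport.** Each column's response is set by its local
  deposition. In the real ocean, remote low-productivity Fe-limited
  (case 4) provinces still receive substantial transported anthropogenic
  iron; here they coincide with the weakest deposition, so the expected
  "largest δ⁵⁶Fe decrease in case 4" ordering does not emerge — case 3
  and the subtropics show slightly larger decreases. All other elements
  of the response matrix (inventory, production, sign and luxury-uptake
  structure) hold.
* The subsurface is prescribed, so feedbacks of surface export on
  subsurface dFe/δ are absent; sediment supply is a fixed coastal flux.
* Fixed ligands, two fixed-rate particle classes, no zooplankton, no
  nitrogen fixation, single macronutrient.
* The spin-up cannot be exactly periodic under the anthropogenic ramp
  (the ramp itself trends ≈1 % yr⁻¹ near 1980); periodicity to 10⁻³ is
  demonstrated for the natural (anthro-off) configuration, and the
  standard spin-up reports its raw year-over-year diagnostic.
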