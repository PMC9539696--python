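# isofe

A desk-scale, seasonal mixed-layer column model of the surface-ocean
dissolved-iron (dFe) cycle that carries **paired ⁵⁶Fe/⁵⁴Fe isotope tracers**
through every iron reservoir, built to study how **anthropogenic aerosol
iron** imprints on surface-ocean productivity and on the dissolved iron
isotope signature δ⁵⁶Fe_diss.

## Who this is for

Marine biogeochemists and isotope geochemists who want to explore the
attribution logic of iron-isotope tracer modelling — which external sources
(desert dust, anthropogenic combustion, wildfire, sediments, rivers,
hydrothermal) and which internal fractionating processes (phytoplankton
uptake, organic complexation) control δ⁵⁶Fe_diss — without running a 3-D
ocean model. The package replaces the 3-D host with a grid of independent
mixed-layer columns over a prescribed subsurface, and replaces simulated
atmospheric deposition with a seeded synthetic generator; downstream
(advective) effects are explicitly out of scope.

## The model

Every iron reservoir *X* holds two prognostic tracers (⁵⁶X, ⁵⁴X); the
signature is always derived:

    δ⁵⁶Fe = 1000 · ( (⁵⁶X/⁵⁴X) / R_std − 1 ),   R_std = 15.698 (IRRM-014)

Five iron pools per column — dissolved Fe, nano- and diatom-phytoplankton
Fe, small and large particulate Fe — plus phytoplankton carbon and one
macronutrient. Per daily time step:

* external dFe sources enter at their endmember δ⁵⁶Fe: dust +0.09 ‰,
  anthropogenic −1.6 ‰ (−4 ‰ sensitivity), wildfire −0.5 ‰, hydrothermal
  −0.5 ‰, river 0 ‰, sediment −1 ‰ above 400 m (crustal below);
* ligand speciation splits dFe into free and complexed pools (quadratic
  equilibrium, fixed ligand), partitioned isotopically with α_ligand =
  1.0006 (complexed Fe heavy);
* quota-based growth with **luxury Fe uptake** (uptake proceeds toward the
  maximum quota even when growth is N- or light-limited), fractionating
  with α_uptake = 0.9995 (light Fe removed, residual dFe driven heavy);
* scavenging removes free (light) dFe, colloidal pumping removes complexed
  (heavy) dFe; mortality, remineralization and export close the cycle;
* the seasonal mixed-layer cycle entrains subsurface dFe and nutrient in
  winter.

The experiment harness reruns history (1780–2014; 200-year spin-up with a
linear anthropogenic ramp 1880–1980) under counterfactuals — anthropogenic
deposition off, each endmember muted to 0 ‰, each α set to 1, a −4 ‰
anthropogenic endmember — and differences the runs to attribute
δ⁵⁶Fe_diss to sources and processes, and to classify each column into the
four-case response matrix (Fe-limited × productivity).

## Worked example

```python
from isofe.column_model import build_scenario
from isofe.experiments import ExperimentSpec, run_experiment, anthro_impact
from isofe.forcing_synth import SOURCES

scenario = build_scenario(seed=1)          # 24 columns, 3 latitude bands
standard = run_experiment(scenario, ExperimentSpec("standard"))
no_anthro = run_experiment(scenario, ExperimentSpec(
    "no-anthro", sources_on={s: s != "anthro" for s in SOURCES}))
impact = anthro_impact(standard, no_anthro)

col = 1   # north-west subpolar, Fe-limited archetype
print(float(standard.delta_dfe.sel(column=col).mean()))
print(float(impact.d_delta.sel(column=col).mean()))
print(float(impact.d_pp.sel(column=col, time=slice(2014, 2015)).max()))
```

prints (seed 1):

```
0.16949229214347786
-0.38122482088806237
0.16939118617843762
```

i.e. the Fe-limited column's dissolved pool averages +0.17 ‰ (uptake
fractionation keeps it heavy despite light sources), anthropogenic iron
lowers δ⁵⁶Fe_diss by ≈ 0.38 ‰ on average, and it boosts the 2014 summer
primary-production peak by ≈ 0.17 mmol C m⁻³ d⁻¹.

The same workflow is scriptable from the shell:

```bash
isofe --config run.yaml suite          # all 11 experiments -> NetCDF
isofe --config run.yaml suite attribute
isofe --config run.yaml regimes classify
isofe --config run.yaml report
```

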