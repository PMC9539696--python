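"""Seasonal mixed-layer iron-cycle column model with paired isotope tracers.

The model is a two-box analog of a 3-D biogeochemical host: a seasonally
varying mixed layer over a prescribed subsurface reservoir.  Five iron
reservoirs each carry paired ⁵⁶Fe/⁵⁴Fe tracers — dissolved Fe, nano- and
diatom phytoplankton Fe, small and large particulate Fe — alongside two
phytoplankton carbon pools and one macronutrient.

Processes per daily time step
-----------------------------
* external dFe sources at their endmember δ⁵⁶Fe: aerosol deposition
  (dust / anthropogenic / wildfire), sediment (gated by how deep the mixed
  layer reaches toward the sediment source), river, hydrothermal;
* entrainment of subsurface water on mixed-layer deepening (detrainment on
  shoaling leaves concentrations unchanged);
* quota-based phytoplankton growth and *luxury* Fe uptake: Fe uptake
  continues toward the maximum quota Q_max even when growth is nitrogen-
  or light-limited; uptake fractionates with α_uptake (light Fe removed);
* ligand speciation (quadratic equilibrium) splitting dFe into free and
  complexed sub-pools, isotopically partitioned with α_ligand (complexed
  Fe heavy);
* scavenging of *free* dFe onto particles (removes light Fe) and
  colloidal pumping of *complexed* dFe (removes heavy Fe), each carrying
  its sub-pool's δ with no extra kinetic fractionation;
* linear + quadratic phytoplankton mortality routing Fe and C to the two
  particle classes without fractionation; remineralization of particulate
  Fe back to dFe at particle δ; export of sinking particles.

Integration is forward Euler (1 day) with a positivity-preserving
proportional sink limiter applied per pool and per isotope, so mass and
both isotopes are conserved to rounding over arbitrary windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from . import _calendar as cal
from .isotope_algebra import (
    R_STD,
    FractionationFactors,
    IsotopePool,
    _partition_fe54_free,
    heavy_fraction,
)
from .forcing_synth import (
    AEROSOL_SOURCES,
    SOURCES,
    BoundaryConditions,
    DepositionSeries,
    ForcingSeries,
    Grid,
    ScenarioParams,
    grid_physics,
    make_grid,
    scenario_boundaries,
    sediment_delta,
    synth_deposition,
)

__all__ = [
    "ModelParams",
    "RunSettings",
    "ColumnState",
    "FluxSet",
    "Scenario",
    "build_scenario",
    "ligand_speciation",
    "uptake_rate",
    "compute_tendencies",
    "step",
    "initial_state",
    "spinup",
    "run",
]

CLASSES = ("nano", "diatom")
FE_POOLS = ("dfe", "phyto_nano", "phyto_diatom", "part_small", "part_large")
LIMITATION_CODES = {"Fe": 0, "N": 1, "light": 2}


class StateError(ValueError):
    """Invalid or numerically broken model state."""


@dataclass
class ModelParams:
    """Biogeochemical parameters of the mixed-layer iron cycle.

    Units: rates d⁻¹ unless noted, concentrations µmol m⁻³, biomass
    mmol C m⁻³, quotas µmol Fe (mmol C)⁻¹.
    """

    fractionation: FractionationFactors = field(default_factory=FractionationFactors)
    r_std: float = R_STD

    # ligand speciation (fixed total ligand + conditional stability)
    ligand_lt: float = 1.2          # µmol m⁻³
    ligand_k: float = 100.0         # m³ µmol⁻¹

    # phytoplankton (nano, diatom)
    mu_max: tuple = (1.0, 1.4)      # d⁻¹ maximum growth
    k_n: float = 500.0              # µmol m⁻³ macronutrient half-saturation
    k_fe: tuple = (0.12, 0.20)      # µmol m⁻³ dFe half-saturation for uptake
    q_min: float = 0.0025           # subsistence Fe quota
    q_max: float = 0.04             # maximum (luxury) Fe quota
    v_max: tuple = (0.05, 0.07)     # µmol Fe (mmol C)⁻¹ d⁻¹ max uptake
    mortality: float = 0.05         # d⁻¹ linear loss
    aggregation: float = 0.10       # (mmol C m⁻³)⁻¹ d⁻¹ quadratic loss
    c_min: float = 1e-3             # mmol C m⁻³ seed stock floor
    r_nc: float = 151.0             # µmol N (mmol C)⁻¹ uptake stoichiometry
    n_remin_frac: float = 0.7       # mortality N recycled to the dissolved pool

    # abiotic Fe cycling
    k_scav: float = 2.0             # (µmol particulate-Fe m⁻³)⁻¹ d⁻¹, on free dFe
    k_coll: float = 0.01            # d⁻¹ colloidal pumping of complexed dFe
    remin_small: float = 0.08       # d⁻¹
    remin_large: float = 0.03       # d⁻¹
    export_small: float = 0.02      # d⁻¹
    export_large: float = 0.12      # d⁻¹

    # subsurface coupling
    subsurface_thickness: float = 200.0  # m, for the dust-dissolution increment
    subsurface_residence_yr: float = 1.0

    dt_days: float = 1.0
    spinup_tolerance: float = 1e-3

    def validate(self) -> None:
        scalars = ("ligand_lt", "ligand_k", "k_n", "q_min", "q_max", "mortality",
                   "aggregation", "c_min", "r_nc", "k_scav", "k_coll",
                   "remin_small", "remin_large", "export_small", "export_large")
        for name in scalars:
            if getattr(self, name) < 0:
                raise StateError(f"parameter {name} must be non-negative")
        if self.q_min >= self.q_max:
            raise StateError("q_min must be smaller than q_max")
        if self.dt_days <= 0:
            raise StateError("dt must be positive")


@dataclass
class RunSettings:
    """Per-experiment switches: source on/off, endmember δ and α overrides."""

    sources_on: dict = field(default_factory=lambda: {s: True for s in SOURCES})
    endmember_overrides: dict = field(default_factory=dict)
    alpha_uptake: float | None = None     # None -> ModelParams value
    alpha_ligand: float | None = None

    def validate(self) -> None:
        for s in list(self.sources_on) + list(self.endmember_overrides):
            if s not in SOURCES:
                raise StateError(f"unknown Fe source {s!r}")

    def resolved_alphas(self, params: ModelParams) -> tuple:
        au = params.fractionation.alpha_uptake if self.alpha_uptake is None else self.alpha_uptake
        al = params.fractionation.alpha_ligand if self.alpha_ligand is None else self.alpha_ligand
        if au <= 0 or al <= 0:
            raise StateError("fractionation factors must be positive")
        return au, al

    def on(self, source: str) -> bool:
        return bool(self.sources_on.get(source, True))


@dataclass
class ColumnState:
    """Mixed-layer state, vectorized over columns (all arrays shape (n,))."""

    dfe: IsotopePool
    phyto_fe_nano: IsotopePool
    phyto_fe_diatom: IsotopePool
    pfe_small: IsotopePool
    pfe_large: IsotopePool
    phyto_c_nano: np.ndarray
    phyto_c_diatom: np.ndarray
    n: np.ndarray
    mld: np.ndarray
    day: int  # day index from 1780-01-01 (no-leap calendar)

    def copy(self) -> "ColumnState":
        return ColumnState(
            self.dfe.copy(), self.phyto_fe_nano.copy(), self.phyto_fe_diatom.copy(),
            self.pfe_small.copy(), self.pfe_large.copy(),
            np.array(self.phyto_c_nano, copy=True), np.array(self.phyto_c_diatom, copy=True),
            np.array(self.n, copy=True), np.array(self.mld, copy=True), self.day)

    def fe_pools(self) -> dict:
        return {"dfe": self.dfe, "phyto_nano": self.phyto_fe_nano,
                "phyto_diatom": self.phyto_fe_diatom,
                "part_small": self.pfe_small, "part_large": self.pfe_large}

    def fe_inventory(self) -> tuple:
        """Per-isotope mixed-layer Fe inventory (µmol m⁻²), summed over pools."""
        i56 = sum(np.asarray(p.fe56) for p in self.fe_pools().values()) * self.mld
        i54 = sum(np.asarray(p.fe54) for p in self.fe_pools().values()) * self.mld
        return i56, i54

    def validate(self, params: ModelParams | None = None) -> None:
        for name, p in self.fe_pools().items():
            for comp, v in (("fe56", p.fe56), ("fe54", p.fe54)):
                v = np.asarray(v)
                if not np.all(np.isfinite(v)):
                    raise StateError(f"non-finite {comp} in pool {name!r}")
                if np.any(v < 0):
                    raise StateError(f"negative {comp} in pool {name!r}")
        for name in ("phyto_c_nano", "phyto_c_diatom", "n", "mld"):
            v = np.asarray(getattr(self, name))
            if not np.all(np.isfinite(v)):
                raise StateError(f"non-finite values in {name!r}")
            if np.any(v < 0):
                raise StateError(f"negative values in {name!r}")
        if np.any(np.asarray(self.mld) <= 0):
            raise StateError("mixed-layer depth must be positive")


@dataclass
class FluxSet:
    """Named per-process fluxes (µmol Fe m⁻³ d⁻¹ unless noted).

    Iron fluxes are :class:`IsotopePool` pairs whose components sum to the
    process total exactly; carbon/nitrogen fluxes are plain arrays.
    """

    deposition: dict          # source -> IsotopePool (volumetric)
    sediment: IsotopePool
    river: IsotopePool
    hydrothermal: IsotopePool
    uptake: dict              # class -> IsotopePool
    scavenging: IsotopePool
    colloidal: IsotopePool
    remin_small: IsotopePool
    remin_large: IsotopePool
    export_small: IsotopePool
    export_large: IsotopePool
    mortality_fe: dict        # class -> IsotopePool
    entrainment_dfe: IsotopePool   # diagnostic rate (µmol m⁻³ d⁻¹)
    growth_c: dict            # class -> mmol C m⁻³ d⁻¹
    mortality_c: dict
    n_uptake: np.ndarray
    n_remin: np.ndarray
    limitation_terms: dict    # 'Fe'/'N'/'light' -> dimensionless per column


# ---------------------------------------------------------------------------
# elementary process laws


def ligand_speciation(dfe_total, l_t: float, k: float):
    """Free/complexed split of dFe for a fixed ligand pool.

    Solves K·[Fe′]·[L′] = [FeL] with [Fe′] + [FeL] = dFe and
    [L′] + [FeL] = L_T via the numerically stable root of the quadratic.
    Returns ``(free, complexed)``; their sum is the input to rounding.
    """
    t = np.asarray(dfe_total, dtype=float)
    if k <= 0 or l_t <= 0:
        out = (t, np.zeros_like(t))
        return (float(out[0]), 0.0) if t.ndim == 0 else out
    b = t + l_t + 1.0 / k
    fel = 2.0 * t * l_t / (b + np.sqrt(b * b - 4.0 * t * l_t))
    fel = np.minimum(fel, t)
    free = t - fel
    if t.ndim == 0:
        return float(free), float(fel)
    return free, fel


def uptake_rate(state: ColumnState, light, params: ModelParams, cls: str):
    """Fe-uptake and C-growth rates for one phytoplankton class.

    Growth: µ_max · light · min(N Monod, Droop quota term) · biomass.
    Fe uptake: V_max · dFe Monod · (1 − Q/Q_max) · biomass — "luxury"
    uptake proceeds toward Q_max regardless of what limits growth.
    Returns ``(fe_uptake_total, c_growth)`` in µmol Fe m⁻³ d⁻¹ and
    mmol C m⁻³ d⁻¹.
    """
    i = CLASSES.index(cls)
    c = np.asarray(state.phyto_c_nano if i == 0 else state.phyto_c_diatom, dtype=float)
    pfe = state.phyto_fe_nano if i == 0 else state.phyto_fe_diatom
    dfe_t = np.asarray(state.dfe.total, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(c > 0, np.asarray(pfe.total) / np.where(c > 0, c, 1.0), params.q_min)
    q_lim = np.clip((q - params.q_min) / (params.q_max - params.q_min), 0.0, 1.0)
    n_lim = state.n / (state.n + params.k_n)
    growth = params.mu_max[i] * np.asarray(light) * np.minimum(n_lim, q_lim) * c
    fe_monod = dfe_t / (dfe_t + params.k_fe[i])
    headroom = np.clip(1.0 - q / params.q_max, 0.0, 1.0)
    fe_up = params.v_max[i] * fe_monod * headroom * c
    return fe_up, growth


# ---------------------------------------------------------------------------
# per-step flux assembly (single code path used by both `step` and the
# fast era integrator)


def _split_source(total_rate, p56):
    """Isotope pair of an external source flux at a fixed heavy fraction."""
    f56 = total_rate * p56
    return f56, total_rate - f56


def _split_alpha(total_amount, fe56, fe54, alpha):
    """Per-isotope split of a withdrawal with flux ratio α·R_pool (clipped)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        r_flux = alpha * fe56 / np.where(fe54 > 0, fe54, 1.0)
        f54 = np.where(fe54 > 0, total_amount / (1.0 + r_flux), 0.0)
    f54 = np.minimum(f54, fe54)
    f56 = total_amount - f54
    f56 = np.minimum(f56, fe56)
    return f56, total_amount - f56


def _split_pool(total_amount, fe56, fe54):
    """Non-fractionating withdrawal at the pool's own ratio."""
    tot = fe56 + fe54
    with np.errstate(divide="ignore", invalid="ignore"):
        f56 = np.where(tot > 0, total_amount * fe56 / np.where(tot > 0, tot, 1.0), 0.0)
    return f56, total_amount - f56


def compute_tendencies(state: ColumnState, light, areal_sources: dict,
                       sub_dfe_conc56, sub_dfe_conc54, dmld_dt,
                       params: ModelParams, settings: RunSettings | None = None,
                       p56_sources: dict | None = None) -> FluxSet:
    """Assemble every process flux for the current state.

    ``areal_sources`` maps source name → areal flux (µmol m⁻² d⁻¹, already
    gated/switched); ``p56_sources`` maps source name → ⁵⁶Fe mass fraction
    of that source's endmember.  Division by the current MLD converts
    areal fluxes to volumetric rates.  Entrainment is reported as a
    diagnostic rate for MLD deepening at ``dmld_dt`` (m d⁻¹).
    """
    state.validate(params)
    settings = settings or RunSettings()
    alpha_u, alpha_l = settings.resolved_alphas(params)
    if p56_sources is None:
        p56_sources = resolve_source_fractions(params, settings)

    mld = np.asarray(state.mld, dtype=float)
    dep = {}
    for s in AEROSOL_SOURCES:
        f56, f54 = _split_source(np.asarray(areal_sources.get(s, 0.0)) / mld, p56_sources[s])
        dep[s] = IsotopePool(f56, f54)
    sed = IsotopePool(*_split_source(np.asarray(areal_sources.get("sediment", 0.0)) / mld,
                                     p56_sources["sediment"]))
    riv = IsotopePool(*_split_source(np.asarray(areal_sources.get("river", 0.0)) / mld,
                                     p56_sources["river"]))
    hyd = IsotopePool(*_split_source(np.asarray(areal_sources.get("hydrothermal", 0.0)) / mld,
                                     p56_sources["hydrothermal"]))

    dfe56 = np.asarray(state.dfe.fe56, dtype=float)
    dfe54 = np.asarray(state.dfe.fe54, dtype=float)
    dfe_t = dfe56 + dfe54

    # speciation and its isotope partition
    free_t, comp_t = ligand_speciation(dfe_t, params.ligand_lt, params.ligand_k)
    free54 = _partition_fe54_free(dfe56, dfe54, np.asarray(free_t), alpha_l)
    free56 = np.asarray(free_t) - free54
    comp56 = dfe56 - free56
    comp54 = dfe54 - free54

    uptake, growth_c, mort_fe, mort_c = {}, {}, {}, {}
    lim_fe_num = np.zeros_like(dfe_t)
    lim_fe_den = np.zeros_like(dfe_t)
    n_lim = state.n / (state.n + params.k_n)
    for i, cls in enumerate(CLASSES):
        c = np.asarray(state.phyto_c_nano if i == 0 else state.phyto_c_diatom, dtype=float)
        pfe = state.phyto_fe_nano if i == 0 else state.phyto_fe_diatom
        fe_up, growth = uptake_rate(state, light, params, cls)
        fe_up = np.minimum(
            fe_up, np.maximum(params.q_max * c - np.asarray(pfe.total), 0.0)
            / params.dt_days)
        u56, u54 = _split_alpha(fe_up, dfe56, dfe54, alpha_u)
        uptake[cls] = IsotopePool(u56, u54)
        # growth may not dilute the quota below Q_min within a step
        growth_c[cls] = np.minimum(
            growth, np.maximum(np.asarray(pfe.total) / params.q_min - c, 0.0)
            / params.dt_days)
        m_spec = params.mortality + params.aggregation * c
        mort_c[cls] = m_spec * c
        mf56, mf54 = m_spec * np.asarray(pfe.fe56), m_spec * np.asarray(pfe.fe54)
        mort_fe[cls] = IsotopePool(mf56, mf54)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(c > 0, np.asarray(pfe.total) / np.where(c > 0, c, 1.0), params.q_min)
        q_lim = np.clip((q - params.q_min) / (params.q_max - params.q_min), 0.0, 1.0)
        lim_fe_num = lim_fe_num + q_lim * c
        lim_fe_den = lim_fe_den + c

    pfe_tot = np.asarray(state.pfe_small.total) + np.asarray(state.pfe_large.total)
    scav_t = params.k_scav * pfe_tot * free_t
    scav = IsotopePool(*_split_pool(scav_t, free56, free54))
    coll_t = params.k_coll * comp_t
    coll = IsotopePool(*_split_pool(coll_t, comp56, comp54))

    rs = IsotopePool(params.remin_small * np.asarray(state.pfe_small.fe56),
                     params.remin_small * np.asarray(state.pfe_small.fe54))
    rl = IsotopePool(params.remin_large * np.asarray(state.pfe_large.fe56),
                     params.remin_large * np.asarray(state.pfe_large.fe54))
    es = IsotopePool(params.export_small * np.asarray(state.pfe_small.fe56),
                     params.export_small * np.asarray(state.pfe_small.fe54))
    el = IsotopePool(params.export_large * np.asarray(state.pfe_large.fe56),
                     params.export_large * np.asarray(state.pfe_large.fe54))

    n_up = params.r_nc * (growth_c["nano"] + growth_c["diatom"])
    n_rm = params.n_remin_frac * params.r_nc * (mort_c["nano"] + mort_c["diatom"])

    dd = np.maximum(np.asarray(dmld_dt, dtype=float), 0.0) / mld
    ent = IsotopePool(dd * (np.asarray(sub_dfe_conc56) - dfe56),
                      dd * (np.asarray(sub_dfe_conc54) - dfe54))

    with np.errstate(invalid="ignore"):
        lim_fe = np.where(lim_fe_den > 0, lim_fe_num / np.where(lim_fe_den > 0, lim_fe_den, 1.0), 1.0)
    return FluxSet(
        deposition=dep, sediment=sed, river=riv, hydrothermal=hyd,
        uptake=uptake, scavenging=scav, colloidal=coll,
        remin_small=rs, remin_large=rl, export_small=es, export_large=el,
        mortality_fe=mort_fe, entrainment_dfe=ent,
        growth_c=growth_c, mortality_c=mort_c, n_uptake=n_up, n_remin=n_rm,
        limitation_terms={"Fe": lim_fe, "N": n_lim,
                          "light": np.broadcast_to(np.asarray(light, dtype=float), dfe_t.shape)},
    )


def resolve_source_fractions(params: ModelParams, settings: RunSettings,
                             boundary: BoundaryConditions | None = None,
                             scenario_endmembers: dict | None = None) -> dict:
    """⁵⁶Fe mass fraction per source after endmember overrides."""
    base = {"dust": 0.09, "anthro": -1.6, "wildfire": -0.5,
            "river": 0.0, "hydrothermal": -0.5, "sediment": -1.0}
    if scenario_endmembers:
        base.update(scenario_endmembers)
    if boundary is not None:
        base["sediment"] = boundary.sediment_delta
        base["river"] = boundary.river_delta
        base["hydrothermal"] = boundary.hydrothermal_delta
    base.update(settings.endmember_overrides)
    return {s: heavy_fraction(base[s], params.r_std) for s in SOURCES}


def step(state: ColumnState, light, areal_sources: dict, sub56, sub54,
         mld_next, params: ModelParams, settings: RunSettings | None = None,
         dt: float | None = None, sub_n=None) -> ColumnState:
    """Advance one forward-Euler step of length ``dt`` days.

    Process fluxes are evaluated at the current state and MLD, sinks are
    limited per pool and per isotope so nothing goes negative (scaling a
    pool's sink fluxes proportionally, which preserves the δ of removed
    material when a pool is fully drained), then the mixed layer is
    deepened/shoaled to ``mld_next`` with discrete entrainment/
    detrainment.
    """
    dt = params.dt_days if dt is None else dt
    if dt <= 0:
        raise StateError("dt must be positive")
    settings = settings or RunSettings()
    fl = compute_tendencies(state, light, areal_sources, sub56, sub54, 0.0,
                            params, settings)
    new = _apply_fluxes(state, fl, dt, params)
    _mix_to_mld(new, np.asarray(mld_next, dtype=float), sub56, sub54,
                sub_n=sub_n)
    new.day = state.day + 1
    new.validate(params)
    return new


def _limit(pool56, pool54, sinks56, sinks54, dt):
    """Per-isotope proportional sink limiter; returns the two scale factors."""
    tot56 = sum(sinks56)
    tot54 = sum(sinks54)
    with np.errstate(divide="ignore", invalid="ignore"):
        s56 = np.where(tot56 * dt > pool56, pool56 / np.where(tot56 > 0, tot56 * dt, 1.0), 1.0)
        s54 = np.where(tot54 * dt > pool54, pool54 / np.where(tot54 > 0, tot54 * dt, 1.0), 1.0)
    return np.clip(s56, 0.0, 1.0), np.clip(s54, 0.0, 1.0)


def _apply_fluxes(state: ColumnState, fl: FluxSet, dt: float,
                  params: ModelParams) -> ColumnState:
    """Euler update from a FluxSet (no MLD change), with sink limiting."""
    new = state.copy()

    # ---- dFe: sinks are the two uptakes, scavenging, colloidal pumping
    snk56 = [np.asarray(fl.uptake[c].fe56) for c in CLASSES] + \
            [np.asarray(fl.scavenging.fe56), np.asarray(fl.colloidal.fe56)]
    snk54 = [np.asarray(fl.uptake[c].fe54) for c in CLASSES] + \
            [np.asarray(fl.scavenging.fe54), np.asarray(fl.colloidal.fe54)]
    s56, s54 = _limit(np.asarray(state.dfe.fe56), np.asarray(state.dfe.fe54),
                      snk56, snk54, dt)
    up56 = [f * s56 for f in snk56[:2]]
    up54 = [f * s54 for f in snk54[:2]]
    scav56, coll56 = snk56[2] * s56, snk56[3] * s56
    scav54, coll54 = snk54[2] * s54, snk54[3] * s54

    src56 = (sum(np.asarray(fl.deposition[s].fe56) for s in AEROSOL_SOURCES)
             + np.asarray(fl.sediment.fe56) + np.asarray(fl.river.fe56)
             + np.asarray(fl.hydrothermal.fe56)
             + np.asarray(fl.remin_small.fe56) + np.asarray(fl.remin_large.fe56))
    src54 = (sum(np.asarray(fl.deposition[s].fe54) for s in AEROSOL_SOURCES)
             + np.asarray(fl.sediment.fe54) + np.asarray(fl.river.fe54)
             + np.asarray(fl.hydrothermal.fe54)
             + np.asarray(fl.remin_small.fe54) + np.asarray(fl.remin_large.fe54))
    new.dfe.fe56 = np.asarray(state.dfe.fe56) + dt * (src56 - sum(up56) - scav56 - coll56)
    new.dfe.fe54 = np.asarray(state.dfe.fe54) + dt * (src54 - sum(up54) - scav54 - coll54)
    # abiotically removed dFe (scavenging + colloidal pumping) joins the
    # small particulate pool
    new.pfe_small.fe56 = np.asarray(new.pfe_small.fe56) + dt * (scav56 + coll56)
    new.pfe_small.fe54 = np.asarray(new.pfe_small.fe54) + dt * (scav54 + coll54)

    # ---- phytoplankton Fe and C
    for i, cls in enumerate(CLASSES):
        pfe = state.phyto_fe_nano if i == 0 else state.phyto_fe_diatom
        npfe = new.phyto_fe_nano if i == 0 else new.phyto_fe_diatom
        c = np.asarray(state.phyto_c_nano if i == 0 else state.phyto_c_diatom)
        mort_c = np.asarray(fl.mortality_c[cls])
        avail = np.maximum(c - params.c_min, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(mort_c * dt > avail, avail / np.where(mort_c > 0, mort_c * dt, 1.0), 1.0)
        fc = np.clip(fc, 0.0, 1.0)
        # same scale on C and Fe mortality keeps the Fe quota unchanged
        m56 = np.asarray(fl.mortality_fe[cls].fe56) * fc
        m54 = np.asarray(fl.mortality_fe[cls].fe54) * fc
        npfe.fe56 = np.asarray(pfe.fe56) + dt * (up56[i] - m56)
        npfe.fe54 = np.asarray(pfe.fe54) + dt * (up54[i] - m54)
        mort_c = mort_c * fc
        c_new = c + dt * (np.asarray(fl.growth_c[cls]) - mort_c)
        if i == 0:
            new.phyto_c_nano = c_new
        else:
            new.phyto_c_diatom = c_new
        dest = new.pfe_small if i == 0 else new.pfe_large
        dest.fe56 = np.asarray(dest.fe56) + dt * m56
        dest.fe54 = np.asarray(dest.fe54) + dt * m54

    # ---- particles: mortality input added above; remin + export sinks
    for pool, npool, r, e in (
        (state.pfe_small, new.pfe_small, fl.remin_small, fl.export_small),
        (state.pfe_large, new.pfe_large, fl.remin_large, fl.export_large),
    ):
        r56, e56 = np.asarray(r.fe56), np.asarray(e.fe56)
        r54, e54 = np.asarray(r.fe54), np.asarray(e.fe54)
        s56p, s54p = _limit(np.asarray(pool.fe56), np.asarray(pool.fe54),
                            [r56, e56], [r54, e54], dt)
        npool.fe56 = np.asarray(npool.fe56) - dt * (r56 + e56) * s56p
        npool.fe54 = np.asarray(npool.fe54) - dt * (r54 + e54) * s54p

    # ---- macronutrient
    n_up = np.asarray(fl.n_uptake)
    with np.errstate(divide="ignore", invalid="ignore"):
        fn = np.where(n_up * dt > state.n, state.n / np.where(n_up > 0, n_up * dt, 1.0), 1.0)
    new.n = state.n + dt * (np.asarray(fl.n_remin) - n_up * np.clip(fn, 0.0, 1.0))

    # the limiters leave at most ulp-scale negatives; shave them off
    for pool in new.fe_pools().values():
        pool.fe56 = np.maximum(np.asarray(pool.fe56), 0.0)
        pool.fe54 = np.maximum(np.asarray(pool.fe54), 0.0)
    new.n = np.maximum(new.n, 0.0)
    return new


def _mix_to_mld(state: ColumnState, mld_next, sub56, sub54, sub_n=None) -> None:
    """Discrete entrainment (deepening) / detrainment (shoaling) in place."""
    mld0 = np.asarray(state.mld, dtype=float)
    dm = mld_next - mld0
    deep = dm > 0
    if np.any(deep):
        w = np.where(deep, dm / mld_next, 0.0)
        for pool, c56, c54 in ((state.dfe, sub56, sub54),):
            pool.fe56 = np.asarray(pool.fe56) * (1 - w) + w * np.asarray(c56)
            pool.fe54 = np.asarray(pool.fe54) * (1 - w) + w * np.asarray(c54)
        for pool in (state.phyto_fe_nano, state.phyto_fe_diatom,
                     state.pfe_small, state.pfe_large):
            pool.fe56 = np.asarray(pool.fe56) * (1 - w)
            pool.fe54 = np.asarray(pool.fe54) * (1 - w)
        state.phyto_c_nano = state.phyto_c_nano * (1 - w)
        state.phyto_c_diatom = state.phyto_c_diatom * (1 - w)
        if sub_n is not None:
            state.n = state.n * (1 - w) + w * np.asarray(sub_n)
        else:
            state.n = state.n * (1 - w) + w * state.n  # no reservoir: unchanged
    state.mld = np.broadcast_to(np.asarray(mld_next, dtype=float), mld0.shape).copy()


# ---------------------------------------------------------------------------
# scenario bundling and the era integrator


@dataclass
class Scenario:
    """Everything needed to integrate a grid of columns: grid, forcing,
    deposition history, per-column boundary conditions, model parameters."""

    grid: Grid
    scenario_params: ScenarioParams
    params: ModelParams
    deposition: DepositionSeries
    physics: ForcingSeries
    boundaries: list
    seed: int

    @property
    def n_columns(self) -> int:
        return self.grid.n_columns

    def boundary_arrays(self) -> dict:
        b = self.boundaries
        return {k: np.array([getattr(x, k) for x in b], dtype=float)
                for k in ("sub_dfe", "sub_delta", "sub_n", "sediment_flux",
                          "sediment_depth", "river_flux", "river_delta",
                          "hydrothermal_flux", "hydrothermal_delta",
                          "dust_subsurface_fraction")}


def build_scenario(scenario_params: ScenarioParams | None = None,
                   params: ModelParams | None = None, seed: int = 0) -> Scenario:
    """Generate the default synthetic scenario for the idealized grid."""
    sp = scenario_params or ScenarioParams()
    mp = params or ModelParams()
    sp.validate()
    mp.validate()
    grid = make_grid(sp)
    dep = synth_deposition(grid, sp, seed=seed)
    phys = grid_physics(grid)
    bnd = scenario_boundaries(grid, sp)
    return Scenario(grid=grid, scenario_params=sp, params=mp, deposition=dep,
                    physics=phys, boundaries=bnd, seed=seed)


def initial_state(scenario: Scenario, day: int = 0) -> ColumnState:
    """Cold-start state: subsurface water filling the mixed layer."""
    n = scenario.n_columns
    ba = scenario.boundary_arrays()
    p56 = heavy_fraction(ba["sub_delta"], scenario.params.r_std)
    dfe56 = ba["sub_dfe"] * p56
    doy = day % cal.DAYS_PER_YEAR
    mld = _daily_physics(scenario)[0][doy].copy()
    c0 = np.full(n, 0.05)
    q0 = 0.01
    pc56 = heavy_fraction(0.0, scenario.params.r_std)
    pfe = q0 * c0
    zero = lambda: IsotopePool(np.zeros(n), np.zeros(n))
    return ColumnState(
        dfe=IsotopePool(dfe56, ba["sub_dfe"] - dfe56),
        phyto_fe_nano=IsotopePool(pfe * pc56, pfe * (1 - pc56)),
        phyto_fe_diatom=IsotopePool(pfe * pc56, pfe * (1 - pc56)),
        pfe_small=zero(), pfe_large=zero(),
        phyto_c_nano=c0.copy(), phyto_c_diatom=c0.copy(),
        n=ba["sub_n"].copy(), mld=mld, day=day)


def _daily_physics(scenario: Scenario):
    """Daily climatological MLD and light, (365, n_columns), cached."""
    cache = getattr(scenario, "_daily_cache", None)
    if cache is not None:
        return cache
    doy = np.arange(cal.DAYS_PER_YEAR)
    m0, m1, w = cal.monthly_interp_weights(doy)
    w = w[:, None]
    mld = scenario.physics.mld[m0] * (1 - w) + scenario.physics.mld[m1] * w
    light = scenario.physics.light[m0] * (1 - w) + scenario.physics.light[m1] * w
    scenario._daily_cache = (mld, light)
    return mld, light


class BudgetTracker:
    """Accumulates per-pool, per-isotope net fluxes (µmol m⁻²) so that
    closure against the inventory change can be checked to rounding."""

    def __init__(self, state: ColumnState):
        n = np.asarray(state.mld).size
        self.net = {p: (np.zeros(n), np.zeros(n)) for p in FE_POOLS}
        self.i0 = {p: (np.asarray(pool.fe56) * state.mld,
                       np.asarray(pool.fe54) * state.mld)
                   for p, pool in state.fe_pools().items()}

    def add(self, pool: str, d56, d54) -> None:
        a, b = self.net[pool]
        a += d56
        b += d54

    def closure(self, state: ColumnState) -> float:
        """Max relative budget error over pools and isotopes."""
        worst = 0.0
        scale = max(float(np.max(np.asarray(p[0]) + np.asarray(p[1])))
                    for p in self.i0.values())
        for p, pool in state.fe_pools().items():
            i56 = np.asarray(pool.fe56) * state.mld
            i54 = np.asarray(pool.fe54) * state.mld
            scale = max(scale, float(np.max(i56 + i54)))
        scale = max(scale, 1e-300)
        for p, pool in state.fe_pools().items():
            i56 = np.asarray(pool.fe56) * state.mld
            i54 = np.asarray(pool.fe54) * state.mld
            e56 = np.max(np.abs(i56 - self.i0[p][0] - self.net[p][0]))
            e54 = np.max(np.abs(i54 - self.i0[p][1] - self.net[p][1]))
            worst = max(worst, float(e56) / scale, float(e54) / scale)
        return worst


def _run_settings_context(scenario: Scenario, settings: RunSettings):
    """Precompute per-run constants: endmember fractions, areal sources,
    effective subsurface isotope concentrations."""
    mp = scenario.params
    sp = scenario.scenario_params
    ba = scenario.boundary_arrays()
    settings.validate()
    alpha_u, alpha_l = settings.resolved_alphas(mp)

    # per-source, per-column ⁵⁶Fe mass fractions
    em = dict(sp.aerosol_endmembers)
    em["river"] = 0.0
    em["hydrothermal"] = 0.0  # per-column values below
    p56 = {}
    for s in AEROSOL_SOURCES:
        d = settings.endmember_overrides.get(s, em[s])
        p56[s] = np.full(scenario.n_columns, heavy_fraction(d, mp.r_std))
    sed_d = settings.endmember_overrides.get(
        "sediment", None)
    sed_delta = (np.full(scenario.n_columns, sed_d) if sed_d is not None
                 else sediment_delta(ba["sediment_depth"]))
    p56["sediment"] = heavy_fraction(sed_delta, mp.r_std)
    riv_d = settings.endmember_overrides.get("river", None)
    p56["river"] = heavy_fraction(
        np.full(scenario.n_columns, riv_d) if riv_d is not None else ba["river_delta"],
        mp.r_std)
    hyd_d = settings.endmember_overrides.get("hydrothermal", None)
    p56["hydrothermal"] = heavy_fraction(
        np.full(scenario.n_columns, hyd_d) if hyd_d is not None else ba["hydrothermal_delta"],
        mp.r_std)

    on = {s: float(settings.on(s)) for s in SOURCES}

    # constant areal source rates, µmol m⁻² d⁻¹
    riv = on["river"] * ba["river_flux"] / cal.DAYS_PER_YEAR
    hyd = on["hydrothermal"] * ba["hydrothermal_flux"] / cal.DAYS_PER_YEAR
    sed = on["sediment"] * ba["sediment_flux"] / cal.DAYS_PER_YEAR

    # subsurface reservoir incl. the dust-dissolution increment (carries the
    # dust endmember, so muting/switching dust propagates below the surface)
    dust_annual = scenario.deposition.flux[:, :, 0].mean(axis=0)
    inc = (on["dust"] * ba["dust_subsurface_fraction"] * dust_annual
           * mp.subsurface_residence_yr / mp.subsurface_thickness)
    base56 = ba["sub_dfe"] * heavy_fraction(ba["sub_delta"], mp.r_std)
    sub56 = base56 + inc * p56["dust"]
    sub54 = (ba["sub_dfe"] - base56) + inc * (1.0 - p56["dust"])

    return {
        "alpha_u": alpha_u, "alpha_l": alpha_l, "p56": p56, "on": on,
        "riv": riv, "hyd": hyd, "sed": sed, "sub56": sub56, "sub54": sub54,
        "sub_n": ba["sub_n"], "sed_depth": ba["sediment_depth"],
    }


def integrate(scenario: Scenario, state: ColumnState, day_start: int,
              day_end: int, settings: RunSettings | None = None,
              collect_monthly: bool = False, budget: BudgetTracker | None = None,
              annual_dfe: list | None = None, dt: float | None = None):
    """Integrate the grid from ``day_start`` to ``day_end`` (day indices).

    The inner loop is a flat numpy formulation of the same process laws as
    :func:`compute_tendencies`, vectorized over columns.  Optionally
    collects monthly-mean diagnostics, a per-pool isotope budget, and
    annual-mean dFe (for spin-up convergence monitoring).
    """
    settings = settings or RunSettings()
    ctx = _run_settings_context(scenario, settings)
    mp = scenario.params
    dt = mp.dt_days if dt is None else dt
    steps_per_day = int(round(1.0 / dt))
    if abs(steps_per_day * dt - 1.0) > 1e-9:
        raise StateError("dt must divide 1 day evenly")

    mld_d, light_d = _daily_physics(scenario)
    sed_gate = np.minimum(1.0, mld_d / ctx["sed_depth"][None, :])

    dep = scenario.deposition
    mi0 = (day_start // cal.DAYS_PER_YEAR) * 12
    # aerosol deposition per month, areal µmol m⁻² d⁻¹, summed over sources
    # after applying switches and endmember fractions
    n_mon_era = (day_end - 1) // cal.DAYS_PER_YEAR * 12 + 12 - mi0
    msl = slice(mi0, mi0 + n_mon_era)
    f = dep.flux[msl] / cal.DAYS_PER_YEAR          # (n_mon, ncol, 3)
    onv = np.array([ctx["on"][s] for s in AEROSOL_SOURCES])
    p56a = np.stack([ctx["p56"][s] for s in AEROSOL_SOURCES], axis=1)  # (ncol, 3)
    dep_tot_m = np.einsum("mcs,s->mc", f, onv)
    dep56_m = np.einsum("mcs,cs,s->mc", f, p56a, onv)
    dep54_m = dep_tot_m - dep56_m

    sed56_a = ctx["sed"] * ctx["p56"]["sediment"]
    sed54_a = ctx["sed"] - sed56_a
    riv56_a = ctx["riv"] * ctx["p56"]["river"]
    riv54_a = ctx["riv"] - riv56_a
    hyd56_a = ctx["hyd"] * ctx["p56"]["hydrothermal"]
    hyd54_a = ctx["hyd"] - hyd56_a
    const56_a = riv56_a + hyd56_a
    const54_a = riv54_a + hyd54_a

    sub56, sub54, sub_n = ctx["sub56"], ctx["sub54"], ctx["sub_n"]
    au, al = ctx["alpha_u"], ctx["alpha_l"]
    lt, kl = mp.ligand_lt, mp.ligand_k
    q_min, q_max, dq = mp.q_min, mp.q_max, mp.q_max - mp.q_min
    k_n, r_nc = mp.k_n, mp.r_nc

    st = state.copy()
    dfe56 = np.asarray(st.dfe.fe56, dtype=float).copy()
    dfe54 = np.asarray(st.dfe.fe54, dtype=float).copy()
    pf56 = [np.asarray(st.phyto_fe_nano.fe56, dtype=float).copy(),
            np.asarray(st.phyto_fe_diatom.fe56, dtype=float).copy()]
    pf54 = [np.asarray(st.phyto_fe_nano.fe54, dtype=float).copy(),
            np.asarray(st.phyto_fe_diatom.fe54, dtype=float).copy()]
    pp56 = [np.asarray(st.pfe_small.fe56, dtype=float).copy(),
            np.asarray(st.pfe_large.fe56, dtype=float).copy()]
    pp54 = [np.asarray(st.pfe_small.fe54, dtype=float).copy(),
            np.asarray(st.pfe_large.fe54, dtype=float).copy()]
    cc = [np.asarray(st.phyto_c_nano, dtype=float).copy(),
          np.asarray(st.phyto_c_diatom, dtype=float).copy()]
    nn = np.asarray(st.n, dtype=float).copy()
    mld = mld_d[day_start % cal.DAYS_PER_YEAR].copy()

    ncol = dfe56.size
    out = None
    if collect_monthly:
        keys = ["dfe56", "dfe54", "pp", "fe_uptake", "lim_fe", "lim_n", "lim_light",
                "mld", "light", "inv_dfe", "n", "phyto_c",
                "flux_dep", "flux_sed", "flux_riv", "flux_hyd", "flux_uptake",
                "flux_scav", "flux_coll", "flux_remin", "flux_export",
                "flux_entrain"]
        out = {k: np.zeros((n_mon_era, ncol)) for k in keys}
        out["days"] = np.zeros(n_mon_era)

    yr_acc = None
    if annual_dfe is not None:
        yr_acc = np.zeros(ncol)
        yr_n = 0

    pool_names = FE_POOLS

    for day in range(day_start, day_end):
        doy = day % cal.DAYS_PER_YEAR
        mi = (day // cal.DAYS_PER_YEAR) * 12 + cal.MONTH_OF_DOY[doy] - mi0
        light = light_d[doy]
        mld_next = mld_d[(doy + 1) % cal.DAYS_PER_YEAR]

        dep56 = dep56_m[mi]
        dep54 = dep54_m[mi]
        gate = sed_gate[doy]
        src56_a = dep56 + const56_a + sed56_a * gate   # areal, µmol m⁻² d⁻¹
        src54_a = dep54 + const54_a + sed54_a * gate

        for _ in range(steps_per_day):
            inv_mld = 1.0 / mld
            s56 = src56_a * inv_mld
            s54 = src54_a * inv_mld

            dfe_t = dfe56 + dfe54
            # speciation
            b = dfe_t + lt + 1.0 / kl
            fel = 2.0 * dfe_t * lt / (b + np.sqrt(b * b - 4.0 * dfe_t * lt))
            fel = np.minimum(fel, dfe_t)
            free_t = dfe_t - fel
            free54 = _partition_fe54_free(dfe56, dfe54, free_t, al)
            free56 = free_t - free54
            comp56 = dfe56 - free56
            comp54 = dfe54 - free54

            # biology
            n_lim = nn / (nn + k_n)
            up_t = [None, None]
            grow = [None, None]
            mort_c = [None, None]
            mor56 = [None, None]
            mor54 = [None, None]
            q_lim_w = 0.0
            c_tot = 0.0
            for i in range(2):
                c = cc[i]
                pfe_t = pf56[i] + pf54[i]
                q = np.where(c > 0, pfe_t / np.maximum(c, 1e-300), q_min)
                q_lim = np.clip((q - q_min) / dq, 0.0, 1.0)
                grow[i] = mp.mu_max[i] * light * np.minimum(n_lim, q_lim) * c
                headroom = np.clip(1.0 - q / q_max, 0.0, 1.0)
                up_t[i] = mp.v_max[i] * dfe_t / (dfe_t + mp.k_fe[i]) * headroom * c
                # hard cap: a step of luxury uptake may not push Q past Q_max
                up_t[i] = np.minimum(up_t[i], np.maximum(q_max * c - pfe_t, 0.0) / dt)
                # one effective specific mortality for C and Fe keeps the
                # quota invariant; capped so biomass never drops below the
                # seed-stock floor within a step
                m_spec = np.minimum(mp.mortality + mp.aggregation * c,
                                    np.maximum(c - mp.c_min, 0.0)
                                    / np.maximum(c * dt, 1e-300))
                mort_c[i] = m_spec * c
                mor56[i] = m_spec * pf56[i]
                mor54[i] = m_spec * pf54[i]
                q_lim_w = q_lim_w + q_lim * c
                c_tot = c_tot + c
            lim_fe = np.where(c_tot > 0, q_lim_w / np.maximum(c_tot, 1e-300), 1.0)

            # growth cap: do not dilute the quota below q_min
            for i in range(2):
                pfe_t = pf56[i] + pf54[i]
                cap = np.maximum(pfe_t / q_min - cc[i], 0.0) / dt
                grow[i] = np.minimum(grow[i], cap)

            # dFe sink isotope splits
            with np.errstate(divide="ignore", invalid="ignore"):
                r_pool = np.where(dfe54 > 0, dfe56 / np.maximum(dfe54, 1e-300), 0.0)
            rp_u = au * r_pool
            u54 = [np.where(dfe54 > 0, up_t[i] / (1.0 + rp_u), 0.0) for i in range(2)]
            u56 = [up_t[i] - u54[i] for i in range(2)]
            pfe_part = pp56[0] + pp54[0] + pp56[1] + pp54[1]
            scav_t = mp.k_scav * pfe_part * free_t
            with np.errstate(divide="ignore", invalid="ignore"):
                fr56 = np.where(free_t > 0, free56 / np.maximum(free_t, 1e-300), 0.0)
                co56 = np.where(fel > 0, comp56 / np.maximum(fel, 1e-300), 0.0)
            scav56 = scav_t * fr56
            scav54 = scav_t - scav56
            coll_t = mp.k_coll * fel
            coll56 = coll_t * co56
            coll54 = coll_t - coll56

            # per-isotope dFe limiter
            snk56 = u56[0] + u56[1] + scav56 + coll56
            snk54 = u54[0] + u54[1] + scav54 + coll54
            f56 = np.where(snk56 * dt > dfe56,
                           dfe56 / np.maximum(snk56 * dt, 1e-300), 1.0)
            f54 = np.where(snk54 * dt > dfe54,
                           dfe54 / np.maximum(snk54 * dt, 1e-300), 1.0)
            f56 = np.clip(f56, 0.0, 1.0)
            f54 = np.clip(f54, 0.0, 1.0)
            u56 = [u * f56 for u in u56]
            u54 = [u * f54 for u in u54]
            scav56, coll56 = scav56 * f56, coll56 * f56
            scav54, coll54 = scav54 * f54, coll54 * f54

            rem56 = [mp.remin_small * pp56[0], mp.remin_large * pp56[1]]
            rem54 = [mp.remin_small * pp54[0], mp.remin_large * pp54[1]]
            exp56 = [mp.export_small * pp56[0], mp.export_large * pp56[1]]
            exp54 = [mp.export_small * pp54[0], mp.export_large * pp54[1]]

            # updates
            d56 = dt * (s56 + rem56[0] + rem56[1] - u56[0] - u56[1] - scav56 - coll56)
            d54 = dt * (s54 + rem54[0] + rem54[1] - u54[0] - u54[1] - scav54 - coll54)
            dfe56_new = dfe56 + d56
            dfe54_new = dfe54 + d54

            pf56_new = [pf56[i] + dt * (u56[i] - mor56[i]) for i in range(2)]
            pf54_new = [pf54[i] + dt * (u54[i] - mor54[i]) for i in range(2)]

            # particle updates: nano -> small (+ scav + coll), diatom -> large
            pp56_new = [
                pp56[0] + dt * (mor56[0] + scav56 + coll56 - rem56[0] - exp56[0]),
                pp56[1] + dt * (mor56[1] - rem56[1] - exp56[1]),
            ]
            pp54_new = [
                pp54[0] + dt * (mor54[0] + scav54 + coll54 - rem54[0] - exp54[0]),
                pp54[1] + dt * (mor54[1] - rem54[1] - exp54[1]),
            ]

            n_up = r_nc * (grow[0] + grow[1])
            fn = np.clip(np.where(n_up * dt > nn, nn / np.maximum(n_up * dt, 1e-300), 1.0),
                         0.0, 1.0)
            grow = [g * fn for g in grow]
            n_up = n_up * fn
            n_rm = mp.n_remin_frac * r_nc * (mort_c[0] + mort_c[1])
            cc_new = [cc[i] + dt * (grow[i] - mort_c[i]) for i in range(2)]
            nn_new = np.maximum(nn + dt * (n_rm - n_up), 0.0)

            if budget is not None:
                a = mld * dt
                budget.add("dfe", (s56 + rem56[0] + rem56[1]
                                   - u56[0] - u56[1] - scav56 - coll56) * a,
                           (s54 + rem54[0] + rem54[1]
                            - u54[0] - u54[1] - scav54 - coll54) * a)
                budget.add("phyto_nano", (u56[0] - mor56[0]) * a, (u54[0] - mor54[0]) * a)
                budget.add("phyto_diatom", (u56[1] - mor56[1]) * a, (u54[1] - mor54[1]) * a)
                budget.add("part_small",
                           (mor56[0] + scav56 + coll56 - rem56[0] - exp56[0]) * a,
                           (mor54[0] + scav54 + coll54 - rem54[0] - exp54[0]) * a)
                budget.add("part_large", (mor56[1] - rem56[1] - exp56[1]) * a,
                           (mor54[1] - rem54[1] - exp54[1]) * a)

            if out is not None:
                out["dfe56"][mi] += dfe56_new * dt
                out["dfe54"][mi] += dfe54_new * dt
                out["pp"][mi] += (grow[0] + grow[1]) * dt
                out["fe_uptake"][mi] += (u56[0] + u54[0] + u56[1] + u54[1]) * dt
                out["lim_fe"][mi] += lim_fe * dt
                out["lim_n"][mi] += n_lim * dt
                out["lim_light"][mi] += light * dt
                out["mld"][mi] += mld * dt
                out["light"][mi] += light * dt
                out["inv_dfe"][mi] += (dfe56_new + dfe54_new) * mld * dt
                out["n"][mi] += nn_new * dt
                out["phyto_c"][mi] += (cc_new[0] + cc_new[1]) * dt
                out["flux_dep"][mi] += (dep56 + dep54) * inv_mld * dt
                out["flux_sed"][mi] += (sed56_a + sed54_a) * gate * inv_mld * dt
                out["flux_riv"][mi] += (riv56_a + riv54_a) * inv_mld * dt
                out["flux_hyd"][mi] += (hyd56_a + hyd54_a) * inv_mld * dt
                out["flux_uptake"][mi] += (u56[0] + u54[0] + u56[1] + u54[1]) * dt
                out["flux_scav"][mi] += (scav56 + scav54) * dt
                out["flux_coll"][mi] += (coll56 + coll54) * dt
                out["flux_remin"][mi] += (rem56[0] + rem54[0] + rem56[1] + rem54[1]) * dt
                out["flux_export"][mi] += (exp56[0] + exp54[0] + exp56[1] + exp54[1]) * dt

            dfe56, dfe54 = dfe56_new, dfe54_new
            pf56, pf54 = pf56_new, pf54_new
            pp56, pp54 = pp56_new, pp54_new
            cc, nn = cc_new, nn_new

        # ---- daily MLD adjustment (entrain on deepening, detrain on shoaling)
        dm = mld_next - mld
        deep = dm > 0
        w = np.where(deep, dm / mld_next, 0.0)
        if budget is not None:
            shal = np.where(deep, 0.0, dm)  # negative or zero
            budget.add("dfe", np.where(deep, dm * sub56, shal * dfe56),
                       np.where(deep, dm * sub54, shal * dfe54))
            budget.add("phyto_nano", np.where(deep, 0.0, shal * pf56[0]),
                       np.where(deep, 0.0, shal * pf54[0]))
            budget.add("phyto_diatom", np.where(deep, 0.0, shal * pf56[1]),
                       np.where(deep, 0.0, shal * pf54[1]))
            budget.add("part_small", np.where(deep, 0.0, shal * pp56[0]),
                       np.where(deep, 0.0, shal * pp54[0]))
            budget.add("part_large", np.where(deep, 0.0, shal * pp56[1]),
                       np.where(deep, 0.0, shal * pp54[1]))
        if out is not None:
            out["flux_entrain"][mi] += np.where(
                deep, (dm * (sub56 + sub54 - dfe56 - dfe54)) / mld_next, 0.0)
        one_w = 1.0 - w
        dfe56 = dfe56 * one_w + w * sub56
        dfe54 = dfe54 * one_w + w * sub54
        for i in range(2):
            pf56[i] = pf56[i] * one_w
            pf54[i] = pf54[i] * one_w
            pp56[i] = pp56[i] * one_w
            pp54[i] = pp54[i] * one_w
            cc[i] = cc[i] * one_w
        nn = nn * one_w + w * sub_n
        mld = mld_next.copy()

        if out is not None:
            out["days"][mi] += 1.0
        if yr_acc is not None:
            yr_acc += dfe56 + dfe54
            yr_n += 1
            if doy == cal.DAYS_PER_YEAR - 1:
                annual_dfe.append(yr_acc / yr_n)
                yr_acc = np.zeros(ncol)
                yr_n = 0

    # the limiters keep pools non-negative up to rounding; shave off any
    # residual ulp-scale negatives before handing the state back
    z = lambda a: np.maximum(a, 0.0)
    final = ColumnState(
        dfe=IsotopePool(z(dfe56), z(dfe54)),
        phyto_fe_nano=IsotopePool(z(pf56[0]), z(pf54[0])),
        phyto_fe_diatom=IsotopePool(z(pf56[1]), z(pf54[1])),
        pfe_small=IsotopePool(z(pp56[0]), z(pp54[0])),
        pfe_large=IsotopePool(z(pp56[1]), z(pp54[1])),
        phyto_c_nano=z(cc[0]), phyto_c_diatom=z(cc[1]), n=z(nn), mld=mld,
        day=day_end)
    if not (np.all(np.isfinite(dfe56)) and np.all(np.isfinite(dfe54))):
        raise StateError("numerical failure: non-finite dFe tracer")
    if out is not None:
        return final, _monthly_dataset(scenario, out, mi0)
    return final


def _monthly_dataset(scenario: Scenario, out: dict, mi0: int) -> xr.Dataset:
    days = out.pop("days")
    nm = days.size
    mask = days > 0
    for k in out:
        out[k] = out[k][mask] / days[mask][:, None]
    months = (mi0 + np.flatnonzero(mask))
    years = cal.BASE_YEAR + months // 12
    mon = months % 12
    time = years + (mon + 0.5) / 12.0
    delta = 1000.0 * (out["dfe56"] / out["dfe54"] / scenario.params.r_std - 1.0)
    lim_stack = np.stack([out["lim_fe"], out["lim_n"], out["lim_light"]])
    limitation = np.argmin(lim_stack, axis=0).astype(np.int8)
    data = {
        "dfe": (("time", "column"), out["dfe56"] + out["dfe54"]),
        "dfe56": (("time", "column"), out["dfe56"]),
        "dfe54": (("time", "column"), out["dfe54"]),
        "delta_dfe": (("time", "column"), delta),
        "dfe_inventory": (("time", "column"), out["inv_dfe"]),
        "pp": (("time", "column"), out["pp"]),
        "fe_uptake": (("time", "column"), out["fe_uptake"] * 1e3),
        "limitation": (("time", "column"), limitation),
        "lim_fe": (("time", "column"), out["lim_fe"]),
        "lim_n": (("time", "column"), out["lim_n"]),
        "lim_light": (("time", "column"), out["lim_light"]),
        "mld": (("time", "column"), out["mld"]),
        "light": (("time", "column"), out["light"]),
        "n": (("time", "column"), out["n"]),
        "phyto_c": (("time", "column"), out["phyto_c"]),
    }
    for k in ("flux_dep", "flux_sed", "flux_riv", "flux_hyd", "flux_uptake",
              "flux_scav", "flux_coll", "flux_remin", "flux_export",
              "flux_entrain"):
        data[k] = (("time", "column"), out[k])
    ds = xr.Dataset(
        data,
        coords={"time": time, "year": ("time", years), "month": ("time", mon + 1),
                "column": np.arange(scenario.n_columns),
                "column_label": ("column", scenario.grid.labels()),
                "band": ("column", list(scenario.grid.band)),
                "lon": ("column", scenario.grid.lon),
                "coastal": ("column", scenario.grid.coastal)},
        attrs={
            "units_dfe": "umol m-3", "units_pp": "mmol C m-3 d-1",
            "units_fe_uptake": "nmol Fe m-3 d-1", "units_delta": "permil",
            "units_dfe_inventory": "umol m-2",
            "limitation_codes": "0=Fe 1=N 2=light",
            "seed": scenario.seed,
        })
    return ds


def spinup(scenario: Scenario, settings: RunSettings | None = None,
           state: ColumnState | None = None, year_end: int = 1980,
           year_start: int = cal.BASE_YEAR):
    """200-year spin-up (1780 → ``year_end``) under climatological natural
    deposition and the ramped anthropogenic flux.

    Returns ``(state_at_year_end, diagnostics)`` where diagnostics holds
    the final-decade max year-over-year relative change of annual-mean
    dFe ('converged' if below the configured tolerance; non-convergence
    is a warning, never a failure).
    """
    import warnings

    settings = settings or RunSettings()
    state = state or initial_state(scenario, day=cal.day_index(year_start))
    annual = []
    final = integrate(scenario, state, cal.day_index(year_start),
                      cal.day_index(year_end), settings, annual_dfe=annual)
    annual = np.asarray(annual[-11:])
    denom = np.maximum(np.abs(annual[:-1]), 1e-12)
    change = float(np.max(np.abs(np.diff(annual, axis=0)) / denom)) if len(annual) > 1 else np.inf
    converged = change < scenario.params.spinup_tolerance
    if not converged:
        warnings.warn(f"spin-up not converged: final-decade change {change:.2e}",
                      RuntimeWarning, stacklevel=2)
    return final, {"yoy_change": change, "converged": converged}


def run(scenario: Scenario, settings: RunSettings | None = None,
        state: ColumnState | None = None, year_start: int = 1980,
        year_end: int = 2014, budget: BudgetTracker | None = None):
    """Monthly-varying run (default 1980–2014 inclusive) from a spun-up state.

    Returns ``(dataset, final_state)``; the dataset holds monthly means of
    dFe, δ⁵⁶Fe_diss, primary production, Fe uptake, the limitation index
    and every process flux.
    """
    settings = settings or RunSettings()
    if state is None:
        state, _ = spinup(scenario, settings, year_end=year_start)
    final, ds = integrate(scenario, state, cal.day_index(year_start),
                          cal.day_index(year_end + 1), settings,
                          collect_monthly=True, budget=budget)
    return ds, final
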