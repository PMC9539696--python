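"""Tests of the mixed-layer column simulator: process laws, stepping,
conservation, limiters and qualitative isotope behaviour."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import brentq

import isofe._calendar as cal
from isofe.column_model import (
    BudgetTracker,
    ColumnState,
    ModelParams,
    RunSettings,
    StateError,
    build_scenario,
    compute_tendencies,
    initial_state,
    integrate,
    ligand_speciation,
    run,
    spinup,
    step,
    uptake_rate,
)
from isofe.forcing_synth import ScenarioParams
from isofe.isotope_algebra import IsotopePool, pool_delta, pool_from_total


def inert_params(**overrides) -> ModelParams:
    """Parameters with every process switched off (rates zero)."""
    base = dict(mu_max=(0.0, 0.0), v_max=(0.0, 0.0), mortality=0.0,
                aggregation=0.0, k_scav=0.0, k_coll=0.0, remin_small=0.0,
                remin_large=0.0, export_small=0.0, export_large=0.0,
                c_min=0.0)
    base.update(overrides)
    return ModelParams(**base)


def make_state(n=1, dfe=1.0, delta=0.0, c=0.5, nut=5000.0, mld=50.0,
               quota=0.01, day=0) -> ColumnState:
    ones = np.ones(n)
    pool = pool_from_total(dfe * ones, delta)
    pfe = pool_from_total(quota * c * ones, 0.0)
    zero = lambda: IsotopePool(np.zeros(n), np.zeros(n))
    return ColumnState(dfe=pool, phyto_fe_nano=pfe.copy(),
                       phyto_fe_diatom=pfe.copy(), pfe_small=zero(),
                       pfe_large=zero(), phyto_c_nano=c * ones.copy(),
                       phyto_c_diatom=c * ones.copy(), n=nut * ones.copy(),
                       mld=mld * ones.copy(), day=day)


def hold(state, params, settings, sources, days, mld=None, light=0.0):
    """Step a state under constant forcing for ``days`` days."""
    mld = state.mld if mld is None else mld
    for _ in range(days):
        state = step(state, light, sources, 0.0, 0.0, mld, params, settings)
    return state


class TestLigandSpeciation:
    def test_no_ligand_all_free(self):
        free, comp = ligand_speciation(0.7, 0.0, 100.0)
        assert free == pytest.approx(0.7) and comp == 0.0

    def test_strong_binding_limit(self):
        free, comp = ligand_speciation(0.5, 2.0, 1e9)
        assert free == pytest.approx(0.0, abs=1e-6)
        assert comp == pytest.approx(0.5, rel=1e-6)

    def test_quadratic_against_root_finder(self):
        t, lt, k = 0.6, 1.0, 100.0
        free, comp = ligand_speciation(t, lt, k)
        assert free + comp == pytest.approx(t, rel=1e-14)
        # equilibrium residual of the solved root
        assert k * free * (lt - comp) - comp == pytest.approx(0.0, abs=1e-10)
        oracle = brentq(lambda x: k * (t - x) * (lt - x) - x, 0.0, min(t, lt),
                        xtol=1e-15)
        assert comp == pytest.approx(oracle, rel=1e-10)


class TestUptakeRate:
    def test_quota_cap(self):
        p = ModelParams()
        st = make_state(dfe=5.0, c=1.0, quota=p.q_max)
        fe_up, _ = uptake_rate(st, 1.0, p, "nano")
        assert np.all(fe_up == 0.0)

    def test_no_iron_no_uptake(self):
        st = make_state(dfe=0.0)
        fe_up, _ = uptake_rate(st, 1.0, ModelParams(), "diatom")
        assert np.all(fe_up == 0.0)

    def test_matches_hand_computed_product(self):
        p = ModelParams()
        st = make_state(dfe=0.5, c=1.0, nut=50000.0, quota=0.01)
        fe_up, growth = uptake_rate(st, 0.8, p, "nano")
        q = 0.01
        expect_up = p.v_max[0] * 0.5 / (0.5 + p.k_fe[0]) * (1 - q / p.q_max) * 1.0
        expect_gr = (p.mu_max[0] * 0.8
                     * min(50000 / (50000 + p.k_n),
                           (q - p.q_min) / (p.q_max - p.q_min)) * 1.0)
        assert fe_up[0] == pytest.approx(expect_up, rel=1e-12)
        assert growth[0] == pytest.approx(expect_gr, rel=1e-12)


class TestTendencies:
    def test_all_off_gives_zero_fluxes(self):
        fl = compute_tendencies(make_state(), 0.0, {}, 0.0, 0.0, 0.0,
                                inert_params())
        for pool in ([fl.sediment, fl.river, fl.hydrothermal, fl.scavenging,
                      fl.colloidal, fl.remin_small, fl.remin_large,
                      fl.export_small, fl.export_large]
                     + list(fl.deposition.values()) + list(fl.uptake.values())
                     + list(fl.mortality_fe.values())):
            assert np.all(np.asarray(pool.fe56) == 0)
            assert np.all(np.asarray(pool.fe54) == 0)
        assert np.all(fl.n_uptake == 0)

    def test_deposition_converts_areal_to_volumetric(self):
        st = make_state(mld=25.0)
        fl = compute_tendencies(st, 0.0, {"anthro": 0.5}, 0.0, 0.0, 0.0,
                                inert_params())
        dep = fl.deposition["anthro"]
        assert dep.total[0] == pytest.approx(0.5 / 25.0, rel=1e-12)
        assert pool_delta(IsotopePool(dep.fe56[0], dep.fe54[0])) == pytest.approx(-1.6, abs=1e-9)

    def test_anthro_only_source_trends_to_endmember(self):
        # single source, removal carrying the pool's own delta: the
        # dissolved pool must converge monotonically onto -1.6 permil
        p = inert_params(k_coll=0.1, ligand_lt=50.0,
                         fractionation=dataclasses.replace(
                             ModelParams().fractionation, alpha_ligand=1.0))
        st = make_state(dfe=0.1, delta=0.0, c=0.0)
        deltas = []
        for _ in range(40):
            st = hold(st, p, RunSettings(), {"anthro": 2.0}, days=10)
            deltas.append(pool_delta(IsotopePool(st.dfe.fe56[0], st.dfe.fe54[0])))
        assert all(np.diff(deltas) <= 1e-9)  # monotone up to rounding jitter
        assert deltas[-1] == pytest.approx(-1.6, abs=1e-3)

    def test_negative_state_rejected(self):
        st = make_state()
        st.n = np.array([-1.0])
        with pytest.raises(StateError):
            compute_tendencies(st, 0.0, {}, 0.0, 0.0, 0.0, ModelParams())


class TestStep:
    def test_zero_tendency_state_unchanged(self):
        st = make_state(c=0.3)
        new = step(st, 0.0, {}, 0.0, 0.0, st.mld, inert_params())
        assert np.array_equal(new.dfe.fe56, st.dfe.fe56)
        assert np.array_equal(new.phyto_c_nano, st.phyto_c_nano)
        assert np.array_equal(new.n, st.n)

    def test_limiter_drains_pool_at_pool_delta(self):
        # sink demand far exceeding the pool: dFe lands at ~0 and the
        # removed material carries the pool's own signature
        p = inert_params(k_coll=25.0, ligand_lt=50.0,
                         fractionation=dataclasses.replace(
                             ModelParams().fractionation, alpha_ligand=1.0))
        st = make_state(dfe=0.4, delta=-0.8, c=0.0)
        new = step(st, 0.0, {}, 0.0, 0.0, st.mld, p)
        assert new.dfe.total[0] <= 1e-12
        removed = IsotopePool(new.pfe_small.fe56[0], new.pfe_small.fe54[0])
        assert removed.total == pytest.approx(0.4, rel=1e-12)
        assert pool_delta(removed) == pytest.approx(-0.8, abs=1e-9)

    def test_shoaling_keeps_concentration_deepening_dilutes(self):
        st = make_state(dfe=0.6, c=0.0)
        shoaled = step(st, 0.0, {}, 0.0, 0.0, np.full(1, 30.0), inert_params())
        assert shoaled.dfe.total[0] == pytest.approx(0.6, rel=1e-12)
        deepened = step(st, 0.0, {}, 0.0, 0.0, np.full(1, 100.0), inert_params())
        assert deepened.dfe.total[0] == pytest.approx(0.6 * 0.5, rel=1e-12)


@pytest.fixture(scope="module")
def small_scenario():
    return build_scenario(ScenarioParams(n_lon=2), seed=3)


class TestIntegration:
    def test_isotope_conservation_short_run(self, small_scenario):
        st = initial_state(small_scenario)
        budget = BudgetTracker(st)
        fin = integrate(small_scenario, st, 0, 3 * 365, budget=budget)
        assert budget.closure(fin) <= 1e-10

    def test_dt_refinement_first_order_convergent(self, small_scenario):
        """Successive step halvings shrink the year-end dFe difference by
        ~2x (forward Euler); the absolute dt=1d sensitivity stays small."""
        st, _ = spinup(small_scenario, year_end=1800)
        d0 = cal.day_index(1800)
        a = integrate(small_scenario, st, d0, d0 + 365, dt=1.0)
        b = integrate(small_scenario, st, d0, d0 + 365, dt=0.5)
        c = integrate(small_scenario, st, d0, d0 + 365, dt=0.25)
        r1 = np.abs(a.dfe.total - b.dfe.total) / np.abs(b.dfe.total)
        r2 = np.abs(b.dfe.total - c.dfe.total) / np.abs(c.dfe.total)
        assert float(r1.max()) < 0.05
        significant = r1 > 1e-3
        ratio = r1[significant] / r2[significant]
        assert np.all(ratio > 1.5)

    def test_monthly_record_count_and_delta_definition(self, small_scenario):
        st = initial_state(small_scenario)
        ds, _ = run(small_scenario, state=st, year_start=1780, year_end=1781)
        assert ds.sizes["time"] == 24
        expect = 1000.0 * (ds.dfe56 / ds.dfe54 / small_scenario.params.r_std - 1.0)
        assert np.allclose(ds.delta_dfe.values, expect.values, atol=1e-12)

    def test_drained_system_converges_to_zero(self):
        sc = build_scenario(ScenarioParams(
            n_lon=2, dust_west=0.0, dust_east=0.0, anthro_west=0.0,
            anthro_east=0.0, wildfire_base=0.0, wildfire_sw_extra=0.0), seed=0)
        for i, b in enumerate(sc.boundaries):
            sc.boundaries[i] = dataclasses.replace(
                b, sub_dfe=0.0, sediment_flux=0.0, river_flux=0.0,
                hydrothermal_flux=0.0)
        state, diag = spinup(sc, year_end=1840)
        assert float(np.max(state.dfe.total)) < 1e-8
        assert diag["converged"]


class TestAbioticIsotopeDirections:
    """Scavenging (free dFe, light) drives the dissolved pool heavy;
    colloidal pumping (complexed dFe, heavy) drives it light."""

    def _steady_delta(self, k_scav, k_coll, ligand_lt=1.2):
        # a moderate complexed fraction keeps both sub-pools populated so
        # the equilibrium offset between them is visible in delta_diss
        p = inert_params(k_scav=k_scav, k_coll=k_coll, ligand_lt=ligand_lt)
        st = make_state(dfe=0.3, delta=0.0, c=0.0)
        st.pfe_small = pool_from_total(np.full(1, 0.05), 0.0)
        settings = RunSettings()
        for _ in range(600):
            st = step(st, 0.0, {"dust": 1.0}, 0.0, 0.0, st.mld, p, settings)
            st.pfe_small = pool_from_total(np.full(1, 0.05), 0.0)  # held fixed
        return pool_delta(IsotopePool(st.dfe.fe56[0], st.dfe.fe54[0]))

    def test_scavenging_dominant_drives_heavy(self):
        d_scav = self._steady_delta(k_scav=2.0, k_coll=0.0)
        assert d_scav > 0.09 + 0.01  # heavier than the dust source

    def test_colloidal_dominant_drives_light(self):
        d_coll = self._steady_delta(k_scav=0.0, k_coll=0.05, ligand_lt=0.15)
        assert d_coll < 0.09 - 0.01  # lighter than the dust source


class TestPositivitySweep:
    def test_random_parameter_draws_stay_nonnegative(self):
        rng = np.random.default_rng(42)
        for _ in range(15):
            p = ModelParams(
                mu_max=tuple(rng.uniform(0.2, 2.5, 2)),
                v_max=tuple(rng.uniform(0.01, 0.2, 2)),
                mortality=rng.uniform(0.0, 0.3),
                aggregation=rng.uniform(0.0, 0.5),
                k_scav=rng.uniform(0.0, 10.0),
                k_coll=rng.uniform(0.0, 0.5),
                remin_small=rng.uniform(0.0, 0.5),
                remin_large=rng.uniform(0.0, 0.5),
                export_small=rng.uniform(0.0, 0.5),
                export_large=rng.uniform(0.0, 0.5),
            )
            st = make_state(n=3, dfe=rng.uniform(0.001, 2.0),
                            c=rng.uniform(0.01, 5.0), nut=rng.uniform(10, 2e4),
                            quota=rng.uniform(p.q_min, p.q_max))
            sources = {"dust": rng.uniform(0, 50), "anthro": rng.uniform(0, 20)}
            for _ in range(50):
                st = step(st, rng.uniform(0, 1), sources, 0.1, 0.01,
                          st.mld * rng.uniform(0.9, 1.1), p)
            st.validate()  # raises on any negative pool


class TestSpinupProtocol:
    def test_spinup_reports_convergence_diagnostic(self, small_scenario):
        state, diag = spinup(small_scenario, year_end=1800)
        assert "yoy_change" in diag and np.isfinite(diag["yoy_change"])
        assert state.day == cal.day_index(1800)
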