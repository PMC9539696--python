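"""Tests of the counterfactual suite, differencing and attribution logic."""

import warnings

import numpy as np
import pytest
import xarray as xr

from isofe.column_model import ModelParams, RunSettings, build_scenario, step
from isofe.experiments import (
    ExperimentSpec,
    SuiteError,
    anthro_impact,
    attribute_delta,
    attribution_frame,
    build_suite,
    fractionation_share,
    fractionation_share_fields,
    run_suite,
)
from isofe.forcing_synth import SOURCES, ScenarioParams
from isofe.isotope_algebra import IsotopePool, mix, pool_delta, pool_from_total
from tests.test_column_model import hold, inert_params, make_state


@pytest.fixture(scope="module")
def mini_runs():
    """Short-era runs of a 6-column scenario for structural checks."""
    sc = build_scenario(ScenarioParams(n_lon=2), seed=5)
    era = dict(year_start=1980, year_end=1984, spinup_start=1950)
    specs = [
        ExperimentSpec("standard", **era),
        ExperimentSpec("no-anthro", sources_on={s: s != "anthro" for s in SOURCES}, **era),
        ExperimentSpec("mute-dust", endmember_overrides={"dust": 0.0}, **era),
        ExperimentSpec("mute-river", endmember_overrides={"river": 0.0}, **era),
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_suite(sc, specs)


class TestBuildSuite:
    def test_default_suite_composition(self):
        specs = build_suite()
        assert len(specs) == 11
        byname = {s.name: s for s in specs}
        std = byname["standard"]
        assert all(std.sources_on.values()) and not std.endmember_overrides
        assert std.alpha_uptake is None and std.alpha_ligand is None
        assert byname["mute-dust"].endmember_overrides == {"dust": 0.0}
        assert all(byname["mute-dust"].sources_on.values())
        assert byname["anthro-minus4"].endmember_overrides == {"anthro": -4.0}
        assert byname["no-uptake-frac"].alpha_uptake == 1.0
        assert byname["no-ligand-frac"].alpha_ligand == 1.0
        assert not byname["no-anthro"].sources_on["anthro"]

    def test_unknown_source_rejected(self):
        with pytest.raises(SuiteError):
            ExperimentSpec("bad", endmember_overrides={"volcano": 0.0}).settings()
        with pytest.raises(SuiteError):
            ExperimentSpec("bad", alpha_uptake=-1.0).settings()


class TestAnthroImpact:
    def test_self_difference_is_zero(self, mini_runs):
        d = anthro_impact(mini_runs["standard"], mini_runs["standard"])
        for v in ("d_dfe", "d_delta", "d_pp", "d_fe_uptake", "d_dfe_inventory"):
            assert float(np.abs(d[v]).max()) == 0.0

    def test_alignment_error(self, mini_runs):
        short = mini_runs["no-anthro"].isel(time=slice(0, 12))
        with pytest.raises(SuiteError):
            anthro_impact(mini_runs["standard"], short)

    def test_relative_change_floor(self, mini_runs):
        d = anthro_impact(mini_runs["standard"], mini_runs["no-anthro"],
                          rel_floor=1e-3)
        assert np.all(np.isfinite(d.d_dfe_rel))


class TestMutingIsIsotopeOnly:
    def test_concentrations_unchanged_by_muting(self, mini_runs):
        std, muted = mini_runs["standard"], mini_runs["mute-dust"]
        for v in ("dfe", "pp", "fe_uptake", "n"):
            np.testing.assert_allclose(muted[v].values, std[v].values,
                                       rtol=1e-9, atol=1e-12)
        # but the isotope signature does change
        assert float(np.abs(muted.delta_dfe - std.delta_dfe).max()) > 1e-3


class TestAttribution:
    def test_missing_run_rejected(self, mini_runs):
        with pytest.raises(SuiteError):
            attribute_delta(mini_runs["standard"],
                            {"dust": mini_runs["mute-dust"]}, {})

    def test_neutral_source_contributes_exactly_zero(self, mini_runs):
        """River enters at 0 permil, so muting it to 0 permil is a no-op and
        its attribution contribution vanishes identically."""
        contrib = mini_runs["standard"].delta_dfe - mini_runs["mute-river"].delta_dfe
        assert float(np.abs(contrib).max()) == 0.0

    def test_frame_schema(self, mini_runs):
        runs = {s: mini_runs["mute-dust"] for s in SOURCES}
        runs["river"] = mini_runs["mute-river"]
        att = attribute_delta(mini_runs["standard"], runs,
                              {"uptake": mini_runs["standard"],
                               "complexation": mini_runs["standard"]})
        df = attribution_frame(att)
        expected = {f"contrib_{s}" for s in SOURCES} | \
            {"contrib_uptake", "contrib_complexation", "residual", "delta_standard"}
        assert expected <= set(df.columns)


class TestTwoSourceMixingOracle:
    def test_steady_state_matches_weighted_endmember_mix(self):
        """Fractionation off, two sources flushing a box: the steady-state
        dissolved delta equals the exact isotope mixture of the combined
        influx, which is within 0.01 permil of the flux-weighted endmember
        average."""
        p = inert_params(k_coll=0.2, ligand_lt=50.0,
                         fractionation=ModelParams().fractionation.__class__(
                             alpha_uptake=1.0, alpha_ligand=1.0))
        st = make_state(dfe=0.05, delta=0.0, c=0.0)
        sources = {"dust": 1.5, "anthro": 1.0}
        st = hold(st, p, RunSettings(), sources, days=1500)
        got = pool_delta(IsotopePool(st.dfe.fe56[0], st.dfe.fe54[0]))
        influx = mix([pool_from_total(1.5, 0.09), pool_from_total(1.0, -1.6)])
        assert got == pytest.approx(pool_delta(influx), abs=1e-6)
        weighted = (1.5 * 0.09 + 1.0 * (-1.6)) / 2.5
        assert got == pytest.approx(weighted, abs=0.01)


class TestFractionationShare:
    def test_arithmetic(self):
        assert fractionation_share(-0.5, -0.3) == pytest.approx(40.0)

    def test_zero_total_undefined(self):
        with pytest.raises(SuiteError):
            fractionation_share(0.0, -0.1)

    def test_alpha_off_share_is_zero(self, mini_runs):
        std, noa = mini_runs["standard"], mini_runs["no-anthro"]
        share = fractionation_share_fields(std, noa, std, noa)
        assert float(np.nanmax(np.abs(share.values))) == 0.0
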