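"""Unit and property tests for the exact two-isotope bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from isofe.isotope_algebra import (
    R_STD,
    IsotopeError,
    IsotopePool,
    delta_to_ratio,
    equilibrium_partition,
    fractionated_flux,
    mix,
    pool_delta,
    pool_from_total,
    ratio_to_delta,
    rayleigh_delta,
)

deltas = st.floats(min_value=-10.0, max_value=10.0)
amounts = st.floats(min_value=1e-9, max_value=1e6)


class TestDeltaRatioConversion:
    @pytest.mark.parametrize("delta,expected", [
        (0.0, R_STD),                      # identity
        (1000.0, 2 * R_STD),               # doubling
        (-1.6, 15.6728832),                # direct evaluation of r_std*(1-0.0016)
    ])
    def test_delta_to_ratio_examples(self, delta, expected):
        assert delta_to_ratio(delta) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("ratio,expected", [
        (R_STD, 0.0), (2 * R_STD, 1000.0),
    ])
    def test_ratio_to_delta_examples(self, ratio, expected):
        assert ratio_to_delta(ratio) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("delta", [-4.0, -1.6, 0.09])
    def test_endmember_round_trip(self, delta):
        assert ratio_to_delta(delta_to_ratio(delta)) == pytest.approx(delta, abs=1e-12)

    @given(deltas)
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_property(self, delta):
        back = ratio_to_delta(delta_to_ratio(delta))
        assert abs(back - delta) <= 1e-12 * max(1.0, abs(delta))

    def test_domain_errors(self):
        with pytest.raises(IsotopeError):
            delta_to_ratio(-1000.0)
        with pytest.raises(IsotopeError):
            ratio_to_delta(0.0)


class TestPoolConstruction:
    def test_neutral_pool_split(self):
        p = pool_from_total(1.0, 0.0)
        assert p.fe56 == pytest.approx(R_STD / (1 + R_STD), rel=1e-12)  # 0.9401126
        assert p.fe56 + p.fe54 == pytest.approx(1.0, rel=1e-15)

    def test_empty_pool(self):
        p = pool_from_total(0.0, -3.0)
        assert p.fe56 == 0.0 and p.fe54 == 0.0
        with pytest.raises(IsotopeError):
            pool_delta(p)

    def test_negative_total_rejected(self):
        with pytest.raises(IsotopeError):
            pool_from_total(-1.0, 0.0)

    @given(amounts, deltas)
    @settings(max_examples=100, derandomize=True)
    def test_delta_inverse_property(self, total, delta):
        assert pool_delta(pool_from_total(total, delta)) == pytest.approx(delta, abs=1e-9)

    def test_scaling_leaves_delta_unchanged(self):
        p = pool_from_total(2.5, 0.09)
        assert pool_delta(p.scaled(7.3)) == pytest.approx(pool_delta(p), abs=1e-12)


class TestMixing:
    def test_two_endmember_mix(self):
        # exact ratio arithmetic on summed components; near the arithmetic
        # mean -0.755 since |delta| << 1000 (frozen from the 54-weighted
        # closed form: sum(w_i*p54_i*d_i)/sum(w_i*p54_i))
        m = mix([pool_from_total(1.0, 0.09), pool_from_total(1.0, -1.6)])
        assert pool_delta(m) == pytest.approx(-0.7556717, abs=1e-6)

    def test_identity_with_empty(self):
        x = pool_from_total(3.0, -0.5)
        m = mix([x, IsotopePool(0.0, 0.0)])
        assert m.fe56 == x.fe56 and m.fe54 == x.fe54

    def test_self_mix_preserves_delta(self):
        x = pool_from_total(3.0, -0.5)
        assert pool_delta(mix([x, x])) == pytest.approx(pool_delta(x), abs=1e-12)

    @given(st.lists(st.tuples(amounts, deltas), min_size=1, max_size=5))
    @settings(max_examples=100, derandomize=True)
    def test_mix_conserves_isotopes_exactly(self, specs):
        pools = [pool_from_total(t, d) for t, d in specs]
        m = mix(pools)
        # left-to-right summation order is the defined contract
        acc56, acc54 = 0.0, 0.0
        for p in pools:
            acc56 += p.fe56
            acc54 += p.fe54
        assert m.fe56 == acc56 and m.fe54 == acc54


class TestFractionatedFlux:
    def test_alpha_one_preserves_delta(self):
        pool = pool_from_total(2.0, 0.3)
        flux, _ = fractionated_flux(pool, 0.5, 1.0)
        assert pool_delta(flux) == pytest.approx(0.3, abs=1e-10)

    def test_small_withdrawal_limit(self):
        # analytic limit: delta_flux -> 1000*(alpha-1)*(1+delta/1000) = -0.5
        pool = pool_from_total(1.0, 0.0)
        flux, _ = fractionated_flux(pool, 1e-9, 0.9995)
        assert pool_delta(flux) == pytest.approx(-0.5, abs=1e-4)

    def test_full_withdrawal_is_mass_balance(self):
        pool = pool_from_total(1.0, 0.7)
        flux, residual = fractionated_flux(pool, pool.total, 0.9995)
        assert pool_delta(flux) == pytest.approx(0.7, abs=1e-9)
        assert residual.fe56 == 0.0 and residual.fe54 == 0.0

    def test_over_withdrawal_rejected(self):
        with pytest.raises(IsotopeError):
            fractionated_flux(pool_from_total(1.0, 0.0), 1.5, 0.9995)

    @given(amounts, deltas, st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=100, derandomize=True)
    def test_conservation_exact(self, total, delta, frac):
        pool = pool_from_total(total, delta)
        flux, residual = fractionated_flux(pool, frac * pool.total, 0.9995)
        assert flux.fe56 + residual.fe56 == pool.fe56
        assert flux.fe54 + residual.fe54 == pool.fe54
        assert flux.fe56 >= 0 and flux.fe54 >= 0
        assert residual.fe56 >= 0 and residual.fe54 >= 0


class TestRayleigh:
    @pytest.mark.parametrize("f,expected", [
        (1.0, 0.0),
        (0.5, 0.3466337),   # closed-form evaluation, alpha=0.9995
        (0.1, 1.1519555),
    ])
    def test_closed_form(self, f, expected):
        assert rayleigh_delta(0.0, f, 0.9995) == pytest.approx(expected, abs=1e-3)

    def test_domain_error(self):
        with pytest.raises(IsotopeError):
            rayleigh_delta(0.0, 0.0, 0.9995)

    def test_stepwise_withdrawals_reproduce_rayleigh(self):
        """10^4 instantaneous-fractionation withdrawals removing 90 % of a
        pool agree with the closed-form distillation to 1e-3 permil."""
        n = 10_000
        pool = pool_from_total(1.0, 0.0)
        keep = 0.1 ** (1.0 / n)
        for _ in range(n):
            _, pool = fractionated_flux(pool, (1 - keep) * pool.total, 0.9995)
        assert pool_delta(pool) == pytest.approx(
            rayleigh_delta(0.0, 0.1, 0.9995), abs=1e-3)


class TestEquilibriumPartition:
    def test_alpha_one_uniform(self):
        total = pool_from_total(1.0, 0.4)
        free, comp = equilibrium_partition(total, 0.5, 1.0)
        assert pool_delta(free) == pytest.approx(0.4, abs=1e-9)
        assert pool_delta(comp) == pytest.approx(0.4, abs=1e-9)

    def test_even_split_epsilon(self):
        # equal split of epsilon ~ 0.6 permil across the two sub-pools
        total = pool_from_total(1.0, 0.0)
        free, comp = equilibrium_partition(total, 0.5, 1.0006)
        assert pool_delta(comp) == pytest.approx(0.3, abs=2e-3)
        assert pool_delta(free) == pytest.approx(-0.3, abs=2e-3)
        # exact ratio condition R_c = alpha * R_f
        r_c = comp.fe56 / comp.fe54
        r_f = free.fe56 / free.fe54
        assert r_c == pytest.approx(1.0006 * r_f, rel=1e-12)

    def test_matches_root_finding_oracle(self):
        """The stable quadratic solution equals an independent brentq solve
        of the two-by-two mass balance."""
        total = pool_from_total(0.6, -0.8)
        frac, alpha = 0.37, 1.0006
        free, comp = equilibrium_partition(total, frac, alpha)
        free_total = (1 - frac) * total.total

        def residual(x54):  # x54 = 54Fe in the free pool
            f56 = free_total - x54
            c56 = total.fe56 - f56
            c54 = total.fe54 - x54
            return c56 * x54 - alpha * f56 * c54

        x = brentq(residual, 1e-12, min(total.fe54, free_total) - 1e-12,
                   xtol=1e-15)
        assert free.fe54 == pytest.approx(x, rel=1e-10)

    def test_full_complexation_limit(self):
        total = pool_from_total(1.0, 0.25)
        _, comp = equilibrium_partition(total, 1.0, 1.0006)
        assert pool_delta(comp) == pytest.approx(0.25, abs=1e-12)

    @given(amounts, deltas, st.floats(min_value=0.01, max_value=0.99))
    @settings(max_examples=100, derandomize=True)
    def test_recombination_exact(self, total, delta, frac):
        pool = pool_from_total(total, delta)
        free, comp = equilibrium_partition(pool, frac, 1.0006)
        recombined = mix([free, comp])
        assert pool_delta(recombined) == pytest.approx(pool_delta(pool), abs=1e-12)
        assert free.fe56 >= 0 and free.fe54 >= 0
        assert comp.fe56 >= 0 and comp.fe54 >= 0
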