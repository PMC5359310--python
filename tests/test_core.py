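"""Allometry, photosynthesis factors, meristem volume and the sink cap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meristree import (
    ModelParameters,
    TreeState,
    alpha2_from_redfarred,
    alpha2_from_stand_allometry,
    assimilation,
    co2_factor,
    estimate_alpha2,
    gamma_from_initial,
    height_from_allometry,
    hydraulic_factor,
    meristem_volume,
    par_factor,
    sink_cap,
    temperature_factor,
)
from meristree.core import ForcingRow

HYP = settings(max_examples=60, deadline=None, derandomize=True)

positive = st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False)
ratio = st.floats(0.05, 0.95)


class TestAllometry:
    @pytest.mark.parametrize(
        "r0, h0, alpha2, expected",
        [
            (1.0, 1.0, 0.4, 1.0),  # identity case
            (0.1, 10.0, 0.4, 10.0 / 0.1**0.8),
        ],
    )
    def test_gamma_from_initial(self, r0, h0, alpha2, expected):
        assert gamma_from_initial(r0, h0, alpha2) == pytest.approx(expected, rel=1e-12)

    def test_height_examples(self):
        gamma = gamma_from_initial(0.1, 10.0, 0.4)
        assert height_from_allometry(0.1, gamma, 0.4) == pytest.approx(10.0)
        assert height_from_allometry(0.2, gamma, 0.4) == pytest.approx(17.41, abs=0.01)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            gamma_from_initial(-0.1, 10.0, 0.4)
        with pytest.raises(ValueError):
            height_from_allometry(0.1, -1.0, 0.4)

    @HYP
    @given(r0=positive, h0=positive, alpha2=ratio)
    def test_round_trip(self, r0, h0, alpha2):
        gamma = gamma_from_initial(r0, h0, alpha2)
        assert height_from_allometry(r0, gamma, alpha2) == pytest.approx(h0, rel=1e-9)

    @HYP
    @given(r=positive, gamma=positive, alpha2=ratio)
    def test_doubling_radius_scales_height_by_power(self, r, gamma, alpha2):
        h1 = height_from_allometry(r, gamma, alpha2)
        h2 = height_from_allometry(2 * r, gamma, alpha2)
        assert h2 / h1 == pytest.approx(2 ** (2 * alpha2), rel=1e-9)

    def test_two_point_inversion_recovers_exponent(self):
        gamma = gamma_from_initial(0.1, 10.0, 0.4)
        h_b = height_from_allometry(0.2, gamma, 0.4)
        est = alpha2_from_stand_allometry((50, 10.0, 0.1), (60, h_b, 0.2))
        assert est.value == pytest.approx(0.4, rel=1e-12)
        assert est.in_range

    def test_equal_heights_give_zero_exponent(self):
        est = alpha2_from_stand_allometry((50, 12.0, 0.1), (60, 12.0, 0.2))
        assert est.value == 0.0
        assert not est.in_range  # outside the physical open interval

    def test_identical_radii_undefined(self):
        with pytest.raises(ValueError):
            alpha2_from_stand_allometry((50, 10.0, 0.1), (60, 12.0, 0.1))

    def test_regression_estimator_matches_noiseless_series(self):
        gamma = gamma_from_initial(0.08, 14.0, 0.38)
        r = np.linspace(0.08, 0.3, 12)
        h = gamma * r ** (2 * 0.38)
        est = estimate_alpha2(h, r)
        assert est.value == pytest.approx(0.38, rel=1e-9)
        assert est.in_range


class TestRedFarRedControl:
    def test_zero_ratio_hits_ceiling(self):
        assert alpha2_from_redfarred(0.0, 0.5, 1.2) == pytest.approx(0.5)

    def test_unshaded_value(self):
        # Ra = 1 is the unshaded reference: alpha2 = alpha0 * e^-alpha3
        assert alpha2_from_redfarred(1.0, 0.5, 1.2) == pytest.approx(0.5 * math.exp(-1.2))

    def test_zero_scale_is_constant(self):
        for ra in (0.0, 0.5, 2.0):
            assert alpha2_from_redfarred(ra, 0.4, 0.0) == pytest.approx(0.4)

    @HYP
    @given(ra=st.floats(0, 5), alpha0=ratio, alpha3=st.floats(0, 3))
    def test_decreasing_and_bounded(self, ra, alpha0, alpha3):
        v = alpha2_from_redfarred(ra, alpha0, alpha3)
        assert 0 < v <= alpha0
        assert alpha2_from_redfarred(ra + 0.5, alpha0, alpha3) <= v

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            alpha2_from_redfarred(-0.1, 0.5, 1.2)


class TestFactors:
    @pytest.mark.parametrize(
        "T, expected",
        [
            (18.0, 1.0),  # optimum
            (39.0, 0.0),  # upper parabola root: 18 + 21
            (-7.0, 0.0),  # lower parabola root: 18 - 25
            (28.5, 1.0 - (10.5 / 21.0) ** 2),
            (50.0, 0.0),  # clamped beyond the envelope
        ],
    )
    def test_temperature_parabola(self, T, expected):
        assert temperature_factor(T) == pytest.approx(expected, abs=1e-12)

    def test_co2_response(self):
        assert co2_factor(0.0, 500.0) == 0.0
        assert co2_factor(500.0, 500.0) == pytest.approx(1 - math.exp(-1))
        assert par_factor(50_000.0, 1000.0) == pytest.approx(1.0, abs=1e-9)

    def test_hydraulic_decline(self):
        # beta*h1 = 67.5 with beta = 3/4 puts the photosynthesis limit at 90 m
        p = ModelParameters()
        assert p.h1 == pytest.approx(90.0)
        assert hydraulic_factor(0.0, p.h1, p.beta) == 1.0
        assert hydraulic_factor(90.0, p.h1, p.beta) == pytest.approx(0.25)
        assert hydraulic_factor(120.0, p.h1, p.beta) == 0.0  # h = h1/beta

    @HYP
    @given(
        T=st.floats(-40, 60),
        cg=st.floats(0, 2000),
        q1=st.floats(0, 5000),
        h=st.floats(0, 200),
    )
    def test_all_factors_in_unit_interval(self, T, cg, q1, h):
        p = ModelParameters()
        for v in (
            temperature_factor(T, p.Topt, p.Ti_above, p.Ti_below),
            co2_factor(cg, p.Cr),
            par_factor(q1, p.Qr),
            hydraulic_factor(h, p.h1, p.beta),
        ):
            assert 0.0 <= v <= 1.0


SATURATED = ForcingRow(year=0, T=18.0, Q1=1e9, Cg=1e9)


class TestAssimilation:
    def test_zero_par_kills_assimilation(self):
        state = TreeState(0.2, 20.0, 0.2)
        row = ForcingRow(0, 18.0, 0.0, 400.0)
        assert assimilation(state, row, ModelParameters()) == 0.0

    def test_saturated_factors_reduce_to_volume_scaling(self):
        # push every factor to 1 (hydraulic via an effectively infinite h1)
        p = ModelParameters(beta_h1=1e12)
        state = TreeState(0.2, 20.0, 0.2)
        a = assimilation(state, SATURATED, p)
        assert a == pytest.approx(206.0 * math.pi * 0.04 * 20.0, rel=1e-9)
        assert a == pytest.approx(517.8, rel=1e-3)

    def test_product_form_matches_explicit_reassembly(self):
        p = ModelParameters()
        rng = np.random.default_rng(1)
        for _ in range(25):
            r, h = rng.uniform(0.01, 1.0), rng.uniform(1.0, 80.0)
            row = ForcingRow(
                0, rng.uniform(-10, 40), rng.uniform(0, 3000), rng.uniform(50, 900)
            )
            expected = (
                p.Amax
                * (1 - math.exp(-row.Cg / p.Cr))
                * (1 - math.exp(-row.Q1 / p.Qr))
                * max(0.0, 1 - ((abs(row.T - p.Topt)) / (21 if row.T > 18 else 25)) ** 2)
                * max(0.0, (p.h1 - p.beta * h) / p.h1)
                * r**2
                * h
            )
            got = assimilation(TreeState(r, h, p.S1), row, p)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_co2_and_par_max_at_topt(self):
        p = ModelParameters()
        state = TreeState(0.2, 20.0, 0.2)

        def a(T=18.0, q=800.0, cg=400.0):
            return assimilation(state, ForcingRow(0, T, q, cg), p)

        assert a(cg=500) > a(cg=400) > a(cg=300)
        assert a(q=1200) > a(q=800) > a(q=400)
        assert a(T=18) > a(T=14) and a(T=18) > a(T=24)


class TestMeristemVolumeAndSinkCap:
    def test_volume_example(self):
        assert meristem_volume(0.2, 20.0, 1.0) == pytest.approx(
            math.pi * 0.04 + 2 * math.pi * 0.2 * 20.0, rel=1e-12
        )

    def test_volume_vanishes_with_radius(self):
        assert meristem_volume(1e-9, 20.0, 1.0) < 1e-6

    def test_lateral_term_dominates_for_tall_trees(self):
        v = meristem_volume(0.1, 500.0, 1.0)
        assert v == pytest.approx(2 * math.pi * 0.1 * 500.0, rel=1e-3)

    def test_cap_zero_at_limit_height(self):
        p = ModelParameters()
        assert sink_cap(TreeState(0.3, 47.0, 0.2), p) == 0.0
        assert sink_cap(TreeState(0.3, 60.0, 0.2), p) == 0.0  # clamped above

    def test_cap_linear_in_height_factor(self):
        p = ModelParameters()
        vme = meristem_volume(0.2, 23.5, p.t_ratio)
        expected = p.g1 * p.k_lat * 0.5 * vme
        assert sink_cap(TreeState(0.2, 23.5, 0.2), p) == pytest.approx(expected)

    def test_cap_reference_value(self):
        p = ModelParameters()
        cap = sink_cap(TreeState(0.2, 20.0, 0.2), p)
        expected = 365 * 0.0201 * (27 / 47) * meristem_volume(0.2, 20.0, 1.0)
        assert cap == pytest.approx(expected, rel=1e-12)
        assert cap == pytest.approx(106.5, rel=5e-3)

    @HYP
    @given(r=st.floats(0.01, 1.0), h=st.floats(1.0, 46.0), dr=st.floats(1e-3, 0.5))
    def test_cap_nonnegative_and_increasing_in_radius(self, r, h, dr):
        p = ModelParameters()
        c1 = sink_cap(TreeState(r, h, p.S1), p)
        c2 = sink_cap(TreeState(r + dr, h, p.S1), p)
        assert c1 >= 0.0
        assert c2 > c1

    def test_tree_state_volume_is_cylinder(self):
        assert TreeState(0.2, 20.0, 0.2).volume == pytest.approx(2.513, abs=2e-3)

    def test_tree_state_validation(self):
        with pytest.raises(ValueError):
            TreeState(-0.1, 10.0, 0.2)
        with pytest.raises(ValueError):
            TreeState(0.1, 10.0, -0.2)
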