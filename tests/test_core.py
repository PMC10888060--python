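"""Closed-form hydrodynamics: values, limits, inverses and monotonicity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from extruflow import (
    NozzleGeometry,
    PowerLawRheology,
    SwellLaw,
    extrudate_radius,
    flow_rate,
    poi,
    printed_radius,
    printing_speed_for_radius,
    shear_state,
    swell_ratio,
    wall_shear_rate,
    wall_shear_stress,
)
from extruflow.errors import InvalidInputError


def flow_rate_oracle(K: float, n: float, R: float, L: float, dP: float) -> float:
    """Independent route to Q: numerically integrate the power-law velocity
    profile u(r) = (n/(n+1)) (dP/2KL)^(1/n) (R^(1+1/n) - r^(1+1/n)) over the
    nozzle cross-section."""

    def u(r):
        return (n / (n + 1)) * (dP / (2 * K * L)) ** (1 / n) * (
            R ** (1 + 1 / n) - r ** (1 + 1 / n)
        )

    value, _ = quad(lambda r: 2 * math.pi * r * u(r), 0, R, epsabs=1e-20, epsrel=1e-12)
    return value


class TestFlowRate:
    def test_reference_hydrogel_at_100_kpa(self, reference_rheology, nozzle_22g):
        q = flow_rate(reference_rheology, nozzle_22g, 100e3)
        # frozen from flow_rate_oracle(222, 0.23, 0.2065e-3, 12.7e-3, 100e3)
        assert q == pytest.approx(1.0635693227e-9, rel=1e-6)

    def test_newtonian_limit_is_hagen_poiseuille(self):
        rheology = PowerLawRheology(consistency_index=1.0, power_law_index=1.0)
        nozzle = NozzleGeometry(inner_radius=1e-3, length=10e-3)
        expected = math.pi * 1e3 * (1e-3) ** 4 / (8 * 1.0 * 10e-3)
        assert flow_rate(rheology, nozzle, 1e3) == pytest.approx(expected, rel=1e-12)

    def test_shear_thinning_amplifies_pressure_ratio(self, reference_rheology, nozzle_22g):
        # Q ~ dP^(1/n): a 13/7 pressure ratio becomes ~14.75-fold in flow
        ratio = flow_rate(reference_rheology, nozzle_22g, 130e3) / flow_rate(
            reference_rheology, nozzle_22g, 70e3
        )
        assert ratio == pytest.approx((13 / 7) ** (1 / 0.23), rel=1e-12)
        assert ratio > 14

    @pytest.mark.parametrize("n", [0.2, 0.5, 0.8, 1.0])
    def test_matches_velocity_profile_integration(self, n):
        K, R, L, dP = 50.0, 0.3e-3, 10e-3, 90e3
        rheology = PowerLawRheology(consistency_index=K, power_law_index=n)
        nozzle = NozzleGeometry(inner_radius=R, length=L)
        assert flow_rate(rheology, nozzle, dP) == pytest.approx(
            flow_rate_oracle(K, n, R, L, dP), rel=1e-6
        )

    @pytest.mark.parametrize(
        "K,R,L,dP",
        [(1.0, 1e-3, 10e-3, 1e3), (222.0, 0.2065e-3, 12.7e-3, 100e3), (10.0, 0.5e-3, 25e-3, 50e3)],
    )
    def test_newtonian_grid(self, K, R, L, dP):
        rheology = PowerLawRheology(consistency_index=K, power_law_index=1.0)
        nozzle = NozzleGeometry(inner_radius=R, length=L)
        expected = math.pi * dP * R**4 / (8 * K * L)
        assert flow_rate(rheology, nozzle, dP) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing_in_pressure(self, reference_rheology, nozzle_22g):
        pressures = np.linspace(10e3, 200e3, 40)
        q = [flow_rate(reference_rheology, nozzle_22g, p) for p in pressures]
        assert np.all(np.diff(q) > 0)

    def test_rejects_non_positive_pressure(self, reference_rheology, nozzle_22g):
        with pytest.raises(InvalidInputError):
            flow_rate(reference_rheology, nozzle_22g, 0.0)


class TestWallShearStress:
    @pytest.mark.parametrize(
        "pressure,expected", [(100e3, 812.9921259842521), (70e3, 569.0944881889764)]
    )
    def test_reference_nozzle(self, nozzle_22g, pressure, expected):
        assert wall_shear_stress(nozzle_22g, pressure) == pytest.approx(expected, rel=1e-12)

    def test_linear_in_pressure(self, nozzle_22g):
        assert wall_shear_stress(nozzle_22g, 2 * 80e3) == pytest.approx(
            2 * wall_shear_stress(nozzle_22g, 80e3), rel=1e-14
        )

    def test_rejects_non_positive_pressure(self, nozzle_22g):
        with pytest.raises(InvalidInputError):
            wall_shear_stress(nozzle_22g, -1.0)


class TestShearState:
    def test_viscosity_equals_k_at_unit_shear_rate(self, reference_rheology):
        assert shear_state(reference_rheology, 1.0).viscosity == pytest.approx(222.0)

    def test_newtonian_viscosity_is_constant(self):
        rheology = PowerLawRheology(consistency_index=5.0, power_law_index=1.0)
        for rate in (0.1, 1.0, 100.0):
            assert shear_state(rheology, rate).viscosity == pytest.approx(5.0)

    def test_wall_shear_rate_inverts_constitutive_law(self, reference_rheology):
        # frozen from a bisection solve of K * rate^n = 813 Pa
        rate = wall_shear_rate(reference_rheology, 812.9921259842521)
        assert rate == pytest.approx(282.4975138, rel=1e-6)
        recovered_tau = 222.0 * rate**0.23
        assert recovered_tau == pytest.approx(812.9921259842521, rel=1e-10)

    def test_zero_shear_rate_rejected(self, reference_rheology):
        with pytest.raises(InvalidInputError):
            shear_state(reference_rheology, 0.0)


class TestSwellRatio:
    def test_reference_law_at_813_pa(self, reference_swell_law):
        assert swell_ratio(reference_swell_law, 812.9921259842521) == pytest.approx(
            1.7726054182, rel=1e-9
        )

    def test_amplitude_zero_is_constant(self):
        law = SwellLaw(offset=1.57, amplitude=0.0, exponent=3.15)
        for tau in (10.0, 800.0, 5000.0):
            assert swell_ratio(law, tau) == 1.57

    def test_pressure_sweep_ratio(self, reference_swell_law, nozzle_22g):
        b_low = swell_ratio(reference_swell_law, wall_shear_stress(nozzle_22g, 70e3))
        b_high = swell_ratio(reference_swell_law, wall_shear_stress(nozzle_22g, 130e3))
        assert b_high / b_low == pytest.approx(1.2428, abs=2e-3)

    def test_non_decreasing_in_stress(self, reference_swell_law):
        taus = np.linspace(100, 2000, 50)
        b = [swell_ratio(reference_swell_law, t) for t in taus]
        assert np.all(np.diff(b) >= 0)


class TestVolumeConservation:
    def test_unit_identity(self):
        assert extrudate_radius(math.pi * 1e-9, 1e-3) == pytest.approx(1e-3, rel=1e-14)

    def test_reference_extrudate_radius(self):
        assert extrudate_radius(1.065e-9, 2.6e-3) == pytest.approx(0.3610e-3, abs=1e-6)

    def test_quadrupling_speed_halves_radius(self):
        q, v = 2.3e-9, 1.7e-3
        assert extrudate_radius(q, 4 * v) == pytest.approx(extrudate_radius(q, v) / 2, rel=1e-14)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        q=st.floats(1e-12, 1e-6),
        v=st.floats(1e-5, 1e-1),
    )
    def test_identity_holds_exactly(self, q, v):
        r = extrudate_radius(q, v)
        assert math.pi * r**2 * v == pytest.approx(q, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        q=st.floats(1e-12, 1e-6),
        r=st.floats(1e-5, 1e-2),
    )
    def test_speed_and_radius_are_exact_inverses(self, q, r):
        v = printing_speed_for_radius(q, r)
        assert printed_radius(q, v) == pytest.approx(r, rel=1e-12)
        assert math.pi * r**2 * v == pytest.approx(q, rel=1e-12)

    def test_printed_radius_decreases_with_speed(self):
        q = 1.06e-9
        speeds = np.linspace(1e-3, 10e-3, 30)
        radii = [printed_radius(q, v) for v in speeds]
        assert np.all(np.diff(radii) < 0)

    def test_rejects_non_positive_inputs(self):
        for func in (extrudate_radius, printed_radius, printing_speed_for_radius):
            with pytest.raises(InvalidInputError):
                func(0.0, 1.0)
            with pytest.raises(InvalidInputError):
                func(1.0, -1.0)


class TestPoi:
    def test_value(self):
        # 1 / (2 * 0.2e-3 m * 800 Pa), strictly SI
        assert poi(0.2e-3, 800.0) == pytest.approx(3.125, rel=1e-12)

    def test_doubling_radius_halves_poi(self):
        assert poi(0.4e-3, 800.0) == pytest.approx(poi(0.2e-3, 800.0) / 2, rel=1e-14)

    def test_chained_from_swell_example(self):
        # Rp = B(813 Pa) * R for the reference law at 100 kPa
        assert poi(0.3660e-3, 812.9921259842521) == pytest.approx(1.6805, abs=2e-3)

    def test_rejects_non_positive_inputs(self):
        with pytest.raises(InvalidInputError):
            poi(0.0, 800.0)


class TestTypeInvariants:
    def test_nozzle_requires_length_beyond_radius(self):
        with pytest.raises(InvalidInputError):
            NozzleGeometry(inner_radius=1e-3, length=0.5e-3)

    @pytest.mark.parametrize("n", [0.0, -0.2, 1.5])
    def test_power_law_index_bounds(self, n):
        with pytest.raises(InvalidInputError):
            PowerLawRheology(consistency_index=1.0, power_law_index=n)

    def test_swell_law_rejects_negative_amplitude(self):
        with pytest.raises(InvalidInputError):
            SwellLaw(offset=1.5, amplitude=-1e-10, exponent=3.0)
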