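import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biodesulf.exceptions import DomainError, InversionError, SingularDesignError
from biodesulf.growth import GrowthParams
from biodesulf.shrinking_core import (
    KineticCoefficients,
    ShrinkingCoreModel,
    ShrinkingCoreParams,
    basis_functions,
    coefficients_from_physical,
    conversion_at_time,
    intermediate_concentrations,
    rate_of_conversion,
    simulate_coupled,
    time_of_conversion,
)
from biodesulf.synthetic import gen_conversion_series

from conftest import rk4_integrate

PHYS = dict(gamma=1.0, delta=1e-5, rho=1300.0, M=0.120, r_s=6.3e-5,
            D1=1e-9, D2=1e-11, k=1e-6, C_l=1.0)

#: Published regression coefficients of the conversion-time law.
TABLE_COEFFS = KineticCoefficients(-2839.16, -8547.56, 7625.26)


class TestBasisFunctions:
    @pytest.mark.parametrize(
        "x, expected",
        [
            (0.0, (0.0, 0.0, 0.0)),
            (1.0, (1.0, 1.0 / 3.0, 1.0)),
            (0.5, (0.5, 0.0367061417, 0.2062994740)),
        ],
    )
    def test_closed_form_values(self, x, expected):
        assert basis_functions(x) == pytest.approx(expected, abs=1e-9)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            basis_functions(1.5)


class TestTimeOfConversion:
    def test_zero_conversion_zero_time(self):
        assert time_of_conversion(KineticCoefficients(3, 7, 11), 0.0) == 0.0

    def test_pure_external_diffusion_is_linear(self):
        assert time_of_conversion(KineticCoefficients(1, 0, 0), 0.5) == pytest.approx(0.5)

    def test_published_coefficients_at_half_conversion(self):
        # sign-mixed published coefficients give a negative time at x=0.5
        t = time_of_conversion(TABLE_COEFFS, 0.5)
        assert t == pytest.approx(-160.2408, abs=5e-3)


class TestInversion:
    def test_zero_time_maps_to_zero_conversion(self):
        assert conversion_at_time(KineticCoefficients(10, 40, 5), 0.0) == 0.0

    def test_linear_case(self):
        assert conversion_at_time(KineticCoefficients(1, 0, 0), 0.25) == pytest.approx(
            0.25, abs=1e-9
        )

    def test_round_trip_identity(self):
        coeffs = KineticCoefficients(10, 40, 5)
        t = time_of_conversion(coeffs, 0.63)
        assert conversion_at_time(coeffs, t) == pytest.approx(0.63, abs=1e-9)

    def test_non_monotone_profile_raises(self):
        with pytest.raises(InversionError):
            conversion_at_time(TABLE_COEFFS, 10.0)

    @given(x=st.floats(0.01, 0.98), a1=st.floats(0.1, 100), a2=st.floats(0.1, 500),
           a3=st.floats(0.1, 100))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_property(self, x, a1, a2, a3):
        coeffs = KineticCoefficients(a1, a2, a3)
        assert conversion_at_time(coeffs, time_of_conversion(coeffs, x)) == pytest.approx(
            x, abs=1e-8
        )


class TestPhysicalMapping:
    def test_direct_arithmetic_example(self):
        coeffs = coefficients_from_physical(ShrinkingCoreParams(**PHYS))
        # A1 = gamma delta rho r_s / (3 M C_l D1)
        assert coeffs.A1 == pytest.approx(1e-5 * 1300 * 6.3e-5 / (3 * 0.12 * 1e-9),
                                          rel=1e-12)
        assert coeffs.A1 == pytest.approx(2275.0, rel=1e-6)

    def test_doubling_cl_halves_all_coefficients(self):
        base = coefficients_from_physical(ShrinkingCoreParams(**PHYS))
        double = coefficients_from_physical(
            ShrinkingCoreParams(**{**PHYS, "C_l": 2.0})
        )
        assert double.as_array() == pytest.approx(base.as_array() / 2)

    def test_doubling_d2_halves_a2_only(self):
        base = coefficients_from_physical(ShrinkingCoreParams(**PHYS))
        mod = coefficients_from_physical(ShrinkingCoreParams(**{**PHYS, "D2": 2e-11}))
        assert mod.A2 == pytest.approx(base.A2 / 2)
        assert mod.A1 == pytest.approx(base.A1)
        assert mod.A3 == pytest.approx(base.A3)

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(DomainError):
            ShrinkingCoreParams(**{**PHYS, "k": 0.0})


class TestRateOfConversion:
    def test_external_diffusion_constant_rate(self):
        coeffs = KineticCoefficients(1, 0, 0)
        for x in (0.0, 0.3, 0.9):
            assert rate_of_conversion(coeffs, x) == pytest.approx(1.0)

    def test_reaction_control_closed_form(self):
        a3 = 7.0
        coeffs = KineticCoefficients(0, 0, a3)
        for x in (0.1, 0.5, 0.9):
            expected = 3.0 * (1 - x) ** (2.0 / 3.0) / a3
            assert rate_of_conversion(coeffs, x) == pytest.approx(expected, rel=1e-12)

    def test_reciprocal_of_time_derivative(self):
        coeffs = KineticCoefficients(10, 40, 5)
        h = 1e-7
        for x in (0.2, 0.5, 0.8):
            dtdx = (time_of_conversion(coeffs, x + h)
                    - time_of_conversion(coeffs, x - h)) / (2 * h)
            assert rate_of_conversion(coeffs, x) * dtdx == pytest.approx(1.0, abs=1e-6)

    def test_integrating_rate_reproduces_time_law(self):
        coeffs = KineticCoefficients(10, 40, 5)
        t_end = time_of_conversion(coeffs, 0.9)
        t_grid = np.linspace(0.0, t_end, 50001)
        x_path = rk4_integrate(
            lambda _t, x: rate_of_conversion(coeffs, min(max(x, 0.0), 1 - 1e-9)),
            0.0, t_grid,
        )
        assert x_path[-1] == pytest.approx(0.9, abs=1e-8)


class TestIntermediateConcentrations:
    def test_no_reaction_no_gradients(self):
        c_s, c_ls = intermediate_concentrations(ShrinkingCoreParams(**PHYS), 0.3, 0.0)
        assert c_s == 0.0 and c_ls == 0.0

    def test_no_product_layer_at_zero_conversion(self):
        c_s, c_ls = intermediate_concentrations(ShrinkingCoreParams(**PHYS), 0.0, -1e-12)
        assert c_s == pytest.approx(c_ls)

    def test_infinite_internal_diffusivity_limit(self):
        fast = ShrinkingCoreParams(**{**PHYS, "D2": 1e3})
        c_s, c_ls = intermediate_concentrations(fast, 0.5, -1e-12)
        assert c_s == pytest.approx(c_ls, rel=1e-6)
        slow = ShrinkingCoreParams(**PHYS)
        c_s2, c_ls2 = intermediate_concentrations(slow, 0.5, -1e-12)
        assert c_s2 > c_ls2


class TestCoefficientFit:
    def test_noiseless_recovery_machine_precision(self):
        x = np.arange(0.05, 0.951, 0.05)
        coeffs = KineticCoefficients(10, 40, 5)
        t = time_of_conversion(coeffs, x)
        res = ShrinkingCoreModel(t, x).fit()
        assert res.coeffs.as_array() == pytest.approx(coeffs.as_array(), rel=1e-10)
        assert res.R == pytest.approx(1.0, abs=1e-12)

    def test_internal_diffusion_dominant_ranking(self):
        """A2 >> A1, A3 reproduces the published control diagnosis:
        |r(A2)| > |r(A3)| > |r(A1)|, internal diffusion controlling."""
        x = np.arange(0.05, 0.951, 0.05)
        t, xg = gen_conversion_series(KineticCoefficients(10, 400, 5), x)
        res = ShrinkingCoreModel(t, xg).fit()
        r = res.term_correlations
        assert abs(r["r_A2"]) > abs(r["r_A3"]) > abs(r["r_A1"])
        assert res.controlling_step[0] == "internal_diffusion"

    def test_nonnegative_mode(self):
        x = np.arange(0.05, 0.951, 0.05)
        t, xg = gen_conversion_series(KineticCoefficients(10, 400, 5), x,
                                      noise_sd=0.1, seed=4)
        res = ShrinkingCoreModel(t, xg).fit(nonnegative=True)
        assert all(a >= 0 for a in res.coeffs)

    def test_constant_conversion_singular(self):
        with pytest.raises((SingularDesignError, DomainError)):
            ShrinkingCoreModel([1, 2, 3, 4], [0.5, 0.5, 0.5, 0.5]).fit()

    def test_few_points_rejected(self):
        with pytest.raises(DomainError):
            ShrinkingCoreModel([1, 2, 3], [0.1, 0.2, 0.3])


class TestCoupledSimulation:
    def test_reduces_to_fixed_coefficients_without_growth(self):
        growth = GrowthParams(u_m=0.0, K=0.3, cl0_over_y=1.0, p0=8.88)
        coeffs = KineticCoefficients(10, 40, 5)
        times = np.linspace(0.0, 25.0, 16)
        _, x = simulate_coupled(growth, coeffs, times)
        expected = [conversion_at_time(coeffs, t) for t in times]
        assert x == pytest.approx(expected, abs=1e-7)

    def test_growing_biomass_accelerates_conversion(self, fitted_growth_params):
        coeffs = KineticCoefficients(10, 40, 5)
        times = np.linspace(0.0, 40.0, 21)
        _, x_growing = simulate_coupled(fitted_growth_params, coeffs, times)
        frozen = GrowthParams(u_m=0.0, K=fitted_growth_params.K,
                              cl0_over_y=fitted_growth_params.cl0_over_y, p0=8.88)
        _, x_fixed = simulate_coupled(frozen, coeffs, times)
        assert np.all(x_growing >= x_fixed - 1e-10)

    def test_matches_rk4_oracle(self, fitted_growth_params):
        coeffs = KineticCoefficients(10, 40, 5)
        growth = fitted_growth_params
        cl_ref = growth.cl0

        def joint_rhs(_t, y):
            p, x = y
            p = min(max(p, 0.0), growth.p0)
            x = min(max(x, 0.0), 1 - 1e-9)
            dp = -growth.u_m * p * (growth.cl0_over_y + growth.p0 - p) / (growth.K + p)
            c_l = growth.cl0 + growth.y * (growth.p0 - p)
            return np.array([dp, (c_l / cl_ref) * rate_of_conversion(coeffs, x)])

        t_grid = np.linspace(0.0, 12.0, 20001)
        y = np.array([growth.p0, 0.0])
        for t0, t1 in zip(t_grid[:-1], t_grid[1:]):
            h = t1 - t0
            k1 = joint_rhs(t0, y)
            k2 = joint_rhs(t0 + h / 2, y + h * k1 / 2)
            k3 = joint_rhs(t0 + h / 2, y + h * k2 / 2)
            k4 = joint_rhs(t0 + h, y + h * k3)
            y = y + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6
        _, x = simulate_coupled(growth, coeffs, [0.0, 12.0])
        assert x[-1] == pytest.approx(y[1], rel=1e-6)


def test_single_resistance_limits():
    """Each single-coefficient model reduces to its classical law."""
    x = np.linspace(0.05, 0.95, 10)
    g1, g2, g3 = basis_functions(x)
    a = 13.0
    assert time_of_conversion(KineticCoefficients(a, 0, 0), x) == pytest.approx(a * g1)
    assert time_of_conversion(KineticCoefficients(0, a, 0), x) == pytest.approx(a * g2)
    assert time_of_conversion(KineticCoefficients(0, 0, a), x) == pytest.approx(a * g3)
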