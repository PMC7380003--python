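import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from persched.model_core import (BaselineHazard, LongitudinalSpec,
                                 ModelParameters, NaturalCubicBasis, RiskSpec,
                                 conditional_survival, default_parameters,
                                 hazard, mean_trajectory)


class TestNaturalCubicBasis:
    def test_dimensions_match_model_structure(self):
        # 3 interior knots -> 4 columns; 1 interior knot -> 2 columns
        assert NaturalCubicBasis([0.1, 0.5, 4.0], (0, 7)).n_basis == 4
        assert NaturalCubicBasis([0.1], (0, 7)).n_basis == 2

    def test_linear_tails_beyond_boundary_knots(self):
        basis = NaturalCubicBasis([0.1, 0.5, 4.0], (0.0, 7.0))
        t = np.array([7.5, 9.0, 12.0])
        d = basis.deriv(t)
        # derivative constant on the right tail = linearity
        assert np.allclose(d[0], d[1], atol=1e-12)
        assert np.allclose(d[0], d[2], atol=1e-12)
        left = basis.deriv(np.array([-1.0, -0.2]))
        assert np.allclose(left[0], left[1], atol=1e-12)

    @pytest.mark.parametrize("knots", [([0.5, 0.1], (0, 7)),
                                       ([0.1, 8.0], (0, 7)),
                                       ([0.1], (7, 0))])
    def test_invalid_knots_rejected(self, knots):
        with pytest.raises(ValueError):
            NaturalCubicBasis(*knots)


class TestMeanTrajectory:
    def test_zero_coefficients_give_zero(self, params):
        long_ = params.longitudinal
        spec = LongitudinalSpec(beta=np.zeros(long_.n_fixed),
                                D=long_.D, sigma=long_.sigma,
                                fixed_basis=long_.fixed_basis,
                                random_basis=long_.random_basis)
        m, mp = mean_trajectory(spec, 65.0, np.zeros(long_.n_random),
                                np.array([0.0, 2.0, 5.0]))
        assert np.allclose(m, 0.0) and np.allclose(mp, 0.0)

    def test_linear_case(self, linear_spec):
        m, mp = mean_trajectory(linear_spec, 70.0, np.zeros(2), np.array([3.0]))
        assert m[0] == pytest.approx(7.0)
        assert mp[0] == pytest.approx(2.0)

    def test_derivative_matches_finite_difference(self, params):
        long_ = params.longitudinal
        rng = np.random.default_rng(7)
        h = 1e-5
        for _ in range(20):
            b = rng.multivariate_normal(np.zeros(long_.n_random), long_.D)
            age = rng.uniform(55, 80)
            t = rng.uniform(h, 10.0)
            _, mp = mean_trajectory(long_, age, b, np.array([t]))
            m_lo, _ = mean_trajectory(long_, age, b, np.array([t - h]))
            m_hi, _ = mean_trajectory(long_, age, b, np.array([t + h]))
            assert mp[0] == pytest.approx((m_hi[0] - m_lo[0]) / (2 * h),
                                          abs=1e-6)

    def test_dimension_mismatch_rejected(self, params):
        with pytest.raises(ValueError):
            mean_trajectory(params.longitudinal, 70.0, np.zeros(5),
                            np.array([1.0]))


class TestHazard:
    def test_weibull_closed_form_without_association(self, params):
        risk = RiskSpec(gamma=np.zeros(2), alpha_value=0.0, alpha_velocity=0.0,
                        baseline=BaselineHazard("weibull", shape=3.0, scale=5.0))
        h = hazard(risk, params.longitudinal, 70.0,
                   np.zeros(params.longitudinal.n_random), np.array([2.5]))
        assert h[0] == pytest.approx((3 / 5) * 0.5 ** 2)  # 0.15

    def test_piecewise_constant_with_constant_trajectory(self, linear_spec):
        # constant m: trajectory 1 + 0*t, gamma'w = 0.3, alpha1 = 0.5
        spec = LongitudinalSpec(beta=np.array([1.0, 0.0, 0.0, 0.0]),
                                D=np.eye(2) * 0.1, sigma=0.1,
                                fixed_basis=linear_spec.fixed_basis,
                                random_basis=linear_spec.random_basis)
        base = BaselineHazard("piecewise_constant", breakpoints=np.array([5.0]),
                              rates=np.array([0.2, 0.2]))
        risk = RiskSpec(gamma=np.array([0.3, 0.0]), alpha_value=0.5,
                        alpha_velocity=0.0, baseline=base, form="value")
        h = hazard(risk, spec, 71.0, np.zeros(2), np.array([1.0, 4.0, 9.0]))
        expected = 0.2 * np.exp(0.3 * 1.0 + 0.5 * 1.0)
        assert np.allclose(h, expected)

    def test_velocity_fold_change_matches_reported_association(self, params):
        """A velocity rise from -0.06 to 0.14 doubles the hazard 2.05-fold."""
        a2 = params.risk.alpha_velocity
        assert np.exp(0.2 * a2) == pytest.approx(2.05, rel=1e-12)

    def test_negative_time_rejected(self, params):
        with pytest.raises(ValueError):
            hazard(params.risk, params.longitudinal, 70.0,
                   np.zeros(3), np.array([-0.5]))


class TestConditionalSurvival:
    def test_degenerate_interval_is_one(self, params):
        assert conditional_survival(params.risk, params.longitudinal, 70.0,
                                    np.zeros(3), 1.5, 1.5) == 1.0

    def test_weibull_closed_form(self, weibull_only_params):
        p = weibull_only_params
        for t0, t1 in [(0.0, 3.0), (1.0, 6.0), (2.5, 2.6)]:
            got = conditional_survival(p.risk, p.longitudinal, 70.0,
                                       np.zeros(3), t0, t1)
            want = np.exp(-((t1 / 5.0) ** 3 - (t0 / 5.0) ** 3))
            assert got == pytest.approx(want, abs=1e-8)

    def test_matches_dense_trapezoid_on_time_varying_hazard(self, params):
        rng = np.random.default_rng(3)
        b = rng.multivariate_normal(np.zeros(3), params.longitudinal.D)
        t0, t1 = 0.5, 6.0
        got = conditional_survival(params.risk, params.longitudinal, 72.0,
                                   b, t0, t1)
        grid = np.linspace(t0, t1, 100_001)
        hs = hazard(params.risk, params.longitudinal, 72.0, b, grid)
        want = np.exp(-integrate.trapezoid(hs, grid))
        assert got == pytest.approx(want, abs=1e-6)

    def test_multiplicative_over_subintervals(self, params):
        b = np.array([0.3, -0.1, 0.05])
        args = (params.risk, params.longitudinal, 68.0, b)
        s02 = conditional_survival(*args, 0.5, 4.0)
        s01 = conditional_survival(*args, 0.5, 2.0)
        s12 = conditional_survival(*args, 2.0, 4.0)
        assert s02 == pytest.approx(s01 * s12, abs=1e-8)

    def test_non_increasing_in_upper_limit(self, params):
        b = np.zeros(3)
        vals = [conditional_survival(params.risk, params.longitudinal, 70.0,
                                     b, 1.0, u) for u in (2.0, 4.0, 8.0)]
        assert vals[0] >= vals[1] >= vals[2]

    def test_reversed_interval_rejected(self, params):
        with pytest.raises(ValueError):
            conditional_survival(params.risk, params.longitudinal, 70.0,
                                 np.zeros(3), 3.0, 1.0)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(t=st.floats(min_value=-2.0, max_value=12.0),
       knot=st.floats(min_value=0.2, max_value=6.0))
def test_spline_basis_derivative_property(t, knot):
    """Analytic basis derivatives agree with central differences everywhere,
    including beyond the boundary knots."""
    basis = NaturalCubicBasis([0.1, knot, 6.5], (0.0, 7.0))
    h = 1e-5
    fd = (basis.design(np.array([t + h])) - basis.design(np.array([t - h]))) \
        / (2 * h)
    assert np.allclose(basis.deriv(np.array([t])), fd, atol=1e-6)


def test_intercept_shift_reparameterization_invariance(params):
    """Shifting the beta intercept by c while absorbing -alpha1*c into a
    baseline covariate offset leaves the hazard unchanged."""
    long_ = params.longitudinal
    c = 0.7
    beta_shift = long_.beta.copy()
    beta_shift[0] += c
    shifted = LongitudinalSpec(beta=beta_shift, D=long_.D, sigma=long_.sigma,
                               fixed_basis=long_.fixed_basis,
                               random_basis=long_.random_basis)
    t = np.array([1.0, 3.0, 6.0])
    b = np.array([0.2, 0.1, -0.3])
    h_orig = hazard(params.risk, long_, 70.0, b, t)
    h_shift = hazard(params.risk, shifted, 70.0, b, t)
    assert np.allclose(h_shift, h_orig * np.exp(params.risk.alpha_value * c))


def test_parameter_roundtrip_through_yaml(tmp_path, params):
    path = tmp_path / "params.yml"
    params.to_yaml(path)
    back = ModelParameters.from_yaml(path)
    assert np.allclose(back.longitudinal.beta, params.longitudinal.beta)
    assert np.allclose(back.longitudinal.D, params.longitudinal.D)
    assert back.risk.alpha_velocity == pytest.approx(params.risk.alpha_velocity)
    assert back.risk.baseline.kind == "weibull"
    assert back.outcome_scale == params.outcome_scale


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        LongitudinalSpec(beta=np.zeros(7), D=np.eye(3) * -1.0, sigma=0.1)
    with pytest.raises(ValueError):
        BaselineHazard("weibull", shape=-1.0, scale=2.0)
    with pytest.raises(ValueError):
        BaselineHazard("piecewise_constant", breakpoints=[1.0],
                       rates=[0.1, -0.2])
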