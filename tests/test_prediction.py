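import numpy as np
import pytest

from persched.model_core import (BaselineHazard, LongitudinalSpec,
                                 ModelParameters, NaturalCubicBasis, RiskSpec)
from persched.prediction import (CENSORED_QUANTILE, PatientHistory,
                                 PatientModelContext, dynamic_survival,
                                 expected_gr_time, posterior_random_effects,
                                 quantile_gr_time, variance_gr_time)


def toy_1d_params(sigma=0.3, alpha=1.0, rate=0.1, d_var=0.25):
    """Random-intercept-only joint model: m(t) = b0, constant hazard rate."""
    basis = NaturalCubicBasis([], (0.0, 7.0))
    long_ = LongitudinalSpec(beta=np.array([0.0, 0.0, 0.0, 0.0]),
                             D=np.array([[d_var]]), sigma=sigma,
                             fixed_basis=basis, random_basis=None)
    risk = RiskSpec(gamma=np.zeros(2), alpha_value=alpha, alpha_velocity=0.0,
                    baseline=BaselineHazard("piecewise_constant",
                                            breakpoints=np.array([]),
                                            rates=np.array([rate])),
                    form="value")
    return ModelParameters(long_, risk)


def grid_posterior_moments(params, history, t, n_grid=4001, span=5.0):
    """Dense-grid quadrature oracle for the 1-D random-intercept posterior."""
    d_sd = np.sqrt(params.longitudinal.D[0, 0])
    grid = np.linspace(-span * d_sd, span * d_sd, n_grid)
    nu, sig = params.longitudinal.residual_df, params.longitudinal.sigma
    logp = -0.5 * grid ** 2 / d_sd ** 2
    for y in history.y:
        logp += -0.5 * (nu + 1) * np.log1p((y - grid) ** 2 / (nu * sig ** 2))
    rate = params.risk.baseline.rates[0]
    alpha = params.risk.alpha_value
    logp -= rate * np.exp(alpha * grid) * t       # survival to t
    w = np.exp(logp - logp.max())
    w /= w.sum()
    mean = (w * grid).sum()
    var = (w * (grid - mean) ** 2).sum()
    return mean, var, grid, w


class TestPosteriorRandomEffects:
    def test_no_information_returns_prior(self):
        params = toy_1d_params(sigma=1e4)
        hist = PatientHistory(np.array([0.0]), np.array([0.0]), 70.0,
                              t_biopsy=0.0)
        pp = posterior_random_effects(hist, params, n_draws=4000, seed=1,
                                      method="laplace_is")
        mean = pp.weights @ pp.draws[:, 0]
        var = pp.weights @ (pp.draws[:, 0] - mean) ** 2
        assert mean == pytest.approx(0.0, abs=0.05)
        assert var == pytest.approx(0.25, rel=0.1)

    @pytest.mark.parametrize("method", ["laplace_is", "mcmc"])
    def test_1d_toy_matches_grid_quadrature(self, method):
        params = toy_1d_params()
        rng = np.random.default_rng(0)
        y = 0.6 + params.longitudinal.sigma * rng.standard_t(3, size=6)
        times = np.linspace(0, 2.0, 6)
        hist = PatientHistory(times, y, 70.0, t_biopsy=2.0)
        pp = posterior_random_effects(hist, params, n_draws=4000, seed=2,
                                      method=method)
        mean_mc = pp.weights @ pp.draws[:, 0]
        var_mc = pp.weights @ (pp.draws[:, 0] - mean_mc) ** 2
        mean_gq, var_gq, _, _ = grid_posterior_moments(params, hist, t=2.0)
        assert mean_mc == pytest.approx(mean_gq, abs=0.01 * max(1, abs(mean_gq)) + 0.02)
        assert var_mc == pytest.approx(var_gq, rel=0.1)

    def test_survival_conditioning_lowers_hazard(self):
        """Knowing the patient stayed event-free to a late t shifts the
        posterior toward lower-hazard intercepts."""
        params = toy_1d_params(alpha=2.0, rate=0.15)
        y = np.array([0.5, 0.55, 0.45, 0.5])
        times = np.array([0.0, 1.0, 2.0, 3.0])
        m_short, _, _, _ = grid_posterior_moments(
            params, PatientHistory(times, y, 70.0), t=0.0)
        m_long, _, _, _ = grid_posterior_moments(
            params, PatientHistory(times, y, 70.0), t=8.0)
        assert m_long < m_short
        # the sampler reproduces the shift
        pp0 = posterior_random_effects(
            PatientHistory(times, y, 70.0, t_biopsy=0.0), params,
            n_draws=3000, seed=3, method="laplace_is")
        pp8 = posterior_random_effects(
            PatientHistory(times, y, 70.0, t_biopsy=8.0), params,
            n_draws=3000, seed=3, method="laplace_is")
        assert pp8.weights @ pp8.draws[:, 0] < pp0.weights @ pp0.draws[:, 0]

    def test_seed_required_and_degenerate_history_rejected(self, params):
        hist = PatientHistory(np.array([0.0]), np.array([2.5]), 70.0)
        with pytest.raises(ValueError):
            posterior_random_effects(hist, params, seed=None)
        with pytest.raises(ValueError):
            posterior_random_effects(PatientHistory(np.array([]), np.array([]),
                                                    70.0), params, seed=1)


@pytest.fixture(scope="module")
def simulated_pp(params):
    rng = np.random.default_rng(12)
    b = rng.multivariate_normal(np.zeros(3), params.longitudinal.D)
    times = np.arange(0, 2.1, 0.25)
    m = params.longitudinal.fixed_design(70.0, times) @ params.longitudinal.beta
    y = m + params.longitudinal.random_design(times) @ b \
        + 0.25 * rng.standard_t(3, size=len(times))
    ctx = PatientModelContext(params, 70.0, times, y, horizon=20.0,
                              grid_step=0.05)
    return ctx.posterior(2.0, 2.0, n_draws=500, rng=5, method="laplace_is")


class TestDynamicSurvival:
    @pytest.fixture
    def pp(self, simulated_pp):
        return simulated_pp

    def test_anchored_at_one(self, pp):
        assert dynamic_survival(pp, pp.t) == pytest.approx(1.0, abs=1e-9)

    def test_non_increasing(self, pp):
        grid = np.linspace(pp.t, 20.0, 200)
        vals = pp.survival(grid)
        assert np.all(np.diff(vals) <= 1e-12)

    def test_u_before_t_rejected(self, pp):
        with pytest.raises(ValueError):
            dynamic_survival(pp, pp.t - 0.5)

    def test_1d_toy_within_mc_error_of_grid_oracle(self):
        params = toy_1d_params()
        y = np.array([0.4, 0.5, 0.6])
        times = np.array([0.0, 0.5, 1.0])
        hist = PatientHistory(times, y, 70.0, t_biopsy=1.0)
        pp = posterior_random_effects(hist, params, n_draws=3000, seed=7,
                                      method="laplace_is")
        _, _, grid, w = grid_posterior_moments(params, hist, t=1.0)
        rate, alpha = 0.1, 1.0
        for u in (2.0, 4.0, 8.0):
            oracle = (w * np.exp(-rate * np.exp(alpha * grid) * (u - 1.0))).sum()
            got = pp.survival(u)
            se = np.sqrt((pp.weights ** 2).sum())  # <= 1/sqrt(ESS)
            assert got == pytest.approx(oracle, abs=3 * se + 5e-3)


class TestMoments:
    def test_exponential_closed_form(self, exponential_pp):
        pp = exponential_pp
        assert expected_gr_time(pp) == pytest.approx(pp.t + 1.0, abs=1e-6)
        assert variance_gr_time(pp) == pytest.approx(1.0, abs=1e-5)
        assert quantile_gr_time(pp, 0.5) == pytest.approx(pp.t + np.log(2.0),
                                                          abs=2e-4)

    def test_quadrature_matches_dense_trapezoid(self, exponential_pp):
        pp = exponential_pp
        grid = np.linspace(pp.t, pp.horizon, 100_001)
        pi = pp.survival(grid)
        e_trap = pp.t + np.trapezoid(pi, grid)
        v_trap = 2 * np.trapezoid((grid - pp.t) * pi, grid) \
            - np.trapezoid(pi, grid) ** 2
        assert expected_gr_time(pp) == pytest.approx(e_trap, abs=1e-5)
        assert variance_gr_time(pp) == pytest.approx(v_trap, abs=1e-5)

    def test_point_mass_posterior(self, params):
        """Degenerate (zero-variance) random effects give var ~ 0 and E at
        the deterministic event time."""
        from conftest import AnalyticPredictive
        t0 = 3.7
        pp = AnalyticPredictive(lambda u: (u < t0).astype(float), t=1.0,
                                horizon=25.0)
        e = expected_gr_time(pp)
        v = variance_gr_time(pp)
        # the step integrand limits quadrature accuracy here
        assert e == pytest.approx(t0, abs=0.05)
        assert v == pytest.approx(0.0, abs=0.15)

    def test_quantile_cdf_consistency(self, params):
        rng = np.random.default_rng(8)
        b = rng.multivariate_normal(np.zeros(3), params.longitudinal.D)
        times = np.arange(0, 1.1, 0.25)
        m = params.longitudinal.fixed_design(68.0, times) @ params.longitudinal.beta
        y = m + params.longitudinal.random_design(times) @ b
        ctx = PatientModelContext(params, 68.0, times, y, horizon=20.0,
                                  grid_step=0.05)
        pp = ctx.posterior(1.0, 1.0, n_draws=400, rng=9, method="laplace_is")
        for p in np.arange(0.1, 0.95, 0.1):
            q = quantile_gr_time(pp, p)
            if q == CENSORED_QUANTILE:
                continue
            assert pp.survival(q) == pytest.approx(1.0 - p, abs=2e-3)

    def test_censored_quantile_sentinel(self):
        from conftest import AnalyticPredictive
        pp = AnalyticPredictive(lambda u: np.full_like(u, 0.9), t=0.0,
                                horizon=20.0)
        assert quantile_gr_time(pp, 0.5) == CENSORED_QUANTILE


def test_sd_decreases_after_each_negative_biopsy(params):
    """Later negative biopsies tighten g(T*): SD drops for most patients."""
    from persched.simulator import SimulationConfig, generate_cohort
    cohort = generate_cohort(
        SimulationConfig(n_patients=40, train_fraction=0.0, seed=17), params)
    rng = np.random.default_rng(3)
    frac_ok = []
    for pat in cohort.test:
        ctx = PatientModelContext(params, pat.age, pat.psa_times, pat.y,
                                  horizon=20.0, grid_step=0.1)
        sds = []
        for t in (1.0, 2.5, 4.0):
            pp = ctx.posterior(t, t, n_draws=300, rng=rng.integers(2 ** 31),
                               method="laplace_is")
            sds.append(np.sqrt(pp.variance()))
        frac_ok.append(sds[0] >= sds[1] >= sds[2])
    assert np.mean(frac_ok) >= 0.8
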