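import numpy as np
import pytest

from persched.model_core import (BaselineHazard, LongitudinalSpec,
                                 ModelParameters, NaturalCubicBasis, RiskSpec,
                                 default_parameters)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def weibull_only_params():
    """Pure Weibull(3, 5) event times: no PSA association, no age effects."""
    base = default_parameters()
    risk = RiskSpec(gamma=np.zeros(2), alpha_value=0.0, alpha_velocity=0.0,
                    baseline=BaselineHazard("weibull", shape=3.0, scale=5.0))
    return ModelParameters(base.longitudinal, risk,
                           outcome_scale=base.outcome_scale)


@pytest.fixture(scope="session")
def linear_spec():
    """Mean trajectory reduced to 1 + 2 t (no age terms, no curvature)."""
    basis = NaturalCubicBasis([], (0.0, 7.0))       # single column: t
    return LongitudinalSpec(beta=np.array([1.0, 0.0, 0.0, 2.0]),
                            D=np.eye(2) * 0.1, sigma=0.1,
                            fixed_basis=basis, random_basis=basis)


class AnalyticPredictive:
    """Predictive with a closed-form dynamic survival, for quadrature tests."""

    def __init__(self, survival_fn, t=0.0, horizon=40.0, s=0.0):
        self._fn = survival_fn
        self.t = t
        self.s = s
        self.horizon = horizon

    def survival(self, u):
        u = np.asarray(u, dtype=float)
        if np.any(u < self.t - 1e-9):
            raise ValueError("u >= t required")
        return self._fn(np.clip(u, self.t, None))


@pytest.fixture
def exponential_pp():
    """pi(u | t) = exp(-(u - t)) with t = 2."""
    t = 2.0
    return AnalyticPredictive(lambda u: np.exp(-(u - t)), t=t, horizon=t + 40.0)
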