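"""Patient-specific posterior predictive distribution of the GR time.

For a new patient j with PSA history Y_j(s) and latest negative biopsy at t,
the predictive distribution g(T_j*) mixes the conditional event-time density
over the posterior of the random effects,

    p(b_j | T_j* > t, Y_j(s), theta)  ∝  p(Y_j | b_j) S(0 -> t | b_j) p(b_j),

with theta plugged in (oracle truth or posterior mean from fitting).  The
dynamic survival probability pi_j(u | t, s) is the Monte-Carlo average of
S(t -> u | b) over (weighted) posterior draws of b; the expected GR time,
its variance and quantiles follow from

    E[T*]  = t + int_t^inf pi(u) du,
    var[T*] = 2 int_t^inf (u - t) pi(u) du - {int_t^inf pi(u) du}^2,

with the integrals truncated at the administrative horizon (tail mass acts
as a point mass at the horizon) and evaluated by composite Gauss-Kronrod
quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import ModelParameters, linear_predictor_parts

__all__ = [
    "PatientHistory",
    "PosteriorPredictive",
    "posterior_random_effects",
    "dynamic_survival",
    "expected_gr_time",
    "variance_gr_time",
    "quantile_gr_time",
    "CENSORED_QUANTILE",
]

#: Sentinel returned by ``quantile_gr_time`` when the requested quantile is
#: not reached within the administrative horizon.
CENSORED_QUANTILE = math.inf

# 15-point Gauss-Kronrod rule on [-1, 1]
_GK15_NODES = np.array([
    -0.991455371120813, -0.949107912342759, -0.864864423359769,
    -0.741531185599394, -0.586087235467691, -0.405845151377397,
    -0.207784955007898, 0.0, 0.207784955007898, 0.405845151377397,
    0.586087235467691, 0.741531185599394, 0.864864423359769,
    0.949107912342759, 0.991455371120813])
_GK15_WEIGHTS = np.array([
    0.022935322010529, 0.063092092629979, 0.104790010322250,
    0.140653259715525, 0.169004726639267, 0.190350578064785,
    0.204432940075298, 0.209482141084728, 0.204432940075298,
    0.190350578064785, 0.169004726639267, 0.140653259715525,
    0.104790010322250, 0.063092092629979, 0.022935322010529])


def gk15_composite(f, a, b, n_sub=64):
    """Composite 15-point Gauss-Kronrod quadrature with vectorized f."""
    if b <= a:
        return 0.0
    edges = np.linspace(a, b, n_sub + 1)
    half = (edges[1] - edges[0]) / 2.0
    mids = (edges[:-1] + edges[1:]) / 2.0
    nodes = (mids[:, None] + half * _GK15_NODES[None, :]).ravel()
    vals = np.asarray(f(nodes)).reshape(n_sub, -1)
    return float((vals @ _GK15_WEIGHTS).sum() * half)


@dataclass
class PatientHistory:
    """One subject's observed data up to the current decision point."""

    psa_times: np.ndarray
    y: np.ndarray                 # outcome on the model (log2 PSA) scale
    age: float
    t_biopsy: float = 0.0         # latest negative biopsy time t
    prior_biopsies: tuple = ()

    def __post_init__(self):
        self.psa_times = np.asarray(self.psa_times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t_biopsy < 0:
            raise ValueError("latest biopsy time must be >= 0")
        if len(self.psa_times) != len(self.y):
            raise ValueError("psa_times and y must have equal length")

    @property
    def s(self) -> float:
        """Time of the latest PSA measurement."""
        return float(self.psa_times.max()) if len(self.psa_times) else 0.0

    @classmethod
    def from_psa(cls, psa_times, psa_values, age, params: ModelParameters,
                 t_biopsy=0.0, prior_biopsies=()):
        return cls(psa_times, params.outcome_from_psa(psa_values), age,
                   t_biopsy, prior_biopsies)


class PatientModelContext:
    """Cached per-patient quantities for repeated posterior computation.

    Holds the log-hazard decomposition log h(v|b) = c(v) + d(v)'b on a dense
    time grid (the log-hazard is linear in b), the longitudinal design
    matrices, and the prior Cholesky factors.  One context serves every
    decision point (t, s) of a patient, which is what makes schedule
    evaluation over thousands of simulated patients tractable.
    """

    def __init__(self, params: ModelParameters, age, psa_times, y,
                 horizon=20.0, grid_step=0.05):
        long_ = params.longitudinal
        self.params = params
        self.age = float(age)
        self.horizon = float(horizon)
        self.psa_times = np.asarray(psa_times, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.X = long_.fixed_design(age, self.psa_times)
        self.Z = long_.random_design(self.psa_times)
        self.mu_fixed = self.X @ long_.beta
        self.sigma = long_.sigma
        self.nu = long_.residual_df
        D = long_.D
        jitter = 1e-10 * np.eye(len(D))
        self.D_chol = np.linalg.cholesky(D + jitter)
        self.D_inv = np.linalg.inv(D + jitter)
        if np.linalg.cond(D + jitter) > 1e12:
            raise ValueError("degenerate random-effects covariance D")
        self.grid = np.arange(0.0, horizon + grid_step / 2.0, grid_step)
        self.grid_step = grid_step
        self._c_fn, self._d_fn = linear_predictor_parts(params, age)
        self.c_grid = self._c_fn(self.grid)
        self.c_grid[~np.isfinite(self.c_grid)] = -745.0  # h0(0)=0 for k>1
        self.d_grid = self._d_fn(self.grid)
        self._surv_cache = {}
        self._point_cache = {}
        self._last_mode = None

    # --- posterior of b given (Y(s), T* > t) -------------------------------

    def _obs_mask(self, s):
        return self.psa_times <= s + 1e-9

    def _survival_terms(self, t):
        """Node weights/values for H(0 -> t | b) = sum_k w_k exp(c_k+d_k'b)."""
        key = round(float(t), 9)
        cached = self._surv_cache.get(key)
        if cached is not None:
            return cached
        if t <= 0:
            out = (np.zeros(0), np.zeros(0),
                   np.zeros((0, self.d_grid.shape[1])))
        else:
            j = int(np.searchsorted(self.grid, t - 1e-12, side="right"))
            nodes = np.concatenate([self.grid[:j], [t]])
            gaps = np.diff(nodes)
            wt = np.zeros(len(nodes))
            wt[:-1] += gaps / 2.0
            wt[1:] += gaps / 2.0
            c = np.concatenate([self.c_grid[:j], self._c_at(t)])
            d = np.vstack([self.d_grid[:j], self._d_at(t)])
            out = (wt, c, d)
        if len(self._surv_cache) > 64:
            self._surv_cache.clear()
        self._surv_cache[key] = out
        return out

    def _c_at(self, t):
        key = round(float(t), 9)
        hit = self._point_cache.get(key)
        if hit is None:
            c = np.atleast_1d(self._c_fn(np.array([float(t)])))
            c[~np.isfinite(c)] = -745.0
            hit = (c, self._d_fn(np.array([float(t)])))
            if len(self._point_cache) > 256:
                self._point_cache.clear()
            self._point_cache[key] = hit
        return hit[0]

    def _d_at(self, t):
        self._c_at(t)
        return self._point_cache[round(float(t), 9)][1]

    def log_posterior(self, b, t, s, include_survival=True):
        """Unnormalized log p(b | Y(s), T* > t); b may be (q,) or (n, q)."""
        b = np.atleast_2d(b)
        mask = self._obs_mask(s)
        r = (self.y[mask] - self.mu_fixed[mask])[None, :] - b @ self.Z[mask].T
        nu, sig = self.nu, self.sigma
        ll_y = -0.5 * (nu + 1.0) * np.log1p(r * r / (nu * sig * sig)).sum(axis=1)
        lp = -0.5 * np.einsum("ni,ij,nj->n", b, self.D_inv, b)
        out = ll_y + lp
        if include_survival and t > 0:
            wt, c, d = self._survival_terms(t)
            H = (np.exp(c[None, :] + b @ d.T) * wt[None, :]).sum(axis=1)
            out = out - H
        return out if out.shape[0] > 1 else float(out[0])

    def _value_grad_hess(self, b, t, s):
        """Log posterior with gradient and Hessian, in one pass (b: (q,))."""
        mask = self._obs_mask(s)
        Z = self.Z[mask]
        r = self.y[mask] - self.mu_fixed[mask] - Z @ b
        nu, s2 = self.nu, self.sigma ** 2
        rr = r * r
        denom = nu * s2 + rr
        Db = self.D_inv @ b
        f = (-0.5 * (nu + 1.0) * np.log1p(rr / (nu * s2)).sum()
             - 0.5 * (b @ Db))
        g = ((nu + 1.0) * r / denom) @ Z - Db
        curv = (nu + 1.0) * (nu * s2 - rr) / denom ** 2
        Hm = -(Z * curv[:, None]).T @ Z - self.D_inv
        if t > 0:
            wt, c, d = self._survival_terms(t)
            e = wt * np.exp(c + d @ b)
            f -= e.sum()
            g = g - e @ d
            Hm = Hm - (d * e[:, None]).T @ d
        return f, g, Hm

    def find_mode(self, t, s, b0=None, max_iter=30, tol=1e-6):
        """Damped Newton ascent of the log posterior."""
        q = self.D_inv.shape[0]
        b = np.zeros(q) if b0 is None else np.array(b0, dtype=float)
        f, g, Hm = self._value_grad_hess(b, t, s)
        for _ in range(max_iter):
            # ensure negative definite for an ascent direction
            ridge = 0.0
            while True:
                try:
                    np.linalg.cholesky(-(Hm - ridge * np.eye(q)))
                    break
                except np.linalg.LinAlgError:
                    ridge = max(ridge * 10.0, 1e-6)
            step = np.linalg.solve(-(Hm - ridge * np.eye(q)), g)
            if not np.all(np.isfinite(step)):
                break
            lam, bn, fn = 1.0, b, f
            for _ in range(25):
                bn = b + lam * step
                fn, gn, Hn = self._value_grad_hess(bn, t, s)
                if fn >= f - 1e-12:
                    break
                lam *= 0.5
            if fn < f and lam < 1e-7:
                break
            moved = np.max(np.abs(bn - b))
            b, f, g, Hm = bn, fn, gn, Hn
            if moved < tol or np.max(np.abs(g)) < 1e-4:
                break
        # eigenvalue clipping guards against indefinite t-likelihood Hessians
        w, V = np.linalg.eigh(-(Hm + Hm.T) / 2.0)
        w = np.clip(w, max(1e-8, 1e-6 * float(np.abs(w).max())), None)
        cov = (V / w) @ V.T
        return b, cov

    def posterior(self, t, s, n_draws=500, rng=None, method="mcmc",
                  mode_start=None):
        """Weighted posterior draws of b, wrapped as a PosteriorPredictive."""
        rng = np.random.default_rng(rng)
        if mode_start is None:
            mode_start = self._last_mode
        mode, cov = self.find_mode(t, s, b0=mode_start)
        self._last_mode = mode
        q = len(mode)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            L = np.linalg.cholesky(cov + 1e-8 * np.eye(q))
        diag = {"method": method, "n_draws": n_draws, "mode": mode}
        if method == "laplace_is":
            # heavier-tailed multivariate-t proposal, importance reweighting
            df = 7.0
            zn = rng.standard_normal((n_draws, q))
            chi = rng.chisquare(df, size=n_draws)
            B = mode[None, :] + (zn @ L.T) / np.sqrt(chi / df)[:, None]
            delta = np.linalg.solve(L, (B - mode).T)
            maha = (delta ** 2).sum(axis=0)
            logq = -0.5 * (df + q) * np.log1p(maha / df)
            logp = self.log_posterior(B, t, s)
            logw = logp - logq
            logw -= logw.max()
            w = np.exp(logw)
            w /= w.sum()
            diag["ess"] = float(1.0 / (w ** 2).sum())
        elif method == "mcmc":
            # random-walk Metropolis started at the Laplace mode
            burn, thin = 200, 2
            total = burn + thin * n_draws
            scale = 2.4 / math.sqrt(q)
            steps = scale * (rng.standard_normal((total, q)) @ L.T)
            logu = np.log(rng.uniform(size=total))
            b = mode.copy()
            lp = self.log_posterior(b, t, s)
            keep = np.empty((n_draws, q))
            acc = 0
            k = 0
            for i in range(total):
                bp = b + steps[i]
                lpp = self.log_posterior(bp, t, s)
                if lpp - lp > logu[i]:
                    b, lp = bp, lpp
                    acc += 1
                if i >= burn and (i - burn) % thin == 0:
                    keep[k] = b
                    k += 1
            B = keep[:k]
            w = np.full(len(B), 1.0 / len(B))
            diag["acceptance"] = acc / total
        else:
            raise ValueError(f"unknown method {method!r}")
        return PosteriorPredictive(context=self, t=float(t), s=float(s),
                                   draws=B, weights=w, diagnostics=diag)


@dataclass
class PosteriorPredictive:
    """Monte-Carlo representation of g(T_j*) given (T* > t, Y(s))."""

    context: PatientModelContext
    t: float
    s: float
    draws: np.ndarray
    weights: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")
        ctx = self.context
        self.horizon = ctx.horizon
        mask = ctx.grid > self.t + 1e-12
        sub = np.concatenate([[self.t], ctx.grid[mask]])
        c = np.concatenate([ctx._c_at(self.t), ctx.c_grid[mask]])
        d = np.vstack([ctx._d_at(self.t), ctx.d_grid[mask]])
        if len(sub) < 2:
            end = max(self.horizon, self.t + 1e-6)
            sub = np.append(sub, end)
            c = np.append(c, ctx._c_at(end))
            d = np.vstack([d, ctx._d_at(end)])
        h = np.exp(c[:, None] + d @ self.draws.T)     # (G, n)
        gaps = np.diff(sub)
        Hrel = np.zeros_like(h)
        np.cumsum((h[1:] + h[:-1]) * 0.5 * gaps[:, None], axis=0, out=Hrel[1:])
        self._sub_grid = sub
        self._Hrel = Hrel
        self._pi_grid = None

    def survival(self, u):
        """Dynamic survival probability pi_j(u | t, s), vectorized in u."""
        u = np.asarray(u, dtype=float)
        scalar = u.ndim == 0
        uu = np.atleast_1d(u)
        if np.any(uu < self.t - 1e-9):
            raise ValueError("survival requires u >= t")
        uu = np.clip(uu, self.t, self.horizon)
        g = self._sub_grid
        idx = np.clip(np.searchsorted(g, uu, side="right"), 1, len(g) - 1)
        frac = (uu - g[idx - 1]) / (g[idx] - g[idx - 1])
        H = self._Hrel[idx - 1] + frac[:, None] * (self._Hrel[idx] - self._Hrel[idx - 1])
        pi = np.exp(-H) @ self.weights
        return float(pi[0]) if scalar else pi

    def expected(self, n_sub=32):
        return self.t + gk15_composite(self.survival, self.t, self.horizon, n_sub)

    def variance(self, n_sub=32):
        i1 = gk15_composite(self.survival, self.t, self.horizon, n_sub)
        i2 = gk15_composite(lambda u: (u - self.t) * self.survival(u),
                            self.t, self.horizon, n_sub)
        return max(2.0 * i2 - i1 * i1, 0.0)

    def quantile(self, p, tol=1e-4):
        """pi^{-1}(1 - p): time at which the dynamic risk reaches p.

        Monotone bisection: the bracketing grid cell is refined twice with
        vectorized survival evaluations down to the requested tolerance.
        """
        if not 0.0 < p < 1.0:
            raise ValueError("p must lie in (0, 1)")
        target = 1.0 - p
        if self._pi_grid is None:
            self._pi_grid = np.exp(-self._Hrel) @ self.weights
        pi = self._pi_grid
        g = self._sub_grid
        if pi[-1] > target:
            return CENSORED_QUANTILE
        j = int(np.argmax(pi <= target))
        if j == 0:
            return float(g[0])
        lo, hi = g[j - 1], g[j]
        while hi - lo > tol:
            us = np.linspace(lo, hi, 33)
            pv = self.survival(us)
            k = int(np.argmax(pv <= target))
            if k == 0:
                return float(us[0])
            lo, hi = us[k - 1], us[k]
        return float(0.5 * (lo + hi))

    def sample_event_times(self, rng, truncate=True):
        """One T* draw per posterior b-draw, by inverse-transform on the grid.

        Times beyond the horizon are set to the horizon (the point-mass
        convention used for the truncated moments) when ``truncate``.
        """
        rng = np.random.default_rng(rng)
        n = len(self.draws)
        targets = -np.log(rng.uniform(1e-300, 1.0, size=n))
        H = self._Hrel
        g = self._sub_grid
        ts = np.full(n, self.horizon if truncate else np.inf)
        for i in range(n):
            col = H[:, i]
            j = int(np.searchsorted(col, targets[i]))
            if j == 0:
                ts[i] = g[0]
            elif j < len(g):
                frac = (targets[i] - col[j - 1]) / max(col[j] - col[j - 1], 1e-300)
                ts[i] = g[j - 1] + frac * (g[j] - g[j - 1])
        return ts


def posterior_random_effects(history: PatientHistory, params: ModelParameters,
                             n_draws=500, seed=None, method="mcmc",
                             horizon=20.0, grid_step=0.05) -> PosteriorPredictive:
    """Draw from p(b | T* > t, Y(s), theta) and wrap as a PosteriorPredictive."""
    if len(history.psa_times) < 1:
        raise ValueError("history must contain at least one PSA measurement")
    if history.t_biopsy > horizon:
        raise ValueError("latest biopsy beyond the administrative horizon")
    if seed is None:
        raise ValueError("a seed is required for posterior sampling")
    ctx = PatientModelContext(params, history.age, history.psa_times,
                              history.y, horizon=horizon, grid_step=grid_step)
    return ctx.posterior(history.t_biopsy, history.s, n_draws=n_draws,
                         rng=seed, method=method)


def dynamic_survival(pp, u) -> float:
    """pi_j(u | t, s); requires u >= t."""
    return pp.survival(u)


def expected_gr_time(pp) -> float:
    """E_g(T*) = t + int_t^H pi(u) du (tail mass as point mass at H)."""
    return pp.expected() if hasattr(pp, "expected") else (
        pp.t + gk15_composite(pp.survival, pp.t, pp.horizon))


def variance_gr_time(pp) -> float:
    """var_g(T*) = 2 int (u-t) pi du - (int pi du)^2, truncated at H."""
    if hasattr(pp, "variance"):
        return pp.variance()
    i1 = gk15_composite(pp.survival, pp.t, pp.horizon)
    i2 = gk15_composite(lambda u: (u - pp.t) * pp.survival(u), pp.t, pp.horizon)
    return max(2.0 * i2 - i1 * i1, 0.0)


def quantile_gr_time(pp, p, tol=1e-4) -> float:
    """quantile(p) = pi^{-1}(1-p); CENSORED_QUANTILE when beyond horizon."""
    if hasattr(pp, "quantile"):
        return pp.quantile(p, tol=tol)
    target = 1.0 - p
    if pp.survival(pp.horizon) > target:
        return CENSORED_QUANTILE
    lo, hi = pp.t, pp.horizon
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if pp.survival(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
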