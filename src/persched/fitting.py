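"""Bayesian fitting of the joint model to interval-censored training data.

The likelihood of one training patient combines the scaled-t longitudinal
contributions with the biopsy-based event information

    p(y_i | b_i) * [S(0 -> l_i | b_i) - S(0 -> r_i | b_i)]   (GR in (l, r])
    p(y_i | b_i) *  S(0 -> l_i | b_i)                        (right-censored)

integrated over the random effects.  Sampling is Metropolis-within-Gibbs:
random-walk Metropolis blocks for beta, (gamma, alpha), the log baseline
rates and log sigma, vectorized per-patient random-walk updates for the b_i,
and a conjugate inverse-Wishart Gibbs step for D.  The baseline hazard is
piecewise-constant (5 pieces by default) with breakpoints at quantiles of
the observed event intervals; cumulative hazards use fixed Gauss-Legendre
quadrature on per-patient node caches.  Proposal scales adapt during
burn-in (Robbins-Monro toward standard acceptance targets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .model_core import (BaselineHazard, LongitudinalSpec, ModelParameters,
                         RiskSpec)

__all__ = ["McmcConfig", "FitResult", "fit_joint_model", "frames_from_cohort"]


@dataclass
class McmcConfig:
    n_iter: int = 3000
    burn: int = 1000
    seed: int = 0
    thin: int = 1
    n_baseline_pieces: int = 5
    gl_points: int = 5     # per quadrature panel (panels split at breakpoints)
    b_sweeps: int = 2      # random-effect updates per parameter sweep


@dataclass
class FitResult:
    draws: dict
    means: dict
    diagnostics: dict
    skeleton: ModelParameters
    breakpoints: np.ndarray

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("max_rhat", np.inf) <= 1.1)

    def credible_interval(self, name, index=None, level=0.95):
        arr = self.draws[name]
        if index is not None:
            arr = arr[:, index] if arr.ndim > 1 else arr
        lo = (1.0 - level) / 2.0
        return tuple(np.quantile(arr, [lo, 1.0 - lo]))

    def to_model_parameters(self) -> ModelParameters:
        """Posterior-mean parameters in the standard container."""
        sk = self.skeleton.longitudinal
        long_ = LongitudinalSpec(
            beta=self.means["beta"], D=self.means["D"],
            sigma=self.means["sigma"], residual_df=sk.residual_df,
            fixed_basis=sk.fixed_basis, random_basis=sk.random_basis)
        baseline = BaselineHazard("piecewise_constant",
                                  breakpoints=self.breakpoints,
                                  rates=np.exp(self.means["log_rates"]))
        risk = RiskSpec(gamma=self.means["gamma"],
                        alpha_value=self.means["alpha"][0],
                        alpha_velocity=self.means["alpha"][1],
                        baseline=baseline)
        return ModelParameters(long_, risk,
                               outcome_scale=self.skeleton.outcome_scale)


def frames_from_cohort(cohort):
    """Training-data frames (longitudinal, events) from a simulated cohort."""
    long_rows, ev_rows = [], []
    for p in cohort.train:
        for t, v in zip(p.psa_times, p.psa_values):
            long_rows.append((p.id, t, v))
        ev_rows.append((p.id, p.l, p.r, p.age))
    return (pd.DataFrame(long_rows, columns=["id", "time", "psa"]),
            pd.DataFrame(ev_rows, columns=["id", "l", "r", "age"]))


class _FitData:
    """Concatenated design/node caches for vectorized likelihoods."""

    def __init__(self, long_df, events_df, skeleton: ModelParameters,
                 n_pieces, gl_points):
        long_spec = skeleton.longitudinal
        events_df = events_df.reset_index(drop=True)
        ids = events_df["id"].to_numpy()
        self.n = len(ids)
        row_of = {pid: k for k, pid in enumerate(ids)}
        ages = events_df["age"].to_numpy(dtype=float)
        a = ages - long_spec.age_center
        self.W = np.column_stack([a, a * a])
        l = events_df["l"].to_numpy(dtype=float)
        r = events_df["r"].to_numpy(dtype=float)
        r = np.where(np.isfinite(r), r, np.inf)
        self.event = np.isfinite(r)
        # longitudinal observations
        ldf = long_df[long_df["id"].isin(row_of)].copy()
        self.obs_pid = ldf["id"].map(row_of).to_numpy()
        times = ldf["time"].to_numpy(dtype=float)
        self.y = skeleton.outcome_from_psa(ldf["psa"].to_numpy(dtype=float))
        self.Xo = np.vstack([long_spec.fixed_design(ages[p], np.array([t]))
                             for p, t in zip(self.obs_pid, times)])
        self.Zo = long_spec.random_design(times)
        self.nu = long_spec.residual_df
        # baseline breakpoints from the observed interval structure
        mids = np.concatenate([0.5 * (l[self.event] + r[self.event]),
                               l[~self.event][l[~self.event] > 0]])
        if len(mids) < n_pieces:
            mids = np.linspace(0.5, 10.0, 10)
        qs = np.linspace(0, 1, n_pieces + 1)[1:-1]
        bp = np.unique(np.round(np.quantile(mids, qs), 6))
        bp = bp[bp > 0]
        if len(bp) + 1 < n_pieces:  # degenerate spread: fall back to fixed
            bp = np.linspace(1.0, 10.0, n_pieces - 1)
        self.breakpoints = bp
        self.n_pieces = len(bp) + 1
        # Gauss-Legendre node caches for H(0 -> l) and H(l -> r); panels are
        # split at the baseline breakpoints so the piecewise-constant jumps
        # never fall inside a quadrature panel
        gx, gw = np.polynomial.legendre.leggauss(gl_points)

        def build_nodes(lo, hi, keep):
            pids, tt, ww = [], [], []
            for i in np.nonzero(keep)[0]:
                if hi[i] - lo[i] <= 0:
                    continue
                inner = bp[(bp > lo[i] + 1e-12) & (bp < hi[i] - 1e-12)]
                edges = np.concatenate([[lo[i]], inner, [hi[i]]])
                for a_, b_ in zip(edges[:-1], edges[1:]):
                    half = (b_ - a_) / 2.0
                    tt.append(a_ + half * (gx + 1.0))
                    ww.append(gw * half)
                    pids.append(np.full(gl_points, i))
            if not tt:
                return (np.zeros(0, int), np.zeros(0), np.zeros(0),
                        np.zeros((0, long_spec.n_fixed)),
                        np.zeros((0, long_spec.n_random)),
                        np.zeros((0, long_spec.n_fixed)),
                        np.zeros((0, long_spec.n_random)),
                        np.zeros(0, int))
            pid = np.concatenate(pids)
            t = np.concatenate(tt)
            w = np.concatenate(ww)
            X = np.vstack([long_spec.fixed_design(ages[p], np.array([v]))
                           for p, v in zip(pid, t)])
            Z = long_spec.random_design(t)
            Xd = np.vstack([long_spec.fixed_design(ages[p], np.array([v]),
                                                   deriv=True)
                            for p, v in zip(pid, t)])
            Zd = long_spec.random_design(t, deriv=True)
            piece = np.searchsorted(bp, t, side="right")
            return pid, t, w, X, Z, Xd, Zd, piece

        self.nl = build_nodes(np.zeros(self.n), l, np.ones(self.n, bool))
        self.ne = build_nodes(l, np.where(self.event, r, l), self.event)
        self.q = long_spec.n_random
        self.p = long_spec.n_fixed
        # projection caches: beta and gamma change rarely between likelihood
        # calls (most calls come from random-effect sweeps), so X@beta-style
        # products are memoized on the parameter bytes
        self._proj_cache = {}

    def proj(self, key, M, v):
        tag = (key, v.tobytes())
        hit = self._proj_cache.get(tag)
        if hit is None:
            if len(self._proj_cache) > 24:
                self._proj_cache.clear()
            hit = M @ v
            self._proj_cache[tag] = hit
        return hit


def _cumhaz(data: _FitData, nodes, key, beta, gamma, alpha, log_rates, b):
    pid, t, w, X, Z, Xd, Zd, piece = nodes
    if len(pid) == 0:
        return np.zeros(data.n)
    m = data.proj(key + "x", X, beta) + (Z * b[pid]).sum(axis=1)
    mp = data.proj(key + "d", Xd, beta) + (Zd * b[pid]).sum(axis=1)
    logh = (log_rates[piece] + data.proj("w", data.W, gamma)[pid]
            + alpha[0] * m + alpha[1] * mp)
    return np.bincount(pid, weights=w * np.exp(np.clip(logh, -700, 60)),
                       minlength=data.n)


def _sample_invwishart(df, S, rng):
    """D ~ IW(df, S) via the Bartlett decomposition of Wishart(df, S^-1)."""
    q = S.shape[0]
    L = np.linalg.cholesky(np.linalg.inv(S))
    A = np.zeros((q, q))
    for i in range(q):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
        A[i, :i] = rng.standard_normal(i)
    F = L @ A
    return np.linalg.inv(F @ F.T)


def _loglik_long_per_patient(data: _FitData, beta, log_sigma, b):
    r = (data.y - data.proj("o", data.Xo, beta)
         - (data.Zo * b[data.obs_pid]).sum(axis=1))
    nu = data.nu
    sig2 = np.exp(2.0 * log_sigma)
    const = (gammaln((nu + 1) / 2) - gammaln(nu / 2)
             - 0.5 * np.log(nu * np.pi) - log_sigma)
    terms = const - 0.5 * (nu + 1.0) * np.log1p(r * r / (nu * sig2))
    return np.bincount(data.obs_pid, weights=terms, minlength=data.n)


def _loglik_event_per_patient(data, beta, gamma, alpha, log_rates, b):
    Hl = _cumhaz(data, data.nl, "l", beta, gamma, alpha, log_rates, b)
    He = _cumhaz(data, data.ne, "e", beta, gamma, alpha, log_rates, b)
    out = -Hl
    ev = data.event
    with np.errstate(divide="ignore"):
        out[ev] += np.log(-np.expm1(-np.clip(He[ev], 1e-300, None)))
    return out


def fit_joint_model(long_df, events_df, skeleton: ModelParameters,
                    mcmc: McmcConfig | None = None) -> FitResult:
    """MCMC fit; returns posterior draws, means and convergence diagnostics."""
    mcmc = mcmc or McmcConfig()
    rng = np.random.default_rng(mcmc.seed)
    data = _FitData(long_df, events_df, skeleton, mcmc.n_baseline_pieces,
                    mcmc.gl_points)
    n, p, q = data.n, data.p, data.q
    npc = data.n_pieces

    # --- initialization -----------------------------------------------------
    XtX = data.Xo.T @ data.Xo + 1e-6 * np.eye(p)
    beta = np.linalg.solve(XtX, data.Xo.T @ data.y)
    resid0 = data.y - data.Xo @ beta
    log_sigma = np.log(max(np.std(resid0) * 0.7, 1e-3))
    exposure = np.concatenate([data.nl[2], data.ne[2]]).sum()
    crude = max(data.event.sum(), 1) / max(exposure, 1e-6)
    log_rates = np.full(npc, np.log(crude))
    D = 0.1 * np.eye(q)
    D_inv = np.linalg.inv(D)
    # BLUP-style starting values for the random effects
    sig2_0 = float(np.exp(2 * log_sigma))
    b = np.zeros((n, q))
    resid_obs = data.y - data.Xo @ beta
    for i in range(n):
        sel = data.obs_pid == i
        Zi = data.Zo[sel]
        A = Zi.T @ Zi / sig2_0 + D_inv
        b[i] = np.linalg.solve(A, Zi.T @ resid_obs[sel] / sig2_0)
    # start the hazard block at its conditional maximum given the BLUPs
    from scipy.optimize import minimize as _minimize

    def _neg_ev(hz):
        # MAP objective: the prior keeps the conditional optimum away from
        # separation-style divergence when the BLUP velocities are shrunken
        pen = (0.5 * (hz[:2] @ hz[:2]) / 25.0 + 0.5 * (hz[2:4] @ hz[2:4]) / 25.0
               + 0.5 * ((hz[4:] - np.log(0.05)) ** 2).sum() / 9.0)
        return pen - _loglik_event_per_patient(data, beta, hz[:2], hz[2:4],
                                               hz[4:], b).sum()

    hz0 = np.concatenate([np.zeros(4), log_rates])
    opt = _minimize(_neg_ev, hz0, method="Nelder-Mead",
                    options={"maxiter": 2000, "xatol": 1e-3, "fatol": 1e-3})
    hz_init = np.clip(opt.x, np.concatenate([[-2, -0.5, -8, -8],
                                             np.full(npc, -8.0)]),
                      np.concatenate([[2, 0.5, 8, 8], np.full(npc, 2.0)]))
    gamma, alpha, log_rates = hz_init[:2], hz_init[2:4], hz_init[4:]

    beta_prop = np.linalg.cholesky(np.linalg.inv(XtX) + 1e-8 * np.eye(p))
    # one hazard block: (gamma, alpha, log_rates) are posterior-correlated,
    # so they move together under a Haario-style adaptive covariance
    nh = 4 + npc
    haz_scale_base = np.concatenate([[0.02, 0.002, 0.1, 0.3],
                                     np.full(npc, 0.15)])
    haz_mean = np.zeros(nh)
    haz_M2 = np.zeros((nh, nh))
    haz_count = 0
    haz_chol = None

    # priors
    def log_prior(beta, gamma, alpha, log_rates, log_sigma):
        return (-0.5 * (beta @ beta) / 100.0
                - 0.5 * (gamma @ gamma) / 25.0
                - 0.5 * (alpha @ alpha) / 25.0
                - 0.5 * ((log_rates - np.log(0.05)) ** 2).sum() / 9.0
                - 0.5 * (log_sigma - np.log(0.2)) ** 2 / 9.0)

    ll_long = _loglik_long_per_patient(data, beta, log_sigma, b)
    ll_ev = _loglik_event_per_patient(data, beta, gamma, alpha, log_rates, b)

    scales = {"beta": 0.3, "haz": 0.3, "sigma": 0.05}
    b_scale = np.full(n, 0.8)
    trans_scale = np.full(q, 0.1)
    acc_counts = {k: 0 for k in scales}
    n_keep = (mcmc.n_iter - mcmc.burn) // mcmc.thin
    store = {"beta": np.empty((n_keep, p)), "gamma": np.empty((n_keep, 2)),
             "alpha": np.empty((n_keep, 2)),
             "log_rates": np.empty((n_keep, npc)),
             "sigma": np.empty(n_keep), "D": np.empty((n_keep, q, q))}
    kept = 0
    nu0, Psi0 = q + 2.0, 0.1 * np.eye(q)
    L_D = np.linalg.cholesky(D)

    for it in range(mcmc.n_iter):
        adapt = it < mcmc.burn
        gain = 1.0 / (1.0 + it) ** 0.6

        # random effects: vectorized per-patient random walk (several sweeps
        # per parameter update to loosen the alpha-b coupling)
        for _ in range(mcmc.b_sweeps):
            prop = b + b_scale[:, None] * (rng.standard_normal((n, q)) @ L_D.T)
            ll_long_p = _loglik_long_per_patient(data, beta, log_sigma, prop)
            ll_ev_p = _loglik_event_per_patient(data, beta, gamma, alpha,
                                                log_rates, prop)
            pr_cur = -0.5 * np.einsum("ni,ij,nj->n", b, D_inv, b)
            pr_new = -0.5 * np.einsum("ni,ij,nj->n", prop, D_inv, prop)
            log_acc = (ll_long_p + ll_ev_p + pr_new) - (ll_long + ll_ev + pr_cur)
            accept = np.log(rng.uniform(size=n)) < log_acc
            b[accept] = prop[accept]
            ll_long = np.where(accept, ll_long_p, ll_long)
            ll_ev = np.where(accept, ll_ev_p, ll_ev)
            if adapt:
                b_scale *= np.exp(gain * (accept.astype(float) - 0.3))
                b_scale = np.clip(b_scale, 1e-3, 10.0)

        # D: conjugate inverse-Wishart Gibbs step (Bartlett sampler)
        S = Psi0 + b.T @ b
        D = _sample_invwishart(nu0 + n, S, rng)
        D_inv = np.linalg.inv(D)
        L_D = np.linalg.cholesky(D)

        def mh(name, cur_vec, propose, recompute):
            nonlocal ll_long, ll_ev
            cand = propose(cur_vec)
            new_long, new_ev = recompute(cand)
            lp_new = log_prior(*_theta_with(name, cand))
            lp_cur = log_prior(beta, gamma, alpha, log_rates, log_sigma)
            num = new_long.sum() + new_ev.sum() + lp_new
            den = ll_long.sum() + ll_ev.sum() + lp_cur
            if np.log(rng.uniform()) < num - den:
                ll_long, ll_ev = new_long, new_ev
                acc_counts[name] += 1
                if adapt:
                    scales[name] *= np.exp(gain * 0.766)
                return cand, True
            if adapt:
                scales[name] *= np.exp(gain * -0.234)
            return cur_vec, False

        def _theta_with(name, cand):
            th = {"beta": beta,
                  "haz": np.concatenate([gamma, alpha, log_rates]),
                  "sigma": log_sigma}
            th[name] = cand
            hz = th["haz"]
            return th["beta"], hz[:2], hz[2:4], hz[4:], th["sigma"]

        beta, _ = mh(
            "beta", beta,
            lambda v: v + scales["beta"] * (beta_prop @ rng.standard_normal(p)),
            lambda c: (_loglik_long_per_patient(data, c, log_sigma, b),
                       _loglik_event_per_patient(data, c, gamma, alpha,
                                                 log_rates, b)))
        def haz_propose(v):
            z = rng.standard_normal(nh)
            if haz_chol is not None:
                return v + scales["haz"] * (haz_chol @ z)
            return v + scales["haz"] * haz_scale_base * z

        hz, _ = mh(
            "haz", np.concatenate([gamma, alpha, log_rates]), haz_propose,
            lambda c: (ll_long,
                       _loglik_event_per_patient(data, beta, c[:2], c[2:4],
                                                 c[4:], b)))
        gamma, alpha, log_rates = hz[:2], hz[2:4], hz[4:]
        haz_count += 1
        delta = hz - haz_mean
        haz_mean += delta / haz_count
        haz_M2 += np.outer(delta, hz - haz_mean)
        if adapt and haz_count > 300 and haz_count % 50 == 0:
            cov = haz_M2 / (haz_count - 1) + 1e-9 * np.eye(nh)
            haz_chol = np.linalg.cholesky((2.4 ** 2 / nh) * cov)
            scales["haz"] = 1.0
        log_sigma, _ = mh(
            "sigma", log_sigma,
            lambda v: v + scales["sigma"] * rng.standard_normal(),
            lambda c: (_loglik_long_per_patient(data, beta, c, b), ll_ev))

        # translation moves along the confounded fixed/random directions
        # (intercept <-> b0, time slope <-> b1): m_i is invariant, so only
        # the priors enter the acceptance ratio; this decorrelates beta from
        # the random-effect means
        for bj, bk in ((0, 0), (3, 1)):
            if bk >= q:
                continue
            delta = trans_scale[bk] * rng.standard_normal()
            b_new = b.copy()
            b_new[:, bk] -= delta
            dprior_beta = -0.5 * ((beta[bj] + delta) ** 2
                                  - beta[bj] ** 2) / 100.0
            pr_cur = -0.5 * np.einsum("ni,ij,nj->n", b, D_inv, b).sum()
            pr_new = -0.5 * np.einsum("ni,ij,nj->n", b_new, D_inv,
                                      b_new).sum()
            acc = np.log(rng.uniform()) < dprior_beta + pr_new - pr_cur
            if acc:
                beta = beta.copy()
                beta[bj] += delta
                b = b_new
            if adapt:
                trans_scale[bk] *= np.exp(gain * ((1.0 if acc else 0.0) - 0.3))
                trans_scale[bk] = min(max(trans_scale[bk], 1e-3), 5.0)

        if it >= mcmc.burn and (it - mcmc.burn) % mcmc.thin == 0:
            store["beta"][kept] = beta
            store["gamma"][kept] = gamma
            store["alpha"][kept] = alpha
            store["log_rates"][kept] = log_rates
            store["sigma"][kept] = np.exp(log_sigma)
            store["D"][kept] = D
            kept += 1

    draws = {k: v[:kept] for k, v in store.items()}
    means = {k: v.mean(axis=0) for k, v in draws.items()}
    diagnostics = _diagnostics(draws, acc_counts, mcmc)
    return FitResult(draws=draws, means=means, diagnostics=diagnostics,
                     skeleton=skeleton, breakpoints=data.breakpoints)


def _diagnostics(draws, acc_counts, mcmc):
    import arviz as az

    rhats, esss = {}, {}
    for name in ("alpha", "beta", "sigma"):
        arr = draws[name]
        if arr.ndim == 1:
            arr = arr[:, None]
        half = (len(arr) // 2) * 2
        for j in range(arr.shape[1]):
            split = arr[:half, j].reshape(2, -1)
            rhats[f"{name}[{j}]"] = float(az.rhat(split))
            esss[f"{name}[{j}]"] = float(az.ess(split))
    diagnostics = {
        "rhat": rhats, "ess": esss,
        "max_rhat": max(rhats.values()) if rhats else np.inf,
        "acceptance": {k: v / max(mcmc.n_iter, 1)
                       for k, v in acc_counts.items()},
    }
    if diagnostics["max_rhat"] > 1.1:
        diagnostics["warning"] = "possible non-convergence: max R-hat > 1.1"
    return diagnostics
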