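"""Synthetic active-surveillance cohorts.

Emulates a PRIAS-like population: three equal-sized subgroups whose baseline
hazards of Gleason reclassification (GR) are Weibull with (shape, scale)
(1.5, 4), (3, 5) and (4.5, 6) — fast, intermediate and slow progression —
sharing one longitudinal log2-PSA model.  True GR times are drawn by
inverse-transform sampling of each subject's conditional survival function;
PSA is measured on the surveillance protocol grid (every 3 months in the
first two years, every 6 months thereafter) with scaled-t residuals.

Training patients are observed the way a surveillance program observes them:
biopsies follow the PRIAS schedule (with the PSA doubling-time switch to
annual biopsies), so the GR time is only known to lie in an interval
(l, r], and an independent uniform censoring time truncates follow-up.
Test patients retain their true GR time as oracle truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .model_core import ModelParameters, conditional_survival

__all__ = [
    "SimulationConfig",
    "SimulatedPatient",
    "Cohort",
    "prias_protocol_visits",
    "sample_gr_time",
    "sample_gr_times_batch",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

DEFAULT_SUBGROUP_WEIBULLS = ((1.5, 4.0), (3.0, 5.0), (4.5, 6.0))


def prias_protocol_visits(horizon: float) -> np.ndarray:
    """PSA measurement times: every 3 months in years 0-2, then every 6."""
    early = np.arange(0.0, 2.0, 0.25)
    late = np.arange(2.0, horizon + 1e-9, 0.5)
    return np.concatenate([early, late])


@dataclass
class SimulationConfig:
    n_patients: int = 1000
    subgroup_weibulls: tuple = DEFAULT_SUBGROUP_WEIBULLS
    subgroup_probs: tuple = (1 / 3, 1 / 3, 1 / 3)
    psa_visit_times: np.ndarray | None = None   # defaults to PRIAS protocol
    train_fraction: float = 0.75
    censoring_horizon: float = 10.0             # uniform(0, this) for training
    horizon: float = 20.0                       # administrative horizon
    age_mean: float = 70.0
    age_sd: float = 6.0
    seed: int | None = None

    def __post_init__(self):
        if abs(sum(self.subgroup_probs) - 1.0) > 1e-9:
            raise ValueError("subgroup probabilities must sum to 1")
        for k, lam in self.subgroup_weibulls:
            if k <= 0 or lam <= 0:
                raise ValueError("Weibull shapes and scales must be positive")
        if self.psa_visit_times is None:
            self.psa_visit_times = prias_protocol_visits(self.horizon)
        self.psa_visit_times = np.asarray(self.psa_visit_times, dtype=float)
        if self.psa_visit_times[0] != 0.0 or np.any(np.diff(self.psa_visit_times) <= 0):
            raise ValueError("visit times must start at 0 and strictly increase")
        if self.horizon < self.psa_visit_times[0]:
            raise ValueError("horizon shorter than first visit")
        if not 0.0 <= self.train_fraction <= 1.0:
            raise ValueError("train_fraction must be in [0, 1]")


@dataclass
class SimulatedPatient:
    id: int
    subgroup: int
    age: float
    b: np.ndarray
    true_gr_time: float          # +inf when beyond the administrative horizon
    psa_times: np.ndarray
    psa_values: np.ndarray       # ng/mL
    y: np.ndarray                # model-scale outcome (log2 PSA)
    is_train: bool
    censor_time: float | None = None
    biopsy_times: np.ndarray | None = None   # training observation process
    l: float | None = None
    r: float | None = None       # inf when GR not observed

    def __post_init__(self):
        if self.r is not None and np.isfinite(self.r):
            if not (self.l < self.true_gr_time <= self.r):
                raise AssertionError("interval censoring violated")


@dataclass
class Cohort:
    config: SimulationConfig
    params: ModelParameters
    patients: list = field(default_factory=list)

    @property
    def train(self):
        return [p for p in self.patients if p.is_train]

    @property
    def test(self):
        return [p for p in self.patients if not p.is_train]


def sample_gr_time(risk, long_spec, age, b, u, horizon=20.0, tol=1e-6):
    """Invert S(0 -> t* | b) = u by bracketed root-finding.

    Returns +inf when the survival at the administrative horizon still
    exceeds ``u`` (GR would occur beyond follow-up).
    """
    if not 0.0 < u < 1.0:
        raise ValueError("u must lie strictly in (0, 1)")
    target = -np.log(u)

    def cumh(t):
        s = conditional_survival(risk, long_spec, age, b, 0.0, t)
        return -np.log(max(s, 1e-300))

    if cumh(horizon) < target:
        return np.inf
    return float(optimize.brentq(lambda t: cumh(t) - target, 0.0, horizon,
                                 xtol=tol))


def sample_gr_times_batch(params: ModelParameters, ages, bs, subgroups, u,
                          config: SimulationConfig, grid_step=0.01):
    """Vectorized inverse-transform sampling of true GR times.

    The log-hazard is linear in the random effects, so a shared time grid
    carries every patient: cumulative hazards come from trapezoidal
    integration of exp(c_i(v) + d(v)'b_i) on a fine grid and the survival
    equation is solved by linear interpolation within the bracketing step.
    """
    long_ = params.longitudinal
    n = len(ages)
    grid = np.arange(0.0, config.horizon + grid_step / 2, grid_step)
    # shared pieces of c(v): spline part of x'beta and its derivative
    s_val = long_.fixed_basis.design(grid) @ long_.beta[3:]
    s_der = long_.fixed_basis.deriv(grid) @ long_.beta[3:]
    a = np.asarray(ages) - long_.age_center
    q_age = long_.beta[0] + long_.beta[1] * a + long_.beta[2] * a * a
    risk = params.risk
    gamma_w = risk.gamma[0] * a + risk.gamma[1] * a * a
    offset = gamma_w + risk.alpha_value * q_age              # (n,)
    base = risk.alpha_value * s_val + risk.alpha_velocity * s_der  # (G,)
    d = (risk.alpha_value * long_.random_design(grid)
         + risk.alpha_velocity * long_.random_design(grid, deriv=True))  # (G,q)
    subgroups = np.asarray(subgroups)
    logh0 = np.empty((len(grid), n))
    for g, (k, lam) in enumerate(config.subgroup_weibulls):
        mask = subgroups == g
        if mask.any():
            with np.errstate(divide="ignore"):
                col = np.log(k / lam) + (k - 1.0) * np.log(
                    np.clip(grid, 1e-12, None) / lam)
            logh0[:, mask] = col[:, None]
    logh = logh0 + base[:, None] + offset[None, :] + d @ np.asarray(bs).T
    h = np.exp(logh)
    H = np.zeros_like(h)
    np.cumsum((h[1:] + h[:-1]) * 0.5 * grid_step, axis=0, out=H[1:])
    target = -np.log(u)
    t_star = np.full(n, np.inf)
    idx = (H >= target[None, :]).argmax(axis=0)
    reached = H[-1] >= target
    for i in np.nonzero(reached)[0]:
        j = idx[i]
        if j == 0:
            t_star[i] = 0.0
            continue
        h0_, h1_ = H[j - 1, i], H[j, i]
        frac = (target[i] - h0_) / max(h1_ - h0_, 1e-300)
        t_star[i] = grid[j - 1] + frac * grid_step
    return t_star


def _prias_observation_process(psa_times, psa_values, true_t, censor, horizon):
    """Conduct PRIAS-protocol biopsies until detection, censoring or horizon.

    Returns (biopsy_times, l, r).  The PSA-DT switch: whenever the doubling
    time computed from all PSA values observed so far lies in (0, 10] years,
    the next biopsy comes one year after the previous one; otherwise the next
    fixed PRIAS time (1, 4, 7, 10, then every 5 years) is used.
    """
    from .schedulers import fixed_schedule_times

    grid = fixed_schedule_times("prias", psa_times, psa_values,
                                horizon=horizon)
    biopsies = []
    last = 0.0
    for nxt in grid:
        if nxt > censor:
            return np.array(biopsies), last, np.inf
        biopsies.append(nxt)
        if nxt >= true_t:
            return np.array(biopsies), last, nxt
        last = nxt
    return np.array(biopsies), last, np.inf


def generate_cohort(config: SimulationConfig, params: ModelParameters,
                    rng=None) -> Cohort:
    """Draw a full synthetic cohort with a train/test split."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    long_ = params.longitudinal
    n = config.n_patients
    subgroups = rng.choice(len(config.subgroup_weibulls), size=n,
                           p=np.asarray(config.subgroup_probs))
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 50, 90)
    q = long_.n_random
    if np.all(long_.D == 0):
        bs = np.zeros((n, q))
    else:
        bs = rng.multivariate_normal(np.zeros(q), long_.D, size=n,
                                     method="cholesky")
    u = rng.uniform(1e-12, 1.0, size=n)
    t_star = sample_gr_times_batch(params, ages, bs, subgroups, u, config)

    visits = config.psa_visit_times
    X = np.stack([long_.fixed_design(a, visits) for a in ages])
    Z = long_.random_design(visits)
    m = np.einsum("npk,k->np", X, long_.beta) + bs @ Z.T
    eps = long_.sigma * rng.standard_t(long_.residual_df, size=m.shape)
    y = m + eps
    psa = params.psa_from_outcome(y)

    n_train = int(round(config.train_fraction * n))
    is_train = np.zeros(n, dtype=bool)
    is_train[rng.permutation(n)[:n_train]] = True
    censor = rng.uniform(0.0, config.censoring_horizon, size=n)

    patients = []
    for i in range(n):
        if is_train[i]:
            biopsies, l, r = _prias_observation_process(
                visits, psa[i], t_star[i], censor[i], config.horizon)
            obs_mask = visits <= min(censor[i],
                                     r if np.isfinite(r) else config.horizon)
            patients.append(SimulatedPatient(
                id=i, subgroup=int(subgroups[i]), age=float(ages[i]), b=bs[i],
                true_gr_time=float(t_star[i]), psa_times=visits[obs_mask],
                psa_values=psa[i][obs_mask], y=y[i][obs_mask], is_train=True,
                censor_time=float(censor[i]), biopsy_times=biopsies,
                l=float(l), r=float(r)))
        else:
            patients.append(SimulatedPatient(
                id=i, subgroup=int(subgroups[i]), age=float(ages[i]), b=bs[i],
                true_gr_time=float(t_star[i]), psa_times=visits,
                psa_values=psa[i], y=y[i], is_train=False))
    return Cohort(config=config, params=params, patients=patients)


def write_cohort(cohort: Cohort, out_dir):
    """Two delimited tables: longitudinal (id, time, psa) and events."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    long_rows, event_rows = [], []
    for p in cohort.patients:
        for t, v in zip(p.psa_times, p.psa_values):
            long_rows.append((p.id, t, v))
        event_rows.append((p.id, p.l if p.is_train else np.nan,
                           p.r if p.is_train else np.nan, p.age, p.subgroup,
                           int(p.is_train),
                           np.nan if p.is_train else p.true_gr_time))
    pd.DataFrame(long_rows, columns=["id", "time", "psa"]).to_csv(
        out / "longitudinal.csv", index=False)
    pd.DataFrame(event_rows, columns=["id", "l", "r", "age", "subgroup",
                                      "train", "true_gr_time"]).to_csv(
        out / "events.csv", index=False)


def read_cohort(out_dir):
    out = Path(out_dir)
    long_df = pd.read_csv(out / "longitudinal.csv")
    events_df = pd.read_csv(out / "events.csv")
    return long_df, events_df
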