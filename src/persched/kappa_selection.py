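"""Risk-threshold selection for the dynamic-risk schedule via the F1 score.

A patient at risk at time t is predicted to experience GR within the window
(t, t + dt] when pi_j(t + dt | t, s) <= kappa.  Discriminating cases
(t < T* <= t + dt) from controls, kappa is chosen on a grid to maximize

    F1 = 2 * TPR * PPV / (TPR + PPV),

i.e. the harmonic mean of sensitivity and positive predictive value.  In
simulation, case/control status comes from the true simulated GR times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["F1Config", "KappaResult", "f1_score", "select_kappa",
           "cohort_risk_predictions", "kappa_policy"]


@dataclass
class F1Config:
    dt: float = 1.0
    grid: np.ndarray = field(default_factory=lambda: np.round(
        np.arange(0.0, 1.0 + 1e-9, 0.01), 10))
    t: float = 0.0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if np.any((self.grid < 0) | (self.grid > 1)):
            raise ValueError("kappa grid must lie in [0, 1]")


@dataclass
class KappaResult:
    kappa: float | None
    f1: float
    informative: bool


def f1_score(pi, event_times, t, dt, kappa):
    """(F1, TPR, PPV) of the rule pi <= kappa among patients at risk at t.

    ``pi`` are dynamic survival probabilities pi_j(t+dt | t, s); cases are
    patients with t < T* <= t + dt.  Rates with empty denominators, and F1
    when TPR + PPV = 0, are defined as 0.
    """
    pi = np.asarray(pi, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    at_risk = event_times > t
    if not at_risk.any():
        raise ValueError("no patients at risk at t")
    pi, event_times = pi[at_risk], event_times[at_risk]
    case = event_times <= t + dt
    pred = pi <= kappa
    tp = np.sum(case & pred)
    tpr = tp / case.sum() if case.any() else 0.0
    ppv = tp / pred.sum() if pred.any() else 0.0
    f1 = 2.0 * tpr * ppv / (tpr + ppv) if (tpr + ppv) > 0 else 0.0
    return float(f1), float(tpr), float(ppv)


def select_kappa(pi, event_times, config: F1Config) -> KappaResult:
    """Grid-search argmax of F1; ties broken toward larger kappa.

    Larger kappa at equal F1 means later proposed biopsies, i.e. fewer
    biopsies for the same classification accuracy.
    """
    best_f1, best_kappa = 0.0, None
    for kappa in config.grid:
        f1, _, _ = f1_score(pi, event_times, config.t, config.dt, kappa)
        if f1 >= best_f1 and f1 > 0.0:
            best_f1, best_kappa = f1, float(kappa)
    if best_kappa is None:
        return KappaResult(kappa=None, f1=0.0, informative=False)
    return KappaResult(kappa=best_kappa, f1=best_f1, informative=True)


def cohort_risk_predictions(patients, params, t, dt, n_draws=200, seed=0,
                            method="laplace_is", horizon=20.0, grid_step=0.1):
    """pi_j(t+dt | t, s=t) and true GR times for at-risk simulated patients.

    Conditions each at-risk patient (T* > t) on a hypothetical negative
    biopsy at t and the PSA observed up to t.
    """
    from .prediction import PatientModelContext

    pis, times = [], []
    rng = np.random.default_rng(seed)
    for p in patients:
        if p.true_gr_time <= t:
            continue
        mask = p.psa_times <= t + 1e-9
        if mask.sum() < 1:
            continue
        ctx = PatientModelContext(params, p.age, p.psa_times[mask],
                                  p.y[mask], horizon=horizon,
                                  grid_step=grid_step)
        pp = ctx.posterior(t, t, n_draws=n_draws,
                           rng=rng.integers(2 ** 31), method=method)
        pis.append(pp.survival(t + dt))
        times.append(p.true_gr_time)
    return np.asarray(pis), np.asarray(times)


def kappa_policy(patients, params, dt=1.0, t_grid=None, min_at_risk=30,
                 n_draws=100, seed=0, fallback=0.95, **predict_kwargs):
    """Time-varying F1-selected threshold kappa*(t) from a reference cohort.

    Runs the grid search at each evaluation time; when too few patients
    remain at risk (or no threshold is informative) the last informative
    kappa is carried forward.  Returns a step function of the latest-biopsy
    time t.
    """
    if t_grid is None:
        t_grid = np.arange(0.0, 19.0 + 1e-9, 1.0)
    t_grid = np.asarray(t_grid, dtype=float)
    kappas = np.empty(len(t_grid))
    last = fallback
    for i, t in enumerate(t_grid):
        pi, times = cohort_risk_predictions(
            patients, params, t, dt, n_draws=n_draws, seed=seed + i,
            **predict_kwargs)
        if len(pi) >= min_at_risk:
            res = select_kappa(pi, times, F1Config(dt=dt, t=t))
            if res.informative:
                last = res.kappa
        kappas[i] = last

    def policy(t):
        idx = int(np.clip(np.searchsorted(t_grid, t + 1e-9) - 1, 0,
                          len(t_grid) - 1))
        return float(kappas[idx])

    policy.t_grid = t_grid
    policy.kappas = kappas
    return policy
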