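"""Biopsy scheduling rules.

Personalized rules map a patient's posterior predictive GR-time distribution
to a proposed biopsy time by minimizing a posterior expected loss:

* squared loss  -> expected GR time E_g(T*),
* absolute loss -> median GR time, pi^{-1}(0.5),
* multilinear loss with constants (k1, k2) -> pi^{-1}(kappa) with
  kappa = k1/(k1+k2), i.e. biopsy when the dynamic risk of GR reaches
  1 - kappa ("dynamic risk" rule),
* hybrid: the central (median/expected) rule when g(T*) is tight, the
  dynamic-risk rule when its spread (central value minus the 0.025 quantile)
  exceeds a threshold (default 3 years, the maximum possible detection delay
  of the PRIAS fixed schedule in its first decade).

Fixed comparators: annual biopsies, and the PRIAS protocol (years 1, 4, 7,
10, then every 5) with its switch to annual biopsies whenever the PSA
doubling time falls in (0, 10] years.

All rules respect the surveillance constraint that consecutive biopsies are
at least 1 year apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .prediction import (CENSORED_QUANTILE, expected_gr_time,
                         quantile_gr_time)

__all__ = [
    "Scheduler",
    "Decision",
    "propose_time",
    "next_biopsy",
    "compute_psa_dt",
    "fixed_schedule_times",
    "MIN_BIOPSY_GAP",
    "PRIAS_BASE_TIMES",
]

MIN_BIOPSY_GAP = 1.0
PERSONALIZED_KINDS = ("expected", "median", "dyn_risk", "hybrid")
FIXED_KINDS = ("annual", "prias")


def PRIAS_BASE_TIMES(horizon):
    """PRIAS fixed biopsy grid: years 1, 4, 7, 10, then every 5 years."""
    times = [1.0, 4.0, 7.0, 10.0]
    nxt = 15.0
    while nxt <= horizon + 1e-9:
        times.append(nxt)
        nxt += 5.0
    return np.array([t for t in times if t <= horizon + 1e-9])


@dataclass
class Scheduler:
    kind: str
    kappa: float | str | None = None
    hybrid_spread_threshold: float = 3.0
    hybrid_central: str = "median"
    conflict_resolution: str = "recompute"   # or "keep_earlier"
    psa_dt_window: float | None = None       # None: all PSA since entry

    def __post_init__(self):
        if self.kind not in PERSONALIZED_KINDS + FIXED_KINDS:
            raise ValueError(f"unknown scheduler kind {self.kind!r}")
        if (isinstance(self.kappa, (int, float)) and not callable(self.kappa)
                and not 0.0 <= self.kappa <= 1.0):
            raise ValueError("kappa must lie in [0, 1]")
        if self.hybrid_spread_threshold <= 0:
            raise ValueError("hybrid spread threshold must be positive")
        if self.hybrid_central not in ("expected", "median"):
            raise ValueError("hybrid_central must be 'expected' or 'median'")

    def _resolved_kappa(self, t=0.0):
        if callable(self.kappa):
            return float(self.kappa(t))
        if not isinstance(self.kappa, (int, float)):
            raise ValueError(
                "dynamic-risk scheduling needs a numeric kappa or a "
                "kappa policy; 'auto' values must be resolved through "
                "kappa_selection.kappa_policy first")
        return float(self.kappa)


@dataclass
class Decision:
    """Outcome of one visit: either conduct a biopsy or defer to next visit."""

    action: str            # 'biopsy' or 'defer'
    time: float            # biopsy time, or the next-visit time deferred to
    proposed: float        # the raw personalized proposal u


def _dyn_risk_time(pp, kappa):
    """pi^{-1}(kappa); the boundary thresholds degenerate to now / never."""
    if kappa >= 1.0:
        return pp.t
    if kappa <= 0.0:
        return pp.horizon
    return quantile_gr_time(pp, 1.0 - kappa)


def propose_time(scheduler: Scheduler, pp, history=None) -> float:
    """Loss-minimizing biopsy time under the scheduler's rule.

    Proposals are capped at the administrative horizon (censored quantiles
    propose a horizon biopsy rather than none at all) and never precede the
    latest biopsy time t.
    """
    kind = scheduler.kind
    if kind not in PERSONALIZED_KINDS:
        raise ValueError(f"propose_time needs a personalized rule, got {kind!r}")
    if kind == "expected":
        u = expected_gr_time(pp)
    elif kind == "median":
        u = quantile_gr_time(pp, 0.5)
    elif kind == "dyn_risk":
        u = _dyn_risk_time(pp, scheduler._resolved_kappa(pp.t))
    else:  # hybrid
        central = (expected_gr_time(pp) if scheduler.hybrid_central == "expected"
                   else quantile_gr_time(pp, 0.5))
        q025 = quantile_gr_time(pp, 0.025)
        central_c = min(central, pp.horizon)
        spread = central_c - min(q025, pp.horizon)
        if spread > scheduler.hybrid_spread_threshold:
            u = _dyn_risk_time(pp, scheduler._resolved_kappa(pp.t))
        else:
            u = central
    if u == CENSORED_QUANTILE or u > pp.horizon:
        u = pp.horizon
    return float(max(u, pp.t))


def next_biopsy(scheduler: Scheduler, pp, history=None, u_pv=None,
                s_nv=None) -> Decision:
    """One step of the scheduling algorithm at the current visit.

    The proposal u is recomputed from the current posterior (or reconciled
    with the previously proposed time u_pv under 'keep_earlier'); if it
    violates the 1-year gap it is postponed to t + 1; if it falls before the
    next PSA visit s_nv the biopsy is conducted at u (never before the
    current visit), otherwise the decision is deferred to the next visit.
    """
    t = pp.t
    u = propose_time(scheduler, pp, history)
    if u_pv is not None and scheduler.conflict_resolution == "keep_earlier":
        u = min(u, u_pv)
    proposed = u
    if u - t < MIN_BIOPSY_GAP:
        u = t + MIN_BIOPSY_GAP
    if s_nv is None or u <= s_nv + 1e-9:
        return Decision("biopsy", float(max(u, pp.s)), proposed)
    return Decision("defer", float(s_nv), proposed)


def compute_psa_dt(psa_times, psa_values) -> float:
    """PSA doubling time: inverse of the least-squares slope of log2(PSA).

    Returns +inf (non-rising PSA) when the slope is zero or negative.
    """
    times = np.asarray(psa_times, dtype=float)
    values = np.asarray(psa_values, dtype=float)
    if len(np.unique(times)) < 2:
        raise ValueError("PSA doubling time needs >= 2 distinct time points")
    logv = np.log2(np.clip(values, 1e-12, None))
    tc = times - times.mean()
    slope = (tc @ (logv - logv.mean())) / (tc @ tc)
    if slope <= 0:
        return np.inf
    return 1.0 / slope


def fixed_schedule_times(kind, psa_times=None, psa_values=None,
                         horizon=20.0, psa_dt_window=None) -> np.ndarray:
    """Realized biopsy grid of a fixed schedule.

    ``annual``: biopsies at years 1, 2, 3, ...  ``prias``: years 1, 4, 7, 10
    and every 5 thereafter; additionally, the PSA doubling time is
    re-assessed at every PSA visit from the measurements observed so far,
    and once it falls in (0, 10] years the patient switches to the fast
    track — annual biopsies from then on (at visits, respecting the 1-year
    gap to the previous biopsy).
    """
    if kind == "annual":
        return np.arange(1.0, horizon + 1e-9)
    if kind != "prias":
        raise ValueError(f"unknown fixed schedule {kind!r}")
    base = PRIAS_BASE_TIMES(max(horizon, 30.0))
    psa_times = (np.asarray(psa_times, dtype=float)
                 if psa_times is not None else np.array([]))
    psa_values = (np.asarray(psa_values, dtype=float)
                  if psa_values is not None else np.array([]))
    visits = np.unique(np.concatenate([psa_times, base]))
    visits = visits[(visits > 0) & (visits <= horizon + 1e-9)]
    times = []
    last = 0.0
    fast = False
    for v in visits:
        if v < last + MIN_BIOPSY_GAP - 1e-9:
            continue
        if not fast:
            sel = psa_times <= v + 1e-9
            if psa_dt_window is not None:
                sel &= psa_times >= v - psa_dt_window - 1e-9
            if len(np.unique(psa_times[sel])) >= 2:
                dt = compute_psa_dt(psa_times[sel], psa_values[sel])
                fast = 0.0 < dt <= 10.0
        scheduled = np.any(np.abs(base - v) < 1e-9)
        if fast or scheduled:
            times.append(float(v))
            last = v
    return np.array(times)
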