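# Methods

## The joint model

`persched` models an active-surveillance (AS) prostate-cancer cohort with a
joint model for the longitudinal PSA biomarker and the time of Gleason
reclassification (GR), the event that ends surveillance.

**Longitudinal sub-model.** The outcome is log2 PSA (configurable to
log2(PSA+1)). For patient *i* at follow-up time *t* (years),

    y_i(t) = m_i(t) + eps_i(t),
    m_i(t) = beta0 + beta1 (Age_i - 70) + beta2 (Age_i - 70)^2
             + sum_k beta_{k+2} N_k(t) + b_i0 + b_i1 M_1(t) + b_i2 M_2(t),

where `N_k` is a natural cubic spline basis in time with interior knots
{0.1, 0.5, 4} years and boundary knots {0, 7} (four columns), and the
random-effects spline `M` has one interior knot at 0.1 years (two columns
plus the random intercept, so q = 3). Residuals are scaled-t with 3 degrees
of freedom — PSA has occasional outliers — and b_i ~ N(0, D).

The basis is the truncated-power natural-spline construction: the first
column is *t* itself and each curvature column is a difference of scaled
truncated cubics, divided by the squared boundary span so every column has
O(1) magnitude. Natural splines are exactly linear beyond the boundary
knots, which gives the trajectory and its velocity a well-defined linear
extrapolation after year 7.

**Relative-risk sub-model.** The GR hazard is

    h_i(t) = h0(t) exp{gamma1 (Age_i-70) + gamma2 (Age_i-70)^2
                       + alpha1 m_i(t) + alpha2 m_i'(t)},

linking the *error-free* PSA level and velocity to risk. The baseline
hazard h0 is Weibull (shape k, scale lambda; h0(t) = (k/lambda)
(t/lambda)^(k-1)) or piecewise-constant. Because the log-hazard is linear
in b_i, a per-patient decomposition log h(t|b) = c(t) + d(t)'b evaluated
once on a time grid serves every random-effect draw; this is what makes the
simulation experiments tractable.

## Default population parameters

The simulation truth is a PRIAS-like population. Where the literature
reports a quantity, the default reproduces it; the remaining values are
fixed once at clinically plausible magnitudes:

- `alpha2 = ln(2.05)/0.2 ≈ 3.59`: a velocity increase of 0.2 log2-units/yr
  (the interquartile shift of velocities fitted to PRIAS data) multiplies the GR
  hazard by 2.05.
- `alpha1 = 0.02`: in PRIAS-fitted joint models the PSA *level*
  association is weak and
  non-significant; a near-zero value also keeps the marginal GR-time
  distribution close to the specified Weibull baselines.
- Random effects: SD(b0) = 0.5 (between-patient log2-PSA level),
  SD(b1) = SD(b2) = 0.15 with mild correlations. Together with the fixed
  trajectory this puts the quartiles of m'(t) at mid follow-up near
  (-0.06, 0.14), the quartiles seen in PRIAS-fitted trajectories.
- `sigma = 0.25` on the log2 scale (t3-scaled): roughly a 19% coefficient
  of variation, in line with combined assay and biological PSA fluctuation.
- Intercept 2.5 (entry PSA ≈ 5.7 ng/mL), small age effects
  (beta = 0.004, -0.0005; gamma = 0.01, -0.0005), and a mildly rising mean
  trajectory (≈ +0.9 log2-units over 7 years).
- Entry age ~ N(70, 6), truncated to [50, 90].

The simulated cohort has three equal subgroups with Weibull baselines
(1.5, 4), (3, 5), (4.5, 6) — fast, intermediate, slow progression. PSA is
measured on the PRIAS protocol grid (every 3 months in years 0–2, every 6
months thereafter). True GR times come from inverse-transform sampling of
each subject's survival function (vectorized trapezoid cumulative hazard on
a 0.01-year grid; the scalar API refines with Brent root-finding on
adaptive-quadrature survival). Training patients are observed through
PRIAS-schedule biopsies, so GR is interval-censored in (l, r], with an
independent uniform(0, 10) censoring time; test patients keep the true GR
time as oracle truth. Events past the administrative horizon (20 years) are
right-censored.

## Posterior predictive GR-time distribution

For a new patient with latest negative biopsy at *t* and PSA history to
*s*, the random-effects posterior is

    p(b | T* > t, Y(s), theta) ∝ p(Y | b) S(0 -> t | b) p(b),

with theta plugged in (oracle truth, or posterior means from the fitting
module). Two samplers are provided:

- `mcmc` (default): random-walk Metropolis started at the Laplace mode with
  the Laplace covariance as proposal; acceptance rate recorded.
- `laplace_is`: a multivariate-t (df 7) proposal centred at the Laplace
  mode with importance reweighting; the effective sample size is recorded.
  Typical ESS is above 90/100 draws, and this is the method the evaluation
  experiment uses for speed.

The mode is found by damped Newton ascent with analytic gradient and
Hessian (the survival term is convex in b; indefinite t-likelihood
curvature is handled by ridging and, for the Laplace covariance, eigenvalue
clipping).

The dynamic survival probability pi(u | t, s) averages S(t -> u | b) over
the weighted draws, using per-draw cumulative-hazard interpolants on a
0.05-year grid (0.1 in the large experiments). Moments use the
point-mass-at-horizon convention for the truncated tail:

    E[T*]  = t + int_t^H pi(u) du,       var analogous,

evaluated by composite 15-point Gauss–Kronrod quadrature (32 panels;
agreement with a 1e5-node trapezoid oracle is tested to 1e-5). Quantiles
invert pi by monotone bisection refined to 1e-4 years; a quantile not
reached by the horizon returns the +inf sentinel and schedulers fall back
to a horizon biopsy.

## Scheduling rules

Personalized rules minimize a posterior expected loss: squared loss gives
the expected GR time, absolute loss the median, and the multilinear loss
with constants (k1, k2) gives pi^{-1}(kappa), kappa = k1/(k1+k2) — a biopsy
when the patient's conditional GR risk reaches 1 - kappa. The hybrid rule
uses the median unless the spread (central value minus the 0.025 quantile
of g) exceeds 3 years — the worst-case detection delay of the PRIAS fixed
schedule in its first decade — in which case the risk-based time is used.

The visit algorithm: at each PSA visit the posterior is re-conditioned and
a time *u* proposed; if u - t < 1 year it is postponed to t + 1 (the
minimum biopsy gap); if u falls before the next visit the biopsy is
conducted at u, otherwise the decision is deferred and recomputed at the
next visit (a `keep_earlier` option instead reconciles with the previously
proposed time). Every emitted sequence keeps consecutive biopsies >= 1 year
apart.

Fixed comparators: annual biopsies, and the PRIAS protocol — years 1, 4, 7,
10 and every 5 thereafter, with the PSA doubling-time switch. PSA-DT is the
inverse least-squares slope of log2(PSA) on time, computed from all PSA
since entry; the switch is assessed at every visit and treated as
absorbing (once PSA-DT falls in (0, 10] years the patient stays on annual
biopsies). The absorbing reading is what makes the PRIAS comparator's
burden sit just below the annual schedule's, as it does in practice.

**Threshold selection.** kappa can be fixed or selected by maximizing the
F1 score of the classifier "case iff pi(t+1 | t, s) <= kappa" against
GR status in (t, t+1], on a 0.01 grid with ties broken toward larger kappa.
The evaluation experiment estimates kappa*(t) once per experiment on a
750-patient reference cohort at yearly decision times, carrying the last
informative value forward when fewer than 30 patients remain at risk. In
simulation, case/control status is taken from the true GR times — a
deliberate simplification relative to censoring-adjusted rate estimators.

## Schedule evaluation

Each test patient with known T* is run under each schedule; N counts
biopsies through detection and the offset O is detection time minus T*
(months in all reports). Per-dataset means and variances are pooled with
sample-size weights (means) and degrees-of-freedom weights (variances).
Schedules are then compared by compound criteria (weighted sums) or
constrained choice (minimize one criterion subject to bounds on others),
with an explicit no-feasible-schedule result.

The experiment runs at desk scale: 50 datasets x 250 test patients with
oracle parameters, 100 importance-reweighted draws per decision and a
0.1-year hazard grid — enough that Monte-Carlo error is far smaller than
the between-schedule differences being compared. Personalized schedules
condition on the patient's true subgroup baseline (the data-generating
parameters); a fitted-parameter mode is available through the fitting
module. Patients whose GR falls beyond the 20-year horizon are excluded
from all schedules' summaries (kept comparable across schedules) and
counted as censored.

## Fitting

`fit_joint_model` targets the full posterior of (beta, D, sigma, gamma,
alpha, baseline) given interval-censored training data, with the exact
per-patient likelihood

    p(y_i | b_i) [S(0 -> l_i | b_i) - S(0 -> r_i | b_i)]   (event)
    p(y_i | b_i)  S(0 -> l_i | b_i)                        (censored)

and a Metropolis-within-Gibbs sampler: vectorized per-patient random-walk
updates for b_i (two sweeps per iteration), a conjugate inverse-Wishart
Gibbs step for D (weakly informative IW(q+2, 0.1 I); chosen over an
LKJ-style prior because conjugacy removes one slow random-walk block), an
OLS-preconditioned block for beta, one Haario-style adaptively tuned block
for (gamma, alpha, log baseline rates) — these are strongly correlated in
the posterior and must move together — and a scalar block for log sigma.
Translation moves along the confounded fixed/random directions (intercept
vs b0, time slope vs b1) decorrelate beta from the random-effect means;
they leave m_i invariant so only the priors enter the acceptance ratio.
Starting values are BLUP random effects and the conditional MAP of the
hazard block (prior-penalized and clipped, since shrunken BLUP velocities
can otherwise push the conditional optimum toward separation-style
divergence).

The baseline for fitting is piecewise-constant with 5 pieces at quantiles
of the observed event intervals; cumulative hazards use Gauss–Legendre
panels split at the breakpoints (a jump inside a panel would silently bias
the likelihood). Priors elsewhere: N(0, 10^2) on beta, N(0, 5^2) on gamma
and alpha, N(log 0.05, 3^2) on log rates, N(log 0.2, 3^2) on log sigma.
Convergence is summarized by split-R-hat and ESS (via arviz); R-hat > 1.1
sets a warning flag in the result rather than failing silently.

The parameter-recovery experiment simulates n = 200 training patients from
a single common Weibull(3, 5) baseline — i.e. from exactly the model family
being fitted, which is what "recovery from known parameters" requires; the
latent three-subgroup mixture of the evaluation experiment would make the
single-baseline fit deliberately misspecified. Chains are 12,000 iterations
(5,000 burn-in, thinned by 2), about half to one minute per replicate.

## What the generator does and does not emulate

The synthetic cohorts reproduce the structural features that drive
scheduling: protocol-timed noisy PSA, subject-specific levels and
velocities, velocity-dominated hazard, subgroup heterogeneity in
progression speed, interval-censored detection through realistic biopsy
schedules, and non-informative censoring. They do **not** emulate
non-compliance, PSA-informed dropout, measurement error in Gleason grading,
treatment changes, or calendar effects — so passing tests demonstrate
correctness of the machinery under the stated model, not robustness of the
schedules to those real-world violations. Conclusions that depend on the
exact PRIAS-fitted parameter values (which are not public) — most visibly
the near-annual burden of the PRIAS comparator, which depends on how many
simulated patients ever trip the PSA-DT switch — are reproduced in
structure but not to the decimal.

## Known limitations

- theta uncertainty is plugged in (oracle truth or posterior means); full
  theta-mixing of the predictive distribution is not propagated.
- The F1-based kappa policy is estimated from true simulated outcomes, not
  censoring-adjusted estimators.
- The Gibbs sampler's velocity-association component mixes slowly
  (ESS of order 10^2 per 12k iterations); credible intervals at n = 200
  are wide and the R-hat warning is often active at desk-scale chain
  lengths.
- Single-outcome models only; no cure fraction, competing risks, or
  P-spline baselines.
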