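# Methods

## Model and assumptions

The data are longitudinal visit records: subject *d* is seen at days
*t₁ < t₂ < … < t_{l_d}*, covariates are re-measured at every visit, and
follow-up ends in death, censoring, or liver transplantation.  Treating
the interval between consecutive visits as the natural discretization of
time (the visit schedule is clinically determined, so no arbitrary
month/week grid has to be imposed), the discrete hazard

    h_l = Pr(death in interval l | alive at its start)

is modelled on the logit scale as an additive combination of smooth and
linear covariate effects evaluated at the covariate values measured at
the interval's opening visit, with the interval midpoint available as a
"time" covariate.  Expanding each subject into one Bernoulli row per
interval makes the model's partial log likelihood exactly the Bernoulli
log likelihood of the pooled rows, so estimation, deviance, and AIC all
reduce to (penalized) logistic regression on the person-period table.

Assumptions worth stating explicitly:

- covariates are piecewise-constant within an interval (measured at its
  opening visit); no interpolation between visits;
- one terminal event per subject; recurrent events are out of scope;
- censoring and the visit schedule are non-informative given the
  covariates;
- transplantation acts as censoring, optionally plus a time-dependent
  indicator covariate (0 before, 1 at the transplant visit).  Transplanted
  subjects never contribute an event row, so the indicator's coefficient
  is typically strongly negative and can be quasi-separated; the fitter
  detects and warns about diverging log-odds.

## Spline terms and penalties

Smooth terms use clamped cubic B-splines — the minimal degree with the
twice-continuous derivatives the curvature penalty requires — with 10
interior knots by default, placed at equally spaced quantiles of the
observed values (robust to skewed covariates such as bilirubin; the knot
count has little effect provided it is not too small).  Each smooth block
is reparameterized by a sum-to-zero constraint (null space of the
column-mean row vector) so the free intercept stays identifiable; this
removes exactly one column per smooth, e.g. 14 → 13 columns for the
default basis.

The roughness penalty is the integrated squared second derivative,
assembled exactly: on each knot span the integrand is a polynomial of
degree 2(k−2), integrated by Gauss–Legendre quadrature of sufficient
order, then transformed into the constrained parameterization.  Its null
space (constants and linear functions, dimension 2 before centering)
means λ → ∞ shrinks a smooth to a linear effect, never to zero — a
property the test suite exploits as an oracle.

## Fitting

Penalized IRLS (Fisher scoring) with step halving, so the penalized
objective is non-decreasing; convergence at relative objective change
below 1e−11 followed by one polishing Newton step, which takes the
solution to near machine precision (needed so refits inside
cross-validation are insensitive to warm starts).  A ridge of 1e−10 is
added to the normal equations only if the Cholesky factorization fails,
with a warning.  Effective degrees of freedom are the trace of the
influence matrix F = (ZᵀWZ + ΣλᵢSᵢ)⁻¹ ZᵀWZ at convergence, reported in
total and per term (sum of the term's diagonal block of F); residual df
is N − edf.  Deviance is −2 ln L(β̂), the saturated model's log
likelihood being zero for binary responses.

Degenerate inputs: a constant covariate fails knot placement; a
rank-deficient design is rejected with a diagnostic; out-of-range
prediction values are clamped to the boundary knots with a warning;
fitted |log-odds| above 30 trigger a separation warning.

## Smoothing-parameter selection

Ordinary leave-one-out CV (and its GCV approximation, provided as
`gcv_score = N·Dev/(N−edf)²`) treats rows as exchangeable, but a
patient's rows are not independent of one another.  The variant v-fold CV
therefore deletes one *patient* at a time: refit on the remaining
patients' rows, accumulate the held-out patient's Bernoulli log
likelihood over **all** of that patient's rows, and report −2 times the
sum, putting the score on the same scale as deviance and AIC.  When every
subject has a single row this reduces exactly to ordinary LOO CV (checked
to 1e−10 in the tests).  Selection is a deterministic exhaustive grid
search (log-spaced grids such as 10⁻⁴…10² are typical; published optima
in this problem family are round powers of ten), with ties broken toward
the larger, smoother λ.  Warm starts from the full-data fit keep the
n-fold refitting affordable: the 300-subject recovery experiment (5-point
grid, 1500 refits) runs in a few seconds.

LR tests between nested fits use the deviance difference on the
difference of effective df, referred to the chi-square (gamma) with that
fractional df.  Per-term p-values are Wald-type chi-squares on the term's
coefficient block with its edf as df — a convenient approximation,
documented as such, not an exact test.

## Bootstrap goodness of fit — and a measured caution

For ungrouped binary data the deviance is not even approximately
chi-square, so the package calibrates it by bootstrap: resample n whole
patients with replacement (preserving within-patient structure), refit at
the same λ, collect Dev(b), and take the order statistic of rank
round((1−α)(B+1)) as the critical value (B = 400 and α = 0.05 give rank
381); an observed deviance above it flags a poor fit.  With a fixed seed
(per-replicate substreams spawned from one SeedSequence) the result is
bit-reproducible; failed replicate fits are skipped, logged, and counted.

The package's own diagnostics show how conservative this decision is: the
minimized deviance for ungrouped binary responses is nearly a
deterministic function of the fitted coefficients, so the bootstrap
distribution of Dev(b) — case-resampled or redrawn from the fitted
hazards (`method="parametric"`) — centers close to the observed deviance
(the observed value sits near its median in simulation, in correctly
specified *and* misspecified models alike).  Consequently the test almost
never rejects at conventional levels: across 100 replicate synthetic
studies with a correctly specified model the rejection rate at α = 0.05
is 0.00, far below nominal.  The practical reading: an observed deviance
*below* the critical value is weak evidence of fit; one *above* it is a
strong signal.  Users who need a size-respecting GoF test for this model
class should look to grouped-data statistics (e.g. Hosmer–Lemeshow-type
grouping), which are outside this package's scope.

## Prediction

S(t_l) = Π_{i≤l} (1 − h_i) is computed as a plain cumulative product, so
the telescoping identity S(t_l)/S(t_{l−1}) = 1 − h_l holds to machine
precision.  A six-month window rarely aligns with the irregular visit
grid, so the conditional survival Pr(t, Δt) = S(t+Δt)/S(t) interpolates
S between boundaries by treating each interval's hazard as a constant
daily rate r_i = −ln(1−h_i)/length_i; past the last observed interval the
final rate is carried forward, which amounts to carrying the last
observed covariates forward — the minimal extrapolation assumption.  This
makes Pr multiplicative over adjacent windows and reproduces 1 − h_i
exactly over a whole interval.  Group summaries average Pr_d(l, l+Δt)
per visit index over the patients of an outcome group still under
observation at that visit; box-plot-style per-visit quantile tables are
emitted as data, with plotting left to the caller.

## Synthetic cohorts

The generator emulates the structure of the PBC sequential data: default
312 subjects; visits at ~6 and ~12 months then yearly with ±30 days
jitter; staggered-entry administrative censoring uniform on 3–11 years
plus a 2% per-interval dropout, giving ≈2000 rows and ≈32% deaths at the
default size; age increasing linearly within subject, stationary AR(1)
prothrombin time, and a drifting log-scale random-walk bilirubin.  The
true log-odds of death are intercept −3.0 plus a linear age effect (0.04
per year), a linear prothrombin effect (0.3 per second), and a
deliberately nonlinear, saturating bilirubin effect
2·tanh(0.8·(ln b − 1)), so spline-versus-linear comparisons have real
signal.  Transplantation triggers stochastically above a bilirubin
threshold.  Every interval's true hazard is recorded for recovery tests.

What it does **not** emulate: the joint covariate distribution of the
real Mayo cohort, measurement error in laboratory values, informative
visit timing, or covariate-dependent censoring.  Passing tests therefore
demonstrate the estimator's correctness and selection behaviour under the
model's own assumptions, not robustness to their violation.

## Problem sizes used in the shipped experiments

The shipped tests and the reproduction script scale the experiments to
desk size as the package's own choice of study conditions: oracle checks
on ~500-row tables; CV/LOO equivalence at 50 subjects; smoothing-parameter
recovery and the transplantation test at 300 subjects; bootstrap
calibration at 100 subjects × B = 99 × 100 replicate studies.

## Known limitations

- Single terminal event; no recurrent events, no subdistribution-hazard
  competing-risk model (transplantation enters only as the indicator
  covariate).
- No standard-error bands for the fitted smooths.
- No tensor-product interactions between covariates.
- The bootstrap GoF decision is conservative (see above).
- Smoothing parameters are selected on a finite grid, not by continuous
  optimization; this is deliberate (reproducibility, and the score is
  cheap on desk-scale cohorts) but coarse for >2 smooth terms, where the
  cartesian grid grows quickly.
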