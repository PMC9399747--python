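# Methods

## Setting and model

The package implements a model-based meta-analysis (MBMA) of a treatment
effect that develops over time, built for aggregate, arm-level data: one
row per study arm per visit carrying the arm's mean body weight, its size
and the treatment dose. The motivating application is carnitine
supplementation and body weight in polycystic ovary syndrome, where the
evidence base is a handful of small randomised trials reported only as
summary statistics.

Because baseline weights differ between studies, the therapeutic index is
the percent change from each arm's own baseline,

    E% = (E_t − E_0) / E_0 × 100 ,

stored throughout on the ×100 scale (−3.92 means −3.92%). Diet and other
background effects are removed by subtracting the control arm's percent
change from the treatment arm's at matched visits: the net effect
E_B = E_A − E_C. Arms must share the post-baseline visit grid; mismatched
grids are an error rather than interpolated, since no principled
interpolation rule exists for the 3-visit series this design targets.

The net effect in study *i* at time *t_ij* (weeks) follows a saturating
Emax time course with study-level random effects and sample-size-weighted
residual noise:

    E_B,ij = Emax_i · t_ij / (ET50_i + t_ij) + ε_ij ,
    ε_ij ~ N(0, σ²/(N_ij/100)) ,

so an arm of 100 subjects has residual SD exactly σ. Inter-study
variability enters either exponentially (Emax_i = Emax·e^{η1,i}) or
additively (Emax_i = Emax + η1,i), and likewise for ET50, with
η ~ N(0, ω²). ω values are stored as standard deviations of η. The
exponential form is the default on both parameters: it preserves the sign
of Emax and the positivity of ET50 for every η, which the additive form
does not.

Covariates adjust the typical parameter values before the random effects
apply, through one of three relations (categorical additive, centred
additive, centred power), each with a single correction coefficient
θ_cor; centred relations use the population median of the covariate.

## Estimation

The marginal likelihood integrates the per-study η out of the conditional
Gaussian likelihood. The integral is approximated per study by a Laplace
expansion around the joint-density mode: a damped Newton iteration on the
(≤2)-dimensional penalised weighted sum of squares, using the exact
analytic Hessian of the saturating curve (closed forms exist for all
eta-form combinations), with a Gauss–Newton fallback whenever the exact
Hessian is not positive definite (flat or saddle modes). The objective
function value (OFV) is −2× the marginal log-likelihood; with both ω = 0
it reduces exactly to the weighted residual closed form

    Σ_ij [ log(2π σ²/(N_ij/100)) + r_ij² (N_ij/100)/σ² ] .

An independent adaptive Gauss–Hermite quadrature routine (41 nodes per
dimension, tensor product in 2-D, centred and scaled at the same mode) is
provided purely as a numerical cross-check; the test suite requires
Laplace–quadrature agreement within 10⁻³ OFV units on small instances
with ω ≤ 0.05.

Population fitting minimises the OFV over (Emax, ET50, ω_Emax, ω_ET50, σ)
plus any covariate coefficients with bounded L-BFGS-B from a
deterministic 3×3 multi-start grid (Emax ∈ {−10, −4, −1} %, ET50 ∈
{1, 4, 10} weeks); the best converged start wins. Numerical choices that
matter:

- relative OFV tolerance 10⁻⁸, projected-gradient tolerance 10⁻⁶;
- outer finite-difference step 10⁻⁶ — the default 10⁻⁸ step amplifies
  residual inner-optimisation noise (~10⁻¹⁰ OFV) into the numerical
  gradient and causes premature convergence;
- bounds ET50 ≥ 10⁻³ weeks, ω ∈ [0, 10], σ ≥ 10⁻⁴; an ω estimated at the
  0 boundary simply removes that random-effect dimension;
- inner Newton: gradient tolerance 10⁻¹⁰ (relative), backtracking line
  search, η warm-started across outer iterations; |η| is capped at 200 to
  keep the exponential form finite.

Fitting requires at least two studies: inter-study variability is not
identifiable from one.

Stepwise covariate selection follows the conventional likelihood-ratio
procedure: in each forward round every remaining (covariate, parameter,
relation) candidate is added to the current model one at a time
(warm-started, single-start refit), and the largest OFV drop is accepted
if it exceeds 3.84 (χ², α = 0.05, df = 1); ties are broken by candidate
list order. A backward pass then removes any included covariate whose
deletion raises the OFV by no more than 6.63 (α = 0.01, df = 1). Every
tested ΔOFV is recorded in the selection trace. Thresholds are the
2-decimal conventional cutoffs, reproduced by `lrt_threshold` from the
chi-square quantile.

## Evaluation

*Predictions.* Population predictions set η = 0; individual predictions
use the per-study empirical-Bayes η modes from the Laplace inner step.

*CWRES.* Conditional weighted residuals use the first-order-conditional
linearisation: per study the marginal distribution of y is approximated
as N(f(η̂) − G η̂, G Ω Gᵀ + diag(σ²/(N/100))) with G the analytic
sensitivity of the prediction to η at η̂; residuals are decorrelated by
the Cholesky factor of that covariance. With ω = 0 this reduces to
(obs − pred)·√(N/100)/σ. Under a correct model CWRES are approximately
standard normal.

*Bootstrap.* Nonparametric, with the study as the resampling unit — the
study is the model's exchangeable unit and the data are study-level
aggregates. Each replicate refits warm-started from the original
estimates (single start); failed refits are counted and excluded from the
percentiles, with a warning above 20% failures. Summaries are the
replicate median, the 2.5/97.5 percentiles and the relative bias
(median − estimate)/estimate. With a fixed seed the bootstrap is
bit-reproducible.

*pcVPC.* The prediction-corrected visual predictive check simulates
`n_sim` replicate datasets from the fitted model (fresh η per study,
fresh ε per observation), bins by unique observation time, and corrects
observed and simulated values multiplicatively by (bin-median population
prediction)/(observation's population prediction); a bin containing a
zero population prediction switches to additive correction with a logged
warning. Bands are the pooled 2.5/50/97.5 percentiles per bin; coverage
is the fraction of observed (corrected) values inside the 95% band. In a
covariate-free model all studies share one population prediction per bin,
so the correction is the identity — the construction matters only once
covariates differentiate the studies.

Coverage is assessed pooled over several self-simulated datasets: a
single default-design dataset has 12 observations, so an 85% coverage
cut is equivalent to "at most one outside", which a correctly specified
model fails ~12% of the time from binomial granularity alone. Pooling
five datasets (60 observations) measures the same property at usable
precision.

*Prediction.* Monte Carlo efficacy bands draw η per replicate and
evaluate the structural curve over a grid (default 0–24 weeks, step 0.1);
milestone durations invert the curve analytically,
t(f) = ET50·f/(1 − f), at the ET50 point estimate, with the default
fractions (25, 50, 75, 80)% — 80% being the conventional clinical
"plateau" label, treated as a configured fraction, not a derived one.
With ET50 = 3.6 weeks these are 1.2, 3.6, 10.8 and 14.4 weeks.

## Synthetic data generator

The generator emulates the structure of the literature-mined dataset the
analysis assumes, and is the basis of every end-to-end test: 4 two-arm
studies, 242 subjects in total (arm sizes 30/30, 36/35, 25/24, 31/31),
daily doses 250/500/750/1000 mg, visits at 0/4/8/12 weeks, baseline mean
weights 71.8–80.1 kg and mean ages 23.6–30.8 years. Per-study arm sizes
and visit schedules beyond these totals are the package's own plausible
choices. Control arms follow a linear background drift reaching −1% at
week 12 (so the control subtraction is exercised meaningfully);
treatment arms add the study-level Emax effect and residual noise on the
percent scale, mapped back to mean weights, making the percent-change
and subtraction steps exact inverses of the construction. The default
truth is Emax = −3.92%, ET50 = 3.6 weeks, ω_Emax = 0.106,
ω_ET50 = 0.867 (SDs of exponential η) and σ = 0.1 (residual variance
0.01 at N = 100).

What the generator does *not* emulate: individual-patient variation,
dropout, unequal visit grids, reporting or publication bias, and any
true covariate effect (doses, ages and baselines are design constants).
Passing recovery tests therefore show that the estimator inverts its own
generative assumptions at this scale — not that those assumptions hold
in any particular literature dataset.

## Experiment sizes

The recovery experiment fits 100 replicate datasets (seeds 1–100 in the
test suite; seeds derived from the command-line seed in the acceptance
script) with the full multi-start engine and reports median estimates:
medians recover Emax within a few percent and ET50 within ~5–10% of
truth, comfortably inside the ±15%/±40% test tolerances. The
covariate-null experiment runs 50 replicates with all eight
(covariate × parameter) candidates. Bootstrap and VPC defaults are 1,000
replicates/simulations; unit tests use smaller sizes since the checked
identities do not sharpen with n.

## Known limitations

- **Likelihood-ratio covariate selection is anti-conservative at this
  scale.** With 4 studies, residual noise that is tiny relative to the
  inter-study spread (σ = 0.1 vs ω_ET50 = 0.867) pins down each study's
  (Emax_i, ET50_i) almost exactly, so testing a study-level covariate is
  effectively a regression on 4 points with estimated variance. The
  ΔOFV > 3.84 rule then behaves like an F(1, 2) test with roughly a 20%
  false-positive rate per candidate, and eight candidates are tested per
  round. Simulations under the null therefore include at least one
  covariate in far more than 10% of replicates — the inflation is
  genuine likelihood behaviour, reproduced under 41-node adaptive
  Gauss–Hermite quadrature, not an approximation artifact. A single
  observed dataset can well yield an empty covariate set, but that
  outcome is not a stable calibration property of the χ² threshold with
  so few studies; randomisation-calibrated cutoffs would be needed for
  that.
- The Laplace approximation degrades as ω grows (≈0.2 OFV units error at
  ω_ET50 ≈ 0.9 on default-size data); quadrature agreement is asserted
  only on small-ω instances.
- With 4 studies the ω parameters themselves are weakly identified —
  consistent with the very wide bootstrap intervals the method reports
  for them — and individual-replicate ET50 estimates scatter widely;
  only medians over replicates are stable.
- The bootstrap resamples 4 studies with replacement, so only 35
  distinct datasets exist; percentile intervals at this scale are
  coarse summaries, not exact frequentist intervals.
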