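# carnimax

Model-based meta-analysis (MBMA) of a saturating treatment-effect time
course on **aggregate, arm-level trial data** — built around the
question of how carnitine supplementation changes body weight in
polycystic ovary syndrome (PCOS), where the evidence is a handful of
small randomised trials available only as summary statistics.

It is intended for pharmacometricians and meta-analysts who want the
whole workflow — effect construction, nonlinear mixed-effects fitting,
covariate selection, bootstrap/VPC evaluation and milestone prediction —
as a tested, scriptable Python library rather than a NONMEM project.

## The model

For study *i* at treatment duration *t_ij* (weeks), the **net** percent
change in mean body weight (treatment-arm change from baseline minus
control-arm change, both on the ×100 percent scale) is modelled as

    E_B,ij = Emax_i · t_ij / (ET50_i + t_ij) + ε_ij,   ε_ij ~ N(0, σ²/(N_ij/100))

with `Emax` the asymptotic maximal effect (negative for weight loss),
`ET50` the duration at which half of it is reached, residual noise
weighted by the arm's sample size `N_ij`, and study-level random effects
on `Emax` and/or `ET50` (exponential by default, `Emax_i = Emax·e^η`,
`η ~ N(0, ω²)`). The marginal likelihood integrates η out per study by a
Laplace approximation; an adaptive Gauss–Hermite quadrature oracle
cross-checks it in the tests. Covariates (dose, baseline weight, age,
source) can enter `Emax` or `ET50` and are screened by the conventional
likelihood-ratio stepwise rules (ΔOFV > 3.84 forward, > 6.63 backward).

Because no public dataset exists for this literature, the package ships
a synthetic generator that emulates the documented study structure
(4 two-arm studies, 242 patients, 250–1,000 mg/day, 12-week horizon);
every pipeline stage is exercised against it. See `docs/methods.md` for
assumptions, numerical choices and known limitations.

## Worked example

Run the full workflow on a simulated dataset (generate → fit →
bootstrap → pcVPC → predict):

```sh
carnimax run-all --out example --seed 42 --n-boot 200 --n-sim 1000
```

This writes `data.csv`, `effects.csv`, `fit.json`, `predictions.csv`,
`bootstrap.csv`, `vpc.csv`, `milestones.csv`, `efficacy_bands.csv` and a
`run.log`. With seed 42 the fitted model is

```
Emax -3.746 %   ET50 3.941 wk   omega_emax 0.173   omega_et50 0.173   sigma 0.083
```

— the engine recovers the generator's truth (Emax −3.92%, ET50 3.6
weeks) to within the scatter a 4-study design allows. The bootstrap
summary (200 study-resampled refits):

```
 parameter  estimate  median  ci_2.5  ci_97.5    bias
  emax_pct   -3.7464 -3.7464 -4.6704  -3.2689 -0.0000
et50_weeks    3.9410  3.9410  3.0191   5.5333  0.0000
omega_emax    0.1733  0.1471  0.0000   0.2283 -0.1510
omega_et50    0.1733  0.0000  0.0000   0.6019 -0.9999
     sigma    0.0830  0.0796  0.0445   0.1026 -0.0402
```

Point estimates sit mid-interval with near-zero bias; the ω intervals
are wide — four studies carry little information about inter-study
variability, and `bias` is (median − estimate)/estimate. The pcVPC
covers 91.7% of observations with its simulated 95% band, and the
milestone report inverts the fitted curve analytically:

```
2026-09-21 ... INFO milestones: 25% -> 1.3 wk, 50% -> 3.9 wk, 75% -> 11.8 wk, 80% -> 15.8 wk
```

i.e. with this replicate's ET50 of 3.9 weeks, 80% of the maximal effect
takes ~15.8 weeks of supplementation. (At the reference parameters,
ET50 = 3.6 weeks, the 25/50/75/80% milestones are exactly
1.2/3.6/10.8/14.4 weeks.)

The same stages are available individually (`carnimax simulate | fit |
bootstrap | vpc | predict`) and as library calls
(`carnimax.fit`, `carnimax.bootstrap`, `carnimax.pcvpc`, …).

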