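# dtgam — discrete-time hazard GAMs for longitudinal survival data

`dtgam` fits flexible survival models to longitudinal clinic-visit data in
which the covariates change over follow-up — the setting of the Mayo
primary biliary cirrhosis (PBC) sequential study, where 312 patients were
seen at six months, twelve months, and then yearly, and laboratory values
such as serum bilirubin and prothrombin time were re-measured at every
visit.  It is aimed at biostatisticians who want individual short-term
survival predictions (e.g. "probability of surviving the next six
months") updated at every visit, without the proportional-hazards
assumption that time-dependent covariates violate.

## The model

Each subject's follow-up is expanded into one Bernoulli trial per visit
interval (*person-period expansion*): subject *d* with *l<sub>d</sub>*
visits contributes *l<sub>d</sub>* rows with response δ = 1 only on the
final interval of a subject who died.  The discrete hazard
*h<sub>l</sub>* — the probability of death in interval *l* given survival
to its start — follows a generalized additive model on the logit scale,

```
logit h = β₀ + s₀(t) + s₁(x₁) + ... + s_I(x_I),
```

with each smooth *s<sub>i</sub>* a cubic B-spline expansion (10 interior
knots at covariate quantiles by default) and coefficients estimated by
maximizing the penalized Bernoulli log likelihood

```
ln L(β) − ½ Σᵢ λᵢ ∫ s″ᵢ(u)² du
```

via iteratively reweighted least squares.  The pieces around the fit:

- **Smoothing-parameter choice** — a *variant v-fold CV*: leave one
  *patient* out (all of their rows together), refit, score the held-out
  patient's log likelihood; reported as −2·Σ so it is comparable with
  deviance and AIC.  GCV, AIC, and likelihood-ratio tests with fractional
  effective degrees of freedom are provided for model comparison.
- **Goodness of fit** — the binary-data deviance has no usable chi-square
  reference, so the fit is judged against a bootstrap of the deviance
  (resampling whole patients, or parametrically from the fitted hazards).
- **Prediction** — survival curves S(t_l) = Π (1 − h_i), conditional
  six-month survival Pr(t, Δt) = S(t+Δt)/S(t), and group-averaged curves
  for deceased vs censored patients.
- **Competing risk** — liver transplantation is treated as censoring plus
  a time-dependent 0/1 covariate (1 only at the transplant visit), tested
  by deviance reduction.
- **Synthetic cohorts** — a generator emulating the PBC visit structure
  with known true hazards, so every claim above is testable end to end.

## Worked example

```python
from dtgam import *
from dtgam.selection import aic, grid_search_cv, lr_test
from dtgam.prediction import subject_curves, conditional_at_visits, SIX_MONTHS_DAYS

cfg = SimulationConfig(n_subjects=150)
subjects, truth = simulate_cohort(cfg, seed=11)
table = expand_person_period(subjects)

model = DiscreteHazardGAM(
    [LinearTermSpec("age"), SmoothTermSpec("pro"), SmoothTermSpec("bili")]
)
cv = grid_search_cv(model, table, {"pro": [1e-2, 1, 1e2], "bili": [1e-2, 1, 1e2]})
best = DiscreteHazardGAM(model.terms, cv.best_lambdas)
fit = best.fit(table)
gof = bootstrap_gof(best, table, B=199, alpha=0.05, seed=0)
```

printed output:

```
cohort: 150 subjects, 989 person-period rows, 49 deaths
CV-selected lambdas: {'pro': 100.0, 'bili': 100.0} score 361.40
deviance 348.83  edf 5.07  AIC 358.98
edf by term: {'intercept': 1.0, 'age': 1.0, 'pro': 1.04, 'bili': 2.03}
spline-vs-linear (bili): delta = 7.35 on 1.03 df, p = 0.007092
bootstrap GoF: observed Dev 348.83 vs 95% critical value 393.58 -> no evidence of misfit
six-month survival, subject 14 (died): [0.978, 0.976, 0.986, 0.981, 0.977, 0.945, 0.898]
```

Reading it: the patient-wise CV picks heavy smoothing for both lab
covariates on this cohort; the fitted model spends ≈5 effective degrees
of freedom; the spline term for bilirubin improves on a linear effect
(Δ deviance 7.35 on 1.03 df, p ≈ 0.007); the observed deviance sits below
the bootstrap 95% critical value; and the deceased subject's predicted
six-month survival declines from 0.98 at entry to 0.90 just before death
— the qualitative pattern that motivates visit-by-visit prediction.

The same workflow is available from the shell:

```sh
dtgam simulate --n-subjects 150 --seed 11 --out cohort.csv
dtgam cv  --data cohort.csv --model "age + s(pro) + s(bili)" --out cv.json
dtgam fit --data cohort.csv --model "age + s(pro) + s(bili)" \
          --lam pro=100 --lam bili=100 --out fit.json
dtgam gof --data cohort.csv --model "age + s(pro) + s(bili)" \
          --lam pro=100 --lam bili=100 -B 199 --seed 0 --out gof.json
dtgam predict --data cohort.csv --model "age + s(pro) + s(bili)" \
          --lam pro=100 --lam bili=100 --group-average --out-prefix pred
```

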