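# twopartcac

Two-part (hurdle) models for zero-inflated coronary-artery-calcium scores.

## The problem

Coronary artery calcium (CAC), quantified by the Agatston score from cardiac
CT, is a strong predictor of coronary heart disease events. In a relatively
healthy cohort roughly half of the subjects have a score of exactly zero,
while the rest are continuously and right-skewedly distributed — a "point
mass at zero plus continuous" mixture that ordinary regression cannot
describe. This package implements the two-part modelling framework for such
data, aimed at biostatisticians and epidemiologists studying subclinical
atherosclerosis risk factors: who develops *any* calcium, and how much, as a
function of gender, race/ethnicity, smoking, diabetes, blood pressure, age,
BMI, and LDL/HDL cholesterol.

## The models

Write `t = log(1 + CAC)` and `z = 1{CAC > 0}`. A two-part model pairs a
logistic regression for the occurrence of calcium with a Normal linear model
for its burden:

    P(z = 1 | x) = expit( a0 + s1(x) )
    t | z = 1, x ~ Normal( b0 + s2(x), sigma^2 )

Six variants of the covariate indices `s1, s2` are shipped:

| preset | parts        | covariate effects                                  |
|--------|--------------|----------------------------------------------------|
| `i.1`  | proportional | linear for all 13 covariates                       |
| `i.2`  | proportional | linear + quadratic LDL and HDL                     |
| `ii.1` | free         | linear for all 13 covariates                       |
| `ii.2` | free         | linear + quadratic LDL and HDL                     |
| `iii`  | proportional | penalized-spline age/BMI/LDL/HDL, linear otherwise |
| `iv`   | free         | penalized-spline age/BMI/LDL/HDL, linear otherwise |

*Proportional* variants constrain the two parts to share a single risk index
up to a scale factor, `s2 = tau * s1` — the hypothesis that one biological
process drives both the occurrence and the burden of calcium. Semiparametric
variants give designated covariates smooth effects `f_k` estimated by
penalized maximum likelihood, with the roughness penalty
`lambda * sum_k integral f_k''(u)^2 du`. Inference for every parameter uses
the parametric bootstrap (simulate responses from the fitted model at the
observed covariates, refit, take replicate SDs); nested variants are
compared by bootstrap-calibrated likelihood-ratio tests; out-of-sample
performance is measured by repeated random 50/50 train/test splits
(dichotomize the predicted probability at 0.5; overall MSE on the `t` scale
with zeros included).

Because the motivating cohort data are access-restricted, the package
includes a first-class synthetic cohort generator
(`twopartcac.generate_cohort`) with realistic covariate marginals and
known ground-truth parameters, which every downstream stage is tested
against.

## Worked example

```python
import twopartcac as tp

truth = tp.example_truth("i.1", tau=0.67)          # proportional, linear effects
cohort = tp.generate_cohort(truth, n=4000, seed=7)
print("zero fraction:", round((cohort.cac == 0).mean(), 3))

model = tp.fit("i.1", cohort)                      # scikit-learn-style estimator
print("tau_hat:", round(model.tau_, 3), " sigma_hat:", round(model.sigma_, 3))

boot = tp.parametric_bootstrap(model, cohort[model.spec_.covariates], B=200, seed=8)
print("bootstrap SE(tau):", round(boot.se["tau"], 3))

lrt = tp.bootstrap_lrt("i.1", "ii.1", cohort, B=99, seed=9)
print("LRT i.1 vs ii.1: Lambda =", round(lrt.statistic, 2), " p =", round(lrt.p_value, 3))

summary = tp.monte_carlo_evaluation(["i.1", "i.2", "ii.1"], cohort,
                                    tp.SplitPlan(n_splits=50, seed=10))
print(summary)
```

prints

```
zero fraction: 0.506
tau_hat: 0.651  sigma_hat: 1.302
bootstrap SE(tau): 0.043
LRT i.1 vs ii.1: Lambda = 23.39  p = 0.1
  i.1: error rate 0.3236 (0.0095)   MSE 7.3810 (0.2302)
  i.2: error rate 0.3241 (0.0095)   MSE 7.3916 (0.2321)
 ii.1: error rate 0.3243 (0.0088)   MSE 7.3954 (0.2197)
```

Half the simulated scores are zero; the proportional scale parameter is
recovered near its true value 0.67 with a bootstrap SE of ~0.04; the
likelihood-ratio test correctly fails to reject proportionality on data
generated under it (p = 0.10); and the three variants predict almost equally
well — the mean binary error rate and overall MSE across 50 random splits,
with their split SDs in parentheses.

The same pipeline is available from the shell:

```bash
twopartcac simulate --n 4000 --seed 7 --out cohort.csv
twopartcac fit --spec i.1 --data cohort.csv --out fit.json
twopartcac bootstrap --fit fit.json --data cohort.csv --B 200 --seed 8 --out boot.json
twopartcac lrt --null i.1 --alt ii.1 --data cohort.csv --B 99 --seed 9
twopartcac predict-eval --specs i.1,i.2,ii.1 --data cohort.csv --splits 50 --seed 10 --out pe.json
twopartcac report --fit fit.json --bootstrap boot.json --outdir report/
```

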