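# Methods

## Model family

The response is a nonnegative Agatston-type score whose distribution mixes a
point mass at zero with a continuous right tail. We model
`t = log(1 + CAC)` and `z = 1{CAC > 0}` jointly:

    P(z = 1 | x) = expit(eta1),   eta1 = a0 + s1(x)
    t | z = 1, x ~ N(eta2, sigma^2),   eta2 = b0 + s2(x)

The link is fixed to logistic and the positive-part error to Normal on the
log scale; the package varies only the structure of the covariate indices:

- **parametric vs semiparametric** — every effect linear (optionally
  quadratic for LDL and HDL), or penalized-spline smooths for age, BMI, LDL
  and HDL with parametric effects for the seven binary covariates and both
  blood pressures;
- **proportional vs free** — `s2 = tau * s1` (one shared risk index, scale
  factor `tau`), or unconstrained part-specific coefficients.

The per-subject log-likelihood is

    l_i = (1 - z_i) log(1 - p_i)
        + z_i [ log p_i - log sigma - (t_i - eta2_i)^2 / (2 sigma^2) - log(2 pi)/2 ]

with `p_i = expit(eta1_i)`. The Normal constant is kept so that likelihood
values are directly comparable across nested variants (it cancels in any
difference). `log p` and `log(1 - p)` are computed through `logaddexp`
(no probability clipping), so the likelihood is finite for any finite
parameters.

Semiparametric variants maximize the penalized criterion

    (1/n) sum_i l_i  -  lambda * sum_k theta_k' Omega_k theta_k

where `theta_k' Omega_k theta_k` equals the integrated squared second
derivative of the k-th smooth. Each distinct spline coefficient block is
penalized once: both parts for the free variant, the shared block for the
proportional one. A single `lambda` is shared across smooth terms by
default; a per-term override is possible by fitting with a custom
`ModelSpec`.

## Spline machinery

Smooths are cubic B-splines with `q = 10` basis functions per term and
interior knots at empirical quantiles of the observed covariate. The penalty
matrix `Omega` (`integral B_i'' B_j'' du`, in raw covariate units) is
computed exactly by per-interval 3-point Gauss–Legendre quadrature — the
integrand is piecewise polynomial of degree 2 for cubic splines — and its
null space contains all affine coefficient vectors.

Identifiability: the intercepts must absorb the level of every smooth term,
so each fitted curve has empirical mean zero on the fitting data. Because
B-splines form a partition of unity, merely subtracting column means leaves
an exact flat direction (all-equal coefficients represent the zero function
at zero penalty); the constraint `c' theta = 0` (with `c` the basis column
means) is therefore absorbed into the basis through an orthonormal map into
its `(q - 1)`-dimensional null space, the standard sum-to-zero
reparameterization for penalized additive models. Prediction at covariate
values outside the training range clamps to the nearest boundary knot and
warns in the documentation of the prediction contract.

## Estimation

The free (nonproportional) likelihood separates: the logistic part is
maximized by damped Newton iterations on the concave penalized objective,
and the continuous part alternates a closed-form ridge-type solve for the
coefficients with the `sigma^2 = SSR / n1` update (the MLE denominator `n1`,
keeping "maximizer of the likelihood" literal) until joint stationarity.

The proportionality constraint couples the parts, so proportional variants
maximize the joint penalized likelihood over `(a0, b0, theta, tau,
log sigma)` with an exact trust-region Newton method using the analytic
gradient and Hessian (`sigma` on the log scale). Exact Newton was chosen
over quasi-Newton because fits must run tens of thousands of times inside
bootstrap and Monte-Carlo loops; with the analytic Hessian a fit at
n = 2000 converges in under ten iterations and a few tens of milliseconds.
Warm starts come from the separable fit of the same effect structure, with
`tau` started at the least-squares slope of the continuous-part coefficients
on the logistic-part coefficients (consistent under a proportional truth).
On failure the optimizer restarts up to three times from jittered starts.
Convergence requires the sup-norm of the per-observation criterion gradient
below 1e-4 (typically ~1e-9 is reached).

The shared index is anchored in the logistic part by default — its
coefficients carry the logistic scale and `tau` maps them into the
continuous part. Anchoring in the continuous part instead
(`anchor="continuous"`) is an exact reparameterization; the fitted `tau`
inverts (`tau' = 1/tau`) and the likelihood is unchanged, which the tests
verify.

Degenerate data are reported, never silently regularized: a cohort whose
indicator is constant, or a perfectly separated logistic part (detected by
unbounded coefficient drift, |eta| beyond 40 with a non-vanishing gradient)
raises an error. When the shared covariate index carries no information the
scale parameter `tau` is unidentified; the fit flags this through the
curvature-based relative SE of `tau` (threshold 0.15, chosen from the
clear two-orders-of-magnitude gap between well-identified fits, which sit
below ~0.08 down to n = 400, and all-noise indices, above ~0.2), records it
in the convergence report, and warns.

## Tuning-parameter selection

The source framework defers the choice of `lambda` to an external procedure
it does not reproduce, so this package specifies its own stand-in: K-fold
cross-validation (default 5 folds) on the held-out *unpenalized*
log-likelihood over a log-spaced grid (default 1e-4 … 1e2, 13 points), with
ties broken toward the larger (smoother) value. Within the Monte-Carlo
prediction protocol, tuning runs inside each training half only, so no
information leaks from the test half.

## Bootstrap inference

Standard errors for all parameters in all variants use the parametric
bootstrap: hold the covariates fixed, simulate `z` from the fitted logistic
part and `t | z = 1` from `N(eta2_hat, sigma_hat^2)` (same truncation rule as
the generator), refit the same spec, and take replicate SDs (default
B = 500). `lambda` is held at the value selected on the original data
rather than re-tuned per replicate — re-tuning would multiply cost roughly
13-fold with second-order effect on the SEs; this is a documented
limitation. Replicates that fail to converge are dropped and logged, up to
10% of B; beyond that the run aborts. Per-replicate seeds derive from the
master seed by a counter scheme, so results are reproducible replicate by
replicate and independent of execution order.

Nested variants are compared by the likelihood-ratio statistic
`Lambda = 2 (ll_alt - ll_null)` (unpenalized log-likelihoods) calibrated
against its parametric-bootstrap distribution under the fitted null, with
the finite-B corrected p-value `(1 + #{Lambda_b >= Lambda}) / (B + 1)`,
never exactly zero. Nesting is checked against the preset lattice
(quadratics and linear effects lie in the cubic-spline span; proportional
variants are constrained versions of their free counterparts). With a
penalized semiparametric alternative the observed statistic can in
principle be negative at large `lambda` (the penalized optimum need not
dominate the null's MLE in unpenalized likelihood); at tuned values this
does not occur in practice. Bonferroni adjustment multiplies p-values by
the number of comparisons, capped at one.

## Prediction protocol

One split: a random equal partition (training gets the extra subject for
odd n); every candidate variant is fitted on the training half; for each
test subject the predicted probability of nonzero CAC is dichotomized at 0.5
(strict inequality — a tie predicts zero), and the continuous part supplies
`t_hat` only when nonzero status is predicted, floored at zero (a negative
log-scale prediction is incompatible with a predicted nonzero score). Two
metrics per variant: the binary error rate, and the overall MSE on the `t`
scale including zeros (`t_hat = 0` whenever `z_hat = 0`) — a positive-only
MSE is ill-defined because the predicted-positive and observed-positive
subject sets differ. The Monte-Carlo summary repeats this over `n_splits`
deterministic sub-seeds (default 500) and reports mean (SD) per variant.

## Synthetic cohort generator

The generator emulates the structure of a multi-ethnic subclinical-
atherosclerosis cohort: 13 covariates (7 binary, 6 continuous), a
race/ethnicity mix proportional to the published cohort composition
(2619 : 1898 : 1494 : 803 against a Caucasian reference), truncated-normal
continuous marginals in physiological units (SBP 126 ± 21 mmHg, DBP 72 ±
10 mmHg, age 62 ± 10 y on [45, 84], BMI 28.3 ± 5.4 kg/m², LDL 117 ± 31
mg/dL, HDL 51 ± 15 mg/dL), and responses drawn from any of the six variants
with known parameters. Covariates are independent by default (no joint law
is specified by the source framework); a Gaussian-copula correlation hook
over the continuous covariates exists for stress tests.

Shipped example truths use published-style signs and rough magnitudes for
the seven binary effects and both blood pressures (e.g. male ≈ +0.97 on the
logistic scale), invented plausible values for the four effects the
reference treats nonparametrically, scale factor `tau = 0.67`, and error SD
`sigma = 1.3`; intercepts are calibrated analytically so that about half of
the simulated scores are zero and mean `t` among nonzero scores is ≈ 4.4
(Agatston ≈ 80). These values are defaults for simulation studies, not
estimates of any real cohort. An optional U-shaped HDL effect
(`0.0009 (HDL - 51)^2`, centered) emulates a strongly nonlinear lipid
association for detectability studies.

Simulated positive-part draws with `t <= 0` are redrawn (truncation), which
keeps `z = 1 <=> t > 0` exact; with the default truths `P(t <= 0 | z = 1)`
is below 1e-3, so the distortion of the Normal assumption is negligible.
What passing tests on these cohorts do **not** show: robustness to
covariate correlation, measurement error, site/scanner effects, missing
data, or misspecified error laws — none of which the generator emulates.

## Test-suite problem sizes

The end-to-end suite runs at desk scale (about seven minutes on one CPU);
sizes were fixed as the package's own choices:

- separable-fit oracle vs an independent logistic + least-squares fit:
  n = 2000, agreement 1e-6;
- nesting lattice of log-likelihoods: 20 cohorts of n = 1000, slack 1e-6;
- parameter recovery per variant: point fit at n = 20000 against 3
  Monte-Carlo SEs from 60 replicate fits at n = 2000;
- scale-parameter recovery and anchoring swap: n = 5000, B = 60,
  `tau * tau' = 1` to 1e-4;
- heavy-penalty limit (`lambda = 1e6`, all-linear truth): smooths affine to
  1e-4 sup-norm, coefficients matching the all-linear fit to 1e-3;
- bootstrap SE calibration: intercept-only vs closed-form information SE
  (n = 4000, B = 500, 15%); `tau` bootstrap SE vs Monte-Carlo SD over 200
  cohorts at n = 2000 (20%);
- bootstrap LRT size: 200 outer cohorts of n = 600 at B = 99, empirical
  rejection rate within the binomial envelope [0.02, 0.09] at nominal 0.05;
- U-shape detectability: n = 10000, tuned `lambda`, fitted HDL curve beats
  the best affine approximation of the truth in integrated squared error;
- prediction comparison: mean MSEs averaged over three cohorts (n = 3000,
  100 splits each) — a single cohort's ordering noise exceeds the tiny
  true gap between the best variants, so the averaged design resolves the
  ordering above Monte-Carlo noise.

## Known limitations

- `lambda` selection is a cross-validation stand-in, not the source
  framework's (unreproduced) procedure; fitted smooths are comparable in
  shape but not knot-for-knot.
- Bootstrap refits reuse the original `lambda`.
- Partially proportional variants (some effects shared, others free) are
  out of scope by design.
- Asymptotic (information-matrix) SEs are used only as test oracles; all
  reported inference is bootstrap-based.
- The prediction metrics condition on the dichotomize-at-0.5 rule; no
  calibration curves or AUROC are computed.
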