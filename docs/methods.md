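# Methods

This document describes the statistical model, the synthetic-cohort
generator, the dose-error-correction estimators, and the numerical choices
made in `thyrocal`. It is the package's self-contained scientific account;
the API reference lives in the docstrings.

## 1. Scientific setting

The package studies dose–response estimation for thyroid disease prevalence
in a screening cohort whose individual radiation doses are reconstructed,
not observed. A subject's thyroid dose is computed from a *measured*
thyroid radioiodine activity and an *assigned* thyroid mass:

    D_mes = c * A_mes / M_assigned          (measured/reconstructed dose)
    D_true = c * A_true / M_true            (latent true dose)

with `c` a fixed physical scaling constant. The two inputs carry errors of
opposite statistical character:

- **Classical error (activity).** The instrument measures the true
  activity with multiplicative lognormal noise,
  `A_mes = A_true * eps`, `ln eps ~ N(0, sigma_eps^2)` with per-subject
  `sigma_eps = ln gsd_A`. Classical error inflates the spread of measured
  doses and attenuates naive dose–response slopes toward the null.
- **Berkson error (mass).** The mass is assigned from an age-by-sex
  population growth table; the subject's true mass scatters around the
  assignment, `M_true = M_assigned * delta`, `ln delta ~ N(0,
  sigma_delta^2)` with `sigma_delta = ln gsd_M`. Berkson error leaves
  linear-model slopes approximately unbiased but adds residual dose
  uncertainty.

Both error magnitudes are expressed as geometric standard deviations
(GSDs); GSD = 1 means no error.

## 2. Risk model

Prevalent case status is Bernoulli with odds

    odds_i = exp(beta0 + beta_age[cat(a_i)] + beta_sex * male_i) * (1 + EOR_i)

where `a` is age at screening and the excess odds ratio (EOR) takes one of
six nested forms in dose `D` (Gy), age at exposure `e`, and sex:

    1  alpha * D
    2  alpha * D * exp(gamma * D)
    3  alpha * D * exp(gamma * D + kappa * (e - 8))
    4  alpha * D * exp(gamma * D + tau * (a - 22))
    5  alpha * D * exp(gamma * D + psi * (a - e - 14))
    6  alpha * D * exp(gamma * D + eta * 1{male})

Ages are centred at 8 (exposure), 22 (screening) and 14 (time since
exposure) years, near the cohort means, so forms 2–6 nest cleanly and the
modifier parameters are interpretable as log-rate changes per year at the
cohort centre. `alpha` is the slope of the EOR at zero dose (Gy^-1);
`gamma < 0` expresses downward curvature (cell-killing-type flattening at
high dose).

All parameters are estimated by maximum likelihood (Section 5).
Confidence intervals are profile-likelihood based: the 95% interval is the
set of parameter values whose profile log-likelihood lies within
chi2_1(0.95)/2 = 1.9207 of the maximum. Nested forms are compared by
likelihood-ratio tests against the chi-squared reference.

## 3. Synthetic cohort generator

`generate_cohort(CohortConfig(), seed)` produces one cohort. The default
configuration encodes the study conditions:

- **n = 13,127 subjects** across 3 regions x 3 age-at-exposure bands
  (9 strata), region probabilities (0.40, 0.32, 0.28).
- Age at exposure `e ~ 18 * Beta(1.6, 2)`; screening occurs 12–14 years
  later (`a = e + U(12, 14)`); equal sex probabilities.
- Assigned mass from a built-in age-by-sex median growth table
  (log-linear interpolation, 1 g floor). True mass applies the Berkson
  factor.
- True activity is stratum-lognormal with the log-scale mean chosen so the
  implied error-free dose has the configured per-region median (0.15,
  0.20, 0.30 Gy) and log-SD 1.4; this makes the measured dose very nearly
  lognormal (QQ correlation > 0.99), matching the analysis assumption.
- **Activity GSDs** are drawn from a shifted truncated lognormal with
  support [1.11, 10.13] and mean ~1.35, with heavier parameters below an
  error-free dose of 0.5 Gy (counting error grows at low activity).
- **Mass GSDs** follow `1.41 - 0.13 * Beta(1, 5.5)`: support [1.28, 1.41],
  mean exactly 1.39, median ~1.40. A uniform distribution on the same
  support could not reproduce a mean of 1.39; the left-skewed Beta form is
  the simplest shape consistent with that range/mean/median combination.
- Case status is drawn at the **true** dose under form-2 truth
  (alpha = 9 Gy^-1, gamma = -0.10 Gy^-1, female baseline excess
  beta_sex = -0.7, age-category offsets 0.3/0.6 above ages 20/24); the
  intercept beta0 is solved by root finding so the expected case count is
  45.
- Optional features: a shared per-stratum multiplicative activity error
  (`shared_error_logsd`) and missing measured doses (`n_missing`), which
  loaders drop with a logged count.

`CohortConfig.simple(...)` builds a single-stratum, constant-mass,
constant-GSD design. In that regime the lognormal latent models of both
calibration methods are exactly well specified, which is what the
parameter-recovery and calibration studies require.

What the generator does **not** emulate: ultrasound screening logistics,
diagnostic verification bias, spatial dose correlation beyond the optional
shared factor, iodine-deficiency covariates, or time trends in the growth
table. These are out of scope for the estimator-focused studies here.

## 4. Dose-error correction

### 4.1 Latent lognormal deconvolution

For a measured value `V = exp(X + eps)` with latent `X ~ N(mu_X, sigma_X^2)`
per stratum and known per-subject classical log-SD `sigma_eps`,
`fit_latent_lognormal` maximizes the marginal normal likelihood
`ln V_i ~ N(mu_X, sigma_X^2 + sigma_eps_i^2)` by L-BFGS-B with an analytic
gradient, flooring `sigma_X^2` at 0. With homogeneous errors this reduces
to the closed-form deconvolution `sigma_X^2 = max(0, s^2 - sigma_eps^2)`.
Strata with fewer than 10 subjects fall back to pooled estimates.

### 4.2 Regression calibration

The corrected dose is the conditional expectation of the true dose given
the measurements. Under the conjugate lognormal model the posterior of the
latent log-dose is Normal with

    mu_c = (sigma_eps^2 * mu_X + sigma_X^2 * ln D_mes) / (sigma_X^2 + sigma_eps^2)
    sigma_c^2 = sigma_X^2 * sigma_eps^2 / (sigma_X^2 + sigma_eps^2)

and the Berkson mass factor contributes `E[1/delta] = exp(sigma_delta^2/2)`
independently, giving

    E[D | D_mes] = exp(mu_c + sigma_c^2 / 2) * exp(sigma_delta^2 / 2).

Two variants are provided, differing in the scale on which the latent
lognormal population model is fitted:

- **RC1 (dose scale):** the latent model is fitted to the measured doses
  directly.
- **RC2 (activity scale):** the latent model is fitted to the measured
  activities; the corrected dose is
  `c * E[A | A_mes] * exp(sigma_delta^2/2) / M_assigned`.

Both closed forms are verified against independent numerical-quadrature
oracles in the test suite. When all GSDs are 1, both reduce exactly to the
measured dose.

### 4.3 Monte-Carlo maximum likelihood (MCML)

Rather than substituting a single corrected dose, K realizations per
subject are drawn from the conditional dose distribution,
`D^(k) = exp(X^(k)) / delta^(k)` with `X^(k) ~ N(mu_c, sigma_c^2)` and
`ln delta^(k) ~ N(0, sigma_delta^2)`, and the integrated likelihood

    ll(theta) = sum_i ln[ (1/K) sum_k L_i(D_i^(k); theta) ]

is maximized. The per-subject sample mean of the draws converges to the
RC1 dose as K grows, so MCML and regression calibration agree closely in
this setting; MCML additionally propagates dose uncertainty into the
likelihood shape. Externally produced realization matrices (e.g. from a
two-dimensional Monte-Carlo dosimetry system) can be supplied as
long-format CSV in place of the internal sampler.

## 5. Numerical choices

- **Optimization.** Penalized negative log-likelihood with analytic
  gradients, L-BFGS-B (ftol 1e-12, gtol 1e-8), 5 starts (one deterministic
  plus seeded perturbations of the dose-response parameters) and a final
  polish from the best point. The feasibility constraint `1 + EOR > 0` is
  enforced by a smooth penalty. Starting values scale with the mean dose,
  making fits equivariant under a rescaling of the dose axis.
- **Profile CIs.** Bracket doubling from the estimate followed by Brent
  root finding on `profile ll - (max ll - 1.9207)`; endpoints that hit the
  feasibility boundary or fail to bracket are flagged on the fit result.
- **MCML internals.** Per-subject log-sum-exp with max subtraction;
  analytic gradient via softmax weights over draws; infeasible draws
  contribute zero likelihood; the optimizer warm-starts at the fixed-dose
  fit at the per-subject posterior-mean doses. Profile CIs on the
  integrated likelihood reuse the same draws (common random numbers) so
  Monte-Carlo noise cancels between the numerator and denominator fits.
- **Reproducibility.** Every stochastic routine takes an explicit seed or
  `numpy` Generator; the pipeline writes a configuration hash into each
  artifact and produces byte-identical output for a fixed configuration
  and seed.

## 6. Study designs used in the verification suite

The test suite fixes several simulation designs. They were chosen from
power considerations *before* running the checks, and are part of the
experiment definition:

- **Slope recovery / attenuation:** 20 replicates of n = 50,000 at true
  alpha = 5 Gy^-1, ~2% cases, with classical-only (GSD 1.35) and
  Berkson-only (GSD 1.39) error arms, at the study's dose distribution
  (median 0.2 Gy, log-SD 1.4).
- **CI coverage and LRT size:** 200 replicates of n = 5,000 with an
  inflated (~10%) case fraction and a tighter, higher dose distribution
  (median 0.5 Gy, log-SD 1.0). At the study's own ~0.3% case fraction the
  curvature parameter is so weakly identified at n = 5,000 that the LRT
  statistic is severely short-tailed; the more informative design tests
  the asymptotic calibration the procedure is supposed to have.
- **Curvature direction:** 20 replicates of n = 10,000 at alpha = 9,
  gamma = -0.10, ~5% cases, checking that the linear fit's slope is below
  the linear-exponential fit's slope-at-zero.

## 7. Limitations

- The regression-calibration formulas assume the latent log quantity is
  Normal within stratum; under the default multi-stratum generator this
  holds only approximately (mixtures of lognormals), which is the realistic
  misspecification regime rather than a defect.
- The Berkson factor `exp(sigma_delta^2/2)` is the conditional-mean
  correction for a median-unbiased mass assignment. In a logistic model
  the effect of Berkson error on the slope is partly absorbed by the
  nonlinearity, so naive and corrected slopes differ by only a few percent
  at the study's error magnitudes.
- Finite-sample maximum-likelihood estimates of the EOR slope are
  right-skewed at realistic case counts; replicate means can sit a few
  percent above truth even for unbiased designs. Verification tolerances
  account for this where the design permits.
- MCML assumes the sampling model for the dose draws is the same lognormal
  shrinkage model used by RC1; it quantifies dose uncertainty, not model
  misspecification.
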