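# Methods

## Model

`cfjoint` fits a multivariate joint model for K = 1–3 longitudinal
biomarkers and the age at first pulmonary exacerbation (PE).

**Longitudinal submodels.** Each outcome follows a linear mixed model over
age. The fixed design contains an intercept, a natural cubic spline in age
(df = 3 by default; df = 2 is the reduced configuration used when three
outcomes are modelled simultaneously), the configured baseline covariates
(sex, Hispanic ethnicity, low socioeconomic status, genotype and
birth-cohort dummies), the acquired time-varying covariates (MRSA,
*Pseudomonas aeruginosa*, CF-related diabetes, pancreatic-enzyme use —
step functions that switch on at an onset age and never revert), the
number of encounters in the prior year (half-open window (t−1, t], an
irregular-sampling adjustment), and optional covariate-by-spline
interactions. The random design is an intercept plus an age slope centred
at 13 years; the stacked random effects across outcomes share one
unstructured multivariate-normal covariance, which is the sole channel of
cross-outcome correlation.

Natural splines use the truncated-power natural basis (linear beyond the
boundary knots, which sit at the eligibility window edges 6 and 20 years);
interior knots default to equally spaced quantiles of observed ages. Ages
are rescaled to [0, 1] across the boundary span before powers are taken,
for conditioning.

**Event submodel.** A proportional-hazards model on the age scale with
delayed entry: patients contribute to the risk set only from their first
recorded encounter, and the likelihood integrates the hazard from entry
age, never from birth. The linear predictor is

    log h_i(t) = log h0(t) + γ'ω_i(t) + Σ_k a_k (m_ki(t) − c_k),

the "current-value" association: the hazard loads on the error-free
model-implied biomarker, and exp(a_k) is the hazard ratio per unit of
marker k. The centring constants c_k (defaults 0; the bundled
configurations use the approximate cohort means, 90 for FEV₁ and 50 for
percentiles) are pure reparameterisations absorbed by the baseline hazard;
they leave every hazard ratio unchanged and markedly improve the
conditioning of the survival-block posterior. Two baseline-hazard families
are provided: `log h0(t) = B(t)'θ` with a cubic B-spline basis (default 5
basis functions, interior knots at quantiles of observed exit ages,
constant continuation outside the age window), and a Weibull baseline in
(log shape, log scale) form, whose closed-form cumulative hazard anchors
the simulation oracles.

**Quadrature.** Cumulative hazards use 15-node Gauss–Legendre quadrature
applied piecewise: pieces split at covariate switch ages (where the
integrand jumps) and long pieces are subdivided to at most two years. On
smooth test integrands this agrees with a 10⁵-point trapezoid reference to
better than 1e−6 relative.

## Estimation

Blocked Metropolis-within-Gibbs, one sweep per iteration:

* **Random effects** — independence proposal from the exact Gaussian
  conditional implied by the longitudinal data and the random-effects
  prior; the Metropolis correction is the change in each patient's
  survival log likelihood. All patients update in one vectorised step,
  and because the association coefficients are small the acceptance rate
  is high, giving near-independent draws.
* **Fixed effects** — the analogous device per coefficient block
  (conjugate normal proposal, survival-term correction).
* **Residual variances** — conjugate inverse-gamma draws
  (IG(0.01, 0.01) prior).
* **Random-effects covariance** — conjugate inverse-Wishart draw
  (df = q + 2, identity scale). We chose the conjugate inverse-gamma /
  inverse-Wishart pair over half-Cauchy-type and decomposition-based
  priors: at registry-scale data the prior is immaterial, the conjugate
  updates are exact and fast, and both scales are configurable.
* **Survival block** (baseline coefficients, γ, associations a) —
  adaptive random-walk Metropolis with the Haario empirical-covariance
  proposal, five sub-steps per sweep. Adaptation runs during burn-in
  only, so retained draws come from a fixed kernel.

Priors elsewhere are independent zero-mean normals: sd 10³ on
longitudinal fixed effects (effectively flat), 10 on γ and baseline
coefficients, 5 on associations. Initialisation: per-outcome least
squares for the longitudinal blocks, zero for random effects and the
survival block, a crude event-rate constant for the baseline.

The default run length is 900 iterations with 600 burn-in, matching the
shard-fitting practice this package emulates. Three hundred retained
draws is marginal, so every fit attaches per-parameter effective sample
sizes and split-chain R-hat; recovery studies in the test suite use
2400/900 sweeps because at 900/600 the association's effective sample
size (~70) adds visible Monte-Carlo noise to per-replicate posterior
means. The sampler was validated end-to-end against an independent
random-walk Metropolis on the marginalised (random-effects-integrated)
posterior of a reduced model.

**Shard pooling.** For cohorts too large to fit at once, patients are
partitioned into event-balanced shards (shuffled within event strata,
dealt round-robin), each shard fitted separately, and retained draws
pooled by simple concatenation (equal shard weight). Concatenation
understates between-shard variability — the combining rule is isolated
behind one function so alternatives can be slotted in.

## Dynamic prediction

For a patient event-free at landmark t, the PE-free probability over
(t, u] is the posterior expectation of S_i(u|b,θ)/S_i(t|b,θ). Whole
parameter draws θ are resampled from the posterior (never plugged in as
means — the credible band carries full parameter uncertainty); for each θ
the random effects are drawn from p(b | history, T > t, θ) by
independence Metropolis–Hastings whose Gaussian proposal is centred at
the conditional mean of the longitudinal+prior part. Default Monte-Carlo
size: 200 θ-draws × 1 b-draw; the credible interval is the central 95% of
the Monte-Carlo sample of survival ratios. The renormalisation identity
π(u|t₂) = π(u|t₁)/π(t₂|t₁) for landmarks t₁ < t₂ with no intervening data
holds by construction and is verified within Monte-Carlo error in the
tests.

## Evaluation

* **Kaplan–Meier** with left truncation (lifelines), Greenwood-based
  bands; the median is reported as "not reached" when the curve never
  falls to 0.5.
* **Dynamic AUC** at landmark t and window Δ: over pairs (case i with an
  event in (t, t+Δ], control j known event-free through t+Δ), the
  proportion with risk_i > risk_j, ties counting ½, where risk = 1 −
  predicted PE-free probability. Patients censored inside the window are
  excluded from pairs by default; an inverse-probability-of-censoring-
  weighted variant (weights from the Kaplan–Meier of the censoring
  distribution) is available behind a flag because the estimator's
  censoring handling is a genuinely open choice.
* **Cross-validation harness**: per repetition, subsample patients
  (default 700), split into patient-level folds (default 5 — the
  operationally described procedure; fold count is configuration),
  fit on the rest, score held-out landmark risks at ages 12 and 16 with
  windows 0.5/1/2 years. Everything derives from one seed.
* **Parameter recovery**: bias, RMSE and HPD coverage across replicate
  simulate-and-refit runs, matched to the generator's truth by parameter
  name.

## Synthetic registry generator

The generator realises exactly the model above — fixed-effect age curves
are projected onto the same natural-spline basis the fitter uses, so
basis mismatch cannot masquerade as estimation bias, and event times come
from the model's own hazard by inverse-transform sampling (draw
E ~ Exp(1), solve Λ(T) − Λ(entry) = E on the quadrature-based cumulative
hazard, walking yearly/switch-age segments lazily).

Default study conditions (all configurable):

* n = 300 patients; eligibility ages 6–20; entry age 6 + 14·Beta(0.7, 2.2)
  (median ≈ 8.5 y, matching a registry entering in mid-childhood).
* Visits: renewal process with exponential gaps, 4 encounters/year.
* Baseline covariate frequencies at the registry's overall values (male
  51.6%, Hispanic 8.7%, low SES 49.8%, genotype 48.1/38.2/13.7%,
  five birth-cohort categories).
* Acquired covariates: probability already-on at entry of 7.4% (MRSA),
  19.6% (Pa), 3.9% (CFRD), 39% (enzymes), plus small yearly onset rates.
* FEV₁ % predicted declining from ≈97 at age 6 to ≈74 at 20 with
  between-patient SD 13 (intercept) and 1.2 (slope), residual SD 7;
  growth percentiles near the registry medians (BMIp ≈ 49 at entry) with
  intercept SD 24 and residual SD 8–9; intercepts correlated 0.35 across
  outcomes. Percentile outcomes are clipped to [0, 100] and FEV₁ to ≥ 1,
  a mild boundary misspecification affecting ~3% of growth observations.
* Associations a = (−0.03, 0) for (FEV₁, growth marker): hazard ratio
  0.97 per % predicted, null growth association.
* Weibull baseline hazard, shape 3.5 and scale 18.0, calibrated once so
  that with exponential dropout (rate 0.25/y; median follow-up ≈ 2.5 y)
  and administrative censoring at 20 about one third of patients have an
  observed first PE — the cohort's event fraction.

**What the generator does not emulate.** Dropout is independent of
severity (missing at random holds by construction, and stronger: missing
completely at random given covariates); registry follow-up that is
correlated with risk profile is not reproduced. One visible consequence:
the synthetic Kaplan–Meier median onset age is ≈14.5 years, earlier than
the ≈19.5 years seen in registry data, because matching both the event
fraction and a late median requires exactly the dependence between
follow-up and risk that the generator omits. The generator also measures
every configured outcome at every visit, has no secular-trend effects
beyond birth-cohort indicators, and its rates of decline are free
parameters, not registry estimates. Passing recovery tests therefore
demonstrates correctness of the estimation machinery under the stated
model, not registry realism.

## Numerical choices and edge cases

* Quadrature: 15-node Gauss–Legendre per smooth piece, pieces ≤ 2 years.
* HPD intervals by sorted-window search (narrowest window containing the
  target mass); Bayesian two-sided tail probability
  2·min(Pr(>0), Pr(<0)) at draw resolution.
* Marginal likelihood (used only as an oracle): adaptive Gauss–Hermite,
  product rule, integrand recentred at the per-patient conditional mode
  with the numerical-Hessian scale; practical to ~6 random-effect
  dimensions.
* Zero comparable pairs in an AUC cell yields NaN, not an exception;
  all-censored Kaplan–Meier reports the median as not reached (inf).
* Ties in AUC scores count ½; encounter-count windows are half-open
  (t−1, t] so a visit exactly one year earlier is not double counted.
* Degenerate posterior summaries (all draws equal) return SD 0 and a
  point HPD.

## Problem sizes

The test suite and the acceptance script run reduced designs chosen to
keep Monte-Carlo error well inside the asserted tolerances: recovery uses
20 replicates of n = 300 (tests) or 8 replicates (script); the
cross-validation demonstrations use 400 patients with 2–5 repetitions and
shortened chains (300/150) for fold fits; oracle comparisons use 4,000 to
100,000 Monte-Carlo draws as stated per test.

## Known limitations

* Simple concatenation pooling ignores between-shard variability.
* The dynamic AUC's default censoring rule (exclusion) is optimistic when
  censoring inside the window is heavy; use the IPCW flag there.
* No competing risks, recurrent events, interval censoring, or
  slope-type association structures.
* At the default 900/600 run length the survival block's effective sample
  size is marginal; consult the attached diagnostics and lengthen runs
  for publication-grade summaries.
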