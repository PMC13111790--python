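# Methods

## Model

`mcace` estimates complier average causal effects (CACEs) on latent
constructs in two-arm randomized trials where (i) K continuous endpoints
are measured at a shared schedule of J+1 visits, (ii) a binary treatment
receipt D is observed in the intervention arm only, and (iii) the control
arm has no access to the intervention.  Under no-access, the joint
potential receipt (D(1), D(0)) defines exactly two principal strata —
compliers (1, 0) and never-takers (0, 0) — and stratum membership behaves
as a baseline covariate.  The remaining identification assumptions are
the standard potential-outcomes set (SUTVA, randomization, exclusion
restriction) plus four factor-model conditions enforced structurally by
`validate_spec`: conditional independence of endpoints given the factors,
a loading matrix Λ constant over time/strata/arms, rotation restrictions
on Λ (a confirmatory zero pattern, or λ_kq = 0 for q > k in exploratory
mode, plus one positive sign-anchor loading per factor), and the
location/scale normalization (no level-2 intercepts; level-2 disturbance
variance fixed at 1).

Within stratum m and assignment a, the two-level model

    y_ija = λ_m0 + Λ U_mija + b_mia + e_mija,
    U_qmija = x'_qija β_qm + z'_qij v_qmia + ε_qmija,

collapses to a multivariate normal for the stacked K(J+1) outcome vector
(outcome-major, time-minor, so the covariance is literally the Kronecker
composition):

    μ_mia = λ_m0 ⊗ 1 + (Λ ⊗ I)(X_a β_m),
    Σ_mi  = (Λ ⊗ I)(Z Σ_v Z' + D_ε)(Λ ⊗ I)' + diag(ξ_m) ⊗ 11' + diag(τ²_m) ⊗ I.

The observed-data likelihood multiplies Gaussian kernels over treated
compliers and treated never-takers (weighted by the logistic compliance
probability p_ci and 1 − p_ci) with a two-component mixture over the
control arm, combined in log space.  Missing follow-up entries are
handled by restricting each subject's MVN to observed coordinates —
valid likelihood inference under MAR, with no model for the missingness
mechanism.  Because the two potential-outcome vectors are never jointly
observed, no cross-world correlation parameter exists in the likelihood.

Structural identifiability choices worth noting:

* **Never-taker treatment terms are dropped.**  D(a) ≡ 0 for never-takers
  in both arms, so any fixed-effect term involving D has an identically
  zero column in their design; keeping those coefficients would make the
  observed information singular.  The never-taker parameter block
  therefore contains only assignment-free terms.
* **Σ_v is shared across strata** (per-factor blocks, zero cross-factor
  blocks), while ψ_m = (ξ_m, τ²_m) and λ_m0 are stratum-specific.
* **Sign anchors are log-parameterized**, which enforces positivity
  exactly.  Starting values orient each principal component so its
  anchor entry is positive; without that orientation the anchor can be
  trapped at zero when the data prefer the mirrored factor.

## Estimation and inference

The packed parameter space is unconstrained: log variances, per-factor
log-Cholesky factors for Σ_v, log anchors, identity elsewhere.  L-BFGS-B
maximizes the log-likelihood with an *analytic* gradient, obtained by
accumulating MVN scores in (μ, Σ) per bucket of subjects sharing a
(pattern-group, missingness-pattern) and chaining through the moment
composition.  The gradient is verified against central finite differences
on both scales in the test suite (agreement ~1e-6 relative); it makes a
full two-factor fit at N = 300 take under a second, which is what keeps
500-replicate simulation studies desk-scale.  Restarts jitter the start
multiplicatively (sd 0.2) on log-variance coordinates and additively
(sd 0.25|x| + 0.05) elsewhere; defaults are rel_tol 1e-9, grad_tol 1e-5,
max_iter 2000, 3 restarts (study harnesses use 1 restart with
moment-based starts).

The covariance of the estimates is the inverse observed information: a
central finite-difference Hessian *of the analytic gradient* in the
original parameterization (step 1e-4 relative), which is the scale Wald
tables report.  If a variance sits on the transform floor (log-scale
below −12, flagged, never silent), the Hessian is taken on the packed
scale and mapped back by the delta method, since differencing across a
boundary is invalid.  A non-PD information matrix is projected to the
nearest PSD matrix and flagged; a singular one raises, naming the
null-space parameters.  AIC = −2ℓ + 2p and BIC = −2ℓ + p log N use the
number of *subjects* as N — subjects are the independent units of the
likelihood.

Estimands are linear contrasts of β: PCE_qmj = (x_qij(1) − x_qij(0))'β_qm,
with delta-method (here exact) standard errors from the fit covariance,
95% CIs at the exact normal quantile, and two-sided Wald p-values.  The
global test of no treatment effect on any factor is a likelihood-ratio
test against the nested model with every complier D:t slope pinned to
zero (df = Q); tiny negative deviances from optimizer tolerance are
clipped, materially negative ones trigger one escalated refit of the
full model and otherwise raise.  Per-factor Wald p-values are reported
unadjusted after the single global test; the univariate comparator, by
contrast, applies Bonferroni α/K across its K endpoint tests — the
two-tier testing strategy the model is designed around.

## Univariate comparator and domain scores

The comparator fits each endpoint separately with the K = 1
specialization of the same family: loading fixed at 1, the unit-variance
level-2 disturbance removed and absorbed into a free, stratum-specific
residual variance (the disturbance normalization is only needed for
multi-outcome identification), terms t, t², D·t, a random slope in t and
a random intercept.  Its treatment-effect test is the LRT of the D·t
coefficient.  Domain-score analysis averages pre-specified endpoint
groups per subject-visit over *available* members (missing-aware, the
same MAR stance as the likelihood) and runs the K = 1 model on each
score with the full quadratic treatment interaction.

## Synthetic-data generator

The simulator draws baseline covariates, logistic compliance strata,
Bernoulli (or fixed-count) allocation, and then *both* potential-outcome
arrays from the full hierarchy with independent noise in the two
assignment worlds (cross-world correlation never enters the likelihood).
The observed dataset is the realized arm's array with whole-visit MAR
deletion applied to follow-up visits at per-(arm, visit) rates, optionally
shifted on the logit scale by the standardized observed baseline mean.
All generating values live in YAML scenario files, never in code.

The shipped default scenario is the study condition used throughout the
tests and the acceptance script: six endpoints at visits t = 0, 1, 2
(3-month units), two factors with the confirmatory split (endpoints
1, 2, 3, 5 on factor 1; 4, 6 on factor 2), unit free loadings,
ξ = τ² = 1, per-factor random slope variance 0.5, level-2 terms t, t²,
D·t, intercept-only compliance at p_c = 0.3, allocation 0.5, complier
treatment slope 1.5 per factor (D-main effect and D·t² set to zero:
baseline balance within strata of a randomized trial, and a
linear-in-time treatment contrast for clean power comparisons), and
whole-visit missingness at the motivating trial's observed rates
(treated 24.4%/22.2%, control 6.1%/14.3%).  A variant with a binary
compliance predictor and a synthetic trial-like scenario (94 subjects,
0-100-scaled outcomes, quadratic treatment interactions, a four-covariate
compliance model) are also shipped; the latter is *synthetic* — the real
trial's data are not public, and only its design is mirrored.

What the generator does not emulate: skewed or bounded questionnaire
scores (everything is Gaussian), MNAR dropout, item-level missingness
within a visit, cluster or site effects, and time-varying loadings.
Passing tests therefore certify the estimator under the model's own
assumptions, not robustness to their violation.

## Study harness and problem sizes

Power/Type-I grids simulate per cell, run the global MCACE LRT (full +
warm-started null fit) and the Bonferroni univariate procedure, and
report rejection proportions with binomial MC standard errors.
Replicate r always uses seed base + r, so splitting a cell across
invocations and pooling is bit-identical to one run; non-converged
replicates are excluded from the denominator and counted.  The package
defaults to 500 replicates per cell; the shipped test suite and
acceptance script use reduced designs chosen to keep a full run on one
core comfortable — 200 replicates at N = 300 for calibration, 60
replicates for the N = 100 / p_c = 0.3 power and Type-I cells, 50
replicates at N = 200 (30 in the script) for factor-count selection —
with tolerances widened to the corresponding binomial error.

## Known limitations

* With p_c ≈ 0.3 and N ≤ 300, only ~0.15·N treated compliers inform all
  complier-specific parameters.  Estimates are nearly unbiased — the
  free loadings carry the usual O(1/N) maximum-likelihood shrinkage of
  about 1% of their value at N = 300, detectable only with hundreds of
  replicates — but the inverse observed information underestimates the
  sampling spread of complier-stratum parameters by roughly 10–25%
  there, and 95% Wald intervals can cover at ~0.87–0.91 for those
  parameters.  This is a
  finite-sample weak-instrument effect, not an implementation artifact:
  the identical pipeline at N = 4000 gives SE-to-SD ratios of ~1.00 and
  coverage ~0.95, and the gradient/Hessian are verified against finite
  differences.  Calibration studies at small N should read the reported
  coverage tables with this in mind.
* For the same reason, the global likelihood-ratio test over-rejects in
  the hardest cell of the default grid: at N = 100, p_c = 0.3 with the
  default missingness its Type-I error is roughly 0.15 rather than 0.05,
  while at N = 500, p_c = 0.7 without missingness it is calibrated
  (0.067 ± 0.02 over 120 replicates, statistic median matching χ²₂).
  The power *comparison* against the Bonferroni univariate procedure is
  unaffected in direction — both tests inflate in that cell and the
  latent-factor test remains the more powerful — but absolute rejection
  rates in weakly identified cells should be interpreted against a
  simulated null, not the nominal χ² reference.
* Continuous, conditionally Gaussian outcomes only; no categorical or
  mixed-type endpoints, no MNAR sensitivity models, no always-taker or
  defier strata, no factor-rotation algorithms beyond the stated
  constraints, and no Bayesian estimation.
* The control-arm mixture components are identified through the treated
  arm; when the strata truly share all outcome parameters, posterior
  compliance probabilities for controls revert to the prior p_ci.
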