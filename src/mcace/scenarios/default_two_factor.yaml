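# Default two-factor simulation scenario.
#
# Six endpoints at visits t = 0, 1, 2 (3-month units) driven by two latent
# factors: factor 1 loads on outcomes 1, 2, 3, 5 and factor 2 on outcomes
# 4 and 6 (the confirmatory split used throughout).  Free loadings are 1,
# outcome random-intercept and residual variances are 1, each factor has a
# random linear slope with variance 0.5, and compliance is intercept-only
# with p_c = 0.3.  The complier treatment slope (D:t) is 1.5 on both
# factors; the treatment-by-quadratic term and the D main effect are zero
# (baseline balance within strata of a randomized trial).  Follow-up
# missingness uses the motivating trial's observed visit-level rates.
name: default_two_factor
K: 6
Q: 2
times: [0.0, 1.0, 2.0]
n_subjects: 100
allocation: 0.5
factor_names: [self_efficacy, provider_interaction]
loading:
  mode: confirmatory
  mask:
    - [1, 0]
    - [1, 0]
    - [1, 0]
    - [0, 1]
    - [1, 0]
    - [0, 1]
level2:
  fixed_terms:
    - [t, t2, "D:t"]
    - [t, t2, "D:t"]
  random_terms:
    - [t]
    - [t]
compliance_covariates: []
params:
  lambda0:
    c: [0, 0, 0, 0, 0, 0]
    n: [0, 0, 0, 0, 0, 0]
  loadings: [1, 1, 1, 1, 1, 1]
  xi:
    c: [1, 1, 1, 1, 1, 1]
    n: [1, 1, 1, 1, 1, 1]
  tau2:
    c: [1, 1, 1, 1, 1, 1]
    n: [1, 1, 1, 1, 1, 1]
  beta:
    c:
      self_efficacy: {t: 0.5, t2: -0.1, "D:t": 1.5}
      provider_interaction: {t: 0.5, t2: -0.1, "D:t": 1.5}
    n:
      self_efficacy: {t: 0.5, t2: -0.1}
      provider_interaction: {t: 0.5, t2: -0.1}
  sigma_v:
    - [[0.5]]
    - [[0.5]]
  eta: [-0.8472978603872034]   # logit(0.3)
missingness:
  control: [0.061, 0.143]
  treated: [0.244, 0.222]
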