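# Parameter-recovery scenario with a binary compliance predictor.
#
# Same outcome model as default_two_factor, but complier membership
# depends on a Bernoulli(0.5) baseline covariate through the logistic
# model, giving compliance rates of about 0.23 (w = 0) and 0.40 (w = 1).
name: recovery_binary_covariate
K: 6
Q: 2
times: [0.0, 1.0, 2.0]
n_subjects: 300
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
compliance_covariates: [w1]
compliance_covariate_probs: [0.5]
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
  eta: [-1.2, 0.8]
missingness:
  control: [0.061, 0.143]
  treated: [0.244, 0.222]
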