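# Synthetic trial emulating the motivating arthritis self-management RCT.
#
# SYNTHETIC: the real trial data are not public; this scenario only mirrors
# its design — 94 subjects, six 0-100-rescaled endpoints at 0/3/6 months,
# the confirmatory two-factor loading split (self-efficacy: outcomes
# 1, 2, 3, 5; provider interaction: 4, 6), quadratic latent trajectories
# with treatment-by-time interactions, random linear+quadratic slopes on
# the first factor only, a four-covariate logistic compliance model, and
# the observed visit-level missingness rates.  Treatment-slope values are
# chosen to give factor-scale effects of realistic magnitude; all other
# magnitudes are plausible for questionnaire scores, not estimates from
# the real data.
name: ahj_like_synthetic
K: 6
Q: 2
times: [0.0, 1.0, 2.0]
n_subjects: 94
allocation: 0.48
outcome_names:
  [effective_consumer, manage_symptoms, manage_disease, communicate_physician,
   partners_in_health, satisfaction_care]
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
    - [t, t2, "D:t", "D:t2"]
    - [t, t2, "D:t", "D:t2"]
  random_terms:
    - [t, t2]
    - []
compliance_covariates: [early_disease, high_activity, male, older_age]
compliance_covariate_probs: [0.2, 0.5, 0.2, 0.5]
params:
  lambda0:
    c: [62, 60, 61, 63, 60, 64]
    n: [58, 57, 58, 60, 57, 61]
  loadings: [6, 5, 6, 7, 5, 6]
  xi:
    c: [40, 45, 40, 35, 45, 35]
    n: [40, 45, 40, 35, 45, 35]
  tau2:
    c: [30, 35, 30, 25, 35, 25]
    n: [30, 35, 30, 25, 35, 25]
  beta:
    c:
      self_efficacy: {t: 0.4, t2: -0.1, "D:t": 2.8, "D:t2": -1.0}
      provider_interaction: {t: 0.3, t2: -0.1, "D:t": 1.9, "D:t2": -0.5}
    n:
      self_efficacy: {t: 0.4, t2: -0.1}
      provider_interaction: {t: 0.3, t2: -0.1}
  sigma_v:
    - [[0.3, 0.0], [0.0, 0.1]]
    - []
  eta: [-0.825, -2.389, 1.420, -0.888, -0.938]
missingness:
  control: [0.061, 0.143]
  treated: [0.244, 0.222]
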