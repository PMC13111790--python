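# mcace — latent-factor multivariate CACE analysis

Randomized trials of multifaceted interventions (behavioural programs,
self-management tools, education packages) usually measure a handful of
underlying constructs — self-efficacy, quality of interaction with care
providers — through many correlated questionnaire endpoints collected over
repeated visits, and usually suffer treatment noncompliance: a sizeable
fraction of the intervention arm never really takes up the intervention.
Analyzing each endpoint separately then loses power twice, to Bonferroni
correction across endpoints and to the weak-instrument imprecision that
comes with low compliance.

`mcace` implements a latent-factor multivariate complier-average-causal-effect
(MCACE) model for this setting, for biostatisticians analyzing such trials
and for methodologists running simulation studies.  Within each compliance
principal stratum *m* ∈ {complier *c*, never-taker *n*} (control subjects
have no treatment access, ruling out always-takers and defiers), the K
endpoints at visit *j* load on Q ≪ K latent factors:

    y_ija | C_i = m  =  λ_m0 + Λ U_mija + b_mia + e_mija          (level 1)
    U_qmija          =  x'_qija β_qm + z'_qij v_qmia + ε_qmija     (level 2)

with Λ shared across time, strata and arms, outcome random intercepts
b\_mik ~ N(0, ξ\_mk), residuals e\_mijk ~ N(0, τ²\_mk), factor random effects
v\_qmi ~ N(0, Σ\_qv), and the scale normalization Var(ε) = 1 (no level-2
intercepts).  Compliance follows a logistic model
p\_ci = expit(w'\_i η).  Integrating the latent quantities gives a closed-form
multivariate normal for the stacked K·(J+1) outcome vector per (stratum,
arm), so the observed-data likelihood is the product L11 · L10 · L00 over
treated compliers, treated never-takers and the control-arm mixture, with
missing-at-random follow-up entries marginalized by coordinate restriction.
The package maximizes this likelihood by quasi-Newton search with analytic
gradients, reports inverse-observed-information covariances, and computes
the causal estimands

    PCE_qmj = (x_qij(1) − x_qij(0))' β_qm ,   CACE_qj = PCE_qcj ,

which are zero for never-takers by the exclusion restriction.  A single
global likelihood-ratio test of "no treatment effect on any factor"
replaces K Bonferroni-corrected per-endpoint tests; a per-endpoint
univariate comparator and a replicated power/Type-I harness quantify the
gain.

## Worked example

Simulate a 300-subject trial from the shipped two-factor scenario (six
endpoints at months 0/3/6, 30% compliance, complier treatment slope 1.5
per factor — so the true month-6 CACE is 2 × 1.5 = 3 in factor-score
units), fit the confirmatory model, and report the factor CACEs:

```python
import mcace

cfg = mcace.default_scenario().resize(300)
data, truth = mcace.simulate_trial(cfg, seed=1)
fit = mcace.fit_mle(data, cfg.spec, mcace.FitOptions(n_restarts=2, seed=1))
for q in range(cfg.spec.Q):
    rep = mcace.cace(fit, cfg.spec, q, j=2, times=cfg.times)
    print(f"{cfg.spec.factor_names[q]:<22} CACE {rep.estimate:6.3f}"
          f"  SE {rep.se:5.3f}  p {rep.p:.4f}")
```

which prints

```
self_efficacy          CACE  2.473  SE 0.560  p 0.0000
provider_interaction   CACE  4.281  SE 0.588  p 0.0000
```

Each estimate is the tool's month-6 effect on that construct averaged over
compliers, in latent-factor units; both are about two standard errors from
the generating value 3, the sampling variability one expects with ~45
observed compliers.  The same pipeline is available from the shell:

```bash
mcace simulate --n-subjects 300 --seed 1 --out y.csv --covariates-out w.csv
mcace fit --data y.csv --config src/mcace/scenarios/default_two_factor.yaml \
          --out fit.yaml
mcace power --replicates 500 --effects 0,1,2,3 --out power.csv
```

`mcace fit --method univariate` runs the per-endpoint comparator and
`--method domain-score` the pre-specified-average analysis.

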