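"""Observed-data likelihood: densities, MAR marginalization, mixture terms."""

import numpy as np
import pytest
import scipy.integrate
import scipy.stats

import mcace
from mcace import (
    LikelihoodWorkspace,
    TrialData,
    compliance_probability,
    moments_for,
    mvn_logdensity_observed,
    posterior_compliance,
    total_loglik,
)


class TestMvnDensity:
    def test_standard_normal_mode(self, toy_spec, toy_params):
        """Univariate case at the mode with unit variance: log(1/sqrt(2 pi))."""
        mom = moments_for(toy_params, toy_spec, np.array([0.0, 1.0]), "c", 0)
        mom.mu = np.array([0.0, 0, 0, 0])
        mom.sigma = np.eye(4)
        ll = mvn_logdensity_observed(np.array([0.0]), mom, np.array([0]))
        assert ll == pytest.approx(np.log(1.0 / np.sqrt(2 * np.pi)), abs=1e-12)

    def test_full_observation_equals_unrestricted(self, default_cfg):
        spec, pv = default_cfg.spec, default_cfg.true_params
        mom = moments_for(pv, spec, default_cfg.times, "c", 1)
        rng = np.random.default_rng(0)
        y = mom.mu + rng.normal(0, 1, len(mom.mu))
        full = mvn_logdensity_observed(y, mom, np.arange(len(y)))
        ref = scipy.stats.multivariate_normal(mom.mu, mom.sigma).logpdf(y)
        assert full == pytest.approx(ref, abs=1e-8)

    def test_marginalization_matches_numeric_integration(self, default_cfg):
        """Restricting to observed coordinates equals integrating the full
        density over the missing ones (2-dim missing block, quadrature)."""
        spec, pv = default_cfg.spec, default_cfg.true_params
        mom = moments_for(pv, spec, default_cfg.times, "n", 0)
        rng = np.random.default_rng(1)
        y = mom.mu + np.linalg.cholesky(mom.sigma) @ rng.normal(0, 1, len(mom.mu))
        missing = np.array([4, 11])
        obs = np.setdiff1d(np.arange(len(y)), missing)
        target = mvn_logdensity_observed(y[obs], mom, obs)
        dens = scipy.stats.multivariate_normal(mom.mu, mom.sigma)
        sd = np.sqrt(np.diag(mom.sigma)[missing])

        def integrand(u, v):
            z = y.copy()
            z[missing] = [u, v]
            return dens.pdf(z)

        val, _ = scipy.integrate.dblquad(
            integrand,
            mom.mu[missing[1]] - 8 * sd[1],
            mom.mu[missing[1]] + 8 * sd[1],
            lambda v: mom.mu[missing[0]] - 8 * sd[0],
            lambda v: mom.mu[missing[0]] + 8 * sd[0],
            epsabs=1e-12,
            epsrel=1e-10,
        )
        assert np.log(val) == pytest.approx(target, abs=1e-6)


class TestComplianceModel:
    def test_symmetric_logit(self):
        assert compliance_probability(np.ones((1, 1)), np.zeros(1))[0] == 0.5

    def test_intercept_only_rate(self):
        eta = np.array([np.log(0.3 / 0.7)])
        assert compliance_probability(np.ones((3, 1)), eta)[0] == pytest.approx(0.3)

    def test_extreme_logit_is_finite_and_bounded(self):
        p = compliance_probability(np.array([[1.0]]), np.array([40.0]))[0]
        assert 0 < p <= 1 and np.isfinite(np.log(p))
        from mcace.likelihood import _log_sigmoid

        lp, l1p = _log_sigmoid(np.array([40.0, -40.0, 1e4]))
        assert np.all(np.isfinite(lp)) and np.all(np.isfinite(l1p))


def _toy_data(toy_spec, toy_params, n=14, seed=5, p_high=False):
    cfg = mcace.SimConfig(
        spec=toy_spec,
        true_params=toy_params,
        n_subjects=n,
        times=np.array([0.0, 1.0]),
        seed=seed,
    )
    if p_high:
        pv = toy_params.copy()
        pv.eta = np.array([30.0])
        cfg = mcace.SimConfig(
            spec=toy_spec, true_params=pv, n_subjects=n, times=np.array([0.0, 1.0])
        )
    return mcace.simulate_trial(cfg, seed=seed)[0]


class TestTotalLoglik:
    def test_degenerate_mixture_collapses_to_complier_component(
        self, toy_spec, toy_params
    ):
        """p_ci -> 1 reduces every control term to the complier density."""
        data = _toy_data(toy_spec, toy_params, p_high=True)
        pv = toy_params.copy()
        pv.eta = np.array([500.0])
        ll = total_loglik(pv, data, toy_spec)
        # single-stratum oracle: complier density for everyone
        manual = 0.0
        stacked = data.stacked()
        for i in range(data.n_subjects):
            a = int(data.arm[i])
            mom = moments_for(pv, toy_spec, data.times, "c", a)
            obs = np.flatnonzero(np.isfinite(stacked[i]))
            manual += mvn_logdensity_observed(stacked[i][obs], mom, obs)
        assert ll == pytest.approx(manual, abs=1e-8)

    def test_duplicating_subjects_doubles_loglik(self, toy_spec, toy_params):
        data = _toy_data(toy_spec, toy_params)
        doubled = TrialData(
            arm=np.tile(data.arm, 2),
            receipt=np.tile(data.receipt, 2),
            outcomes=np.tile(data.outcomes, (2, 1, 1)),
            times=data.times,
            covariates=np.tile(data.covariates, (2, 1)),
        )
        assert total_loglik(toy_params, doubled, toy_spec) == pytest.approx(
            2 * total_loglik(toy_params, data, toy_spec), rel=1e-12
        )

    def test_subject_order_invariance(self, toy_spec, toy_params):
        data = _toy_data(toy_spec, toy_params)
        perm = np.random.default_rng(3).permutation(data.n_subjects)
        shuffled = TrialData(
            arm=data.arm[perm],
            receipt=data.receipt[perm],
            outcomes=data.outcomes[perm],
            times=data.times,
            covariates=data.covariates[perm],
        )
        assert total_loglik(toy_params, shuffled, toy_spec) == pytest.approx(
            total_loglik(toy_params, data, toy_spec), rel=1e-12
        )

    def test_outcome_permutation_invariance(self, default_cfg, small_data):
        """Permuting endpoint columns together with the matching rows of
        Lambda, lambda0, xi and tau2 leaves the likelihood unchanged."""
        data, _ = small_data
        spec, pv = default_cfg.spec, default_cfg.true_params
        base = total_loglik(pv, data, spec)
        perm = np.array([2, 0, 1, 5, 4, 3])
        data_p = TrialData(
            arm=data.arm,
            receipt=data.receipt,
            outcomes=data.outcomes[:, :, perm],
            times=data.times,
            covariates=data.covariates,
        )
        from mcace import LoadingSpec, ModelSpec

        lam = pv.lambda_matrix(spec)[perm]
        mask_p = spec.loading.mask[perm]
        anchors = []
        for q in range(spec.Q):
            anchors.append(int(np.flatnonzero(mask_p[:, q])[0]))
        spec_p = ModelSpec(
            K=spec.K,
            Q=spec.Q,
            n_visits=spec.n_visits,
            loading=LoadingSpec(mask=mask_p, sign_anchor=tuple(anchors)),
            level2=spec.level2,
            compliance_covariates=spec.compliance_covariates,
        )
        pv_p = pv.copy()
        pv_p.loadings = lam[np.nonzero(mask_p)]
        pv_p.lambda0 = {m: v[perm] for m, v in pv.lambda0.items()}
        pv_p.xi = {m: v[perm] for m, v in pv.xi.items()}
        pv_p.tau2 = {m: v[perm] for m, v in pv.tau2.items()}
        assert total_loglik(pv_p, data_p, spec_p) == pytest.approx(base, rel=1e-12)

    def test_mixture_lower_bound(self, toy_spec, toy_params):
        """log L00_i >= log(max component) + log(min(p, 1-p))."""
        data = _toy_data(toy_spec, toy_params, n=30, seed=8)
        ws = LikelihoodWorkspace(data, toy_spec)
        pv = toy_params
        stacked = data.stacked()
        p = compliance_probability(data.covariates, pv.eta)
        for i in np.flatnonzero(data.arm == 0):
            obs = np.flatnonzero(np.isfinite(stacked[i]))
            comps = []
            for m in ("c", "n"):
                mom = moments_for(pv, toy_spec, data.times, m, 0)
                comps.append(mvn_logdensity_observed(stacked[i][obs], mom, obs))
            w = np.log(p[i]) if comps[0] >= comps[1] else np.log(1 - p[i])
            single = TrialData(
                arm=data.arm[[i]],
                receipt=data.receipt[[i]],
                outcomes=data.outcomes[[i]],
                times=data.times,
                covariates=data.covariates[[i]],
            )
            ll_i = total_loglik(pv, single, toy_spec)
            assert ll_i >= max(comps) + min(np.log(p[i]), np.log(1 - p[i])) - 1e-10
            assert ll_i <= max(comps) + 1e-10
        _ = ws


class TestPosteriorCompliance:
    def test_treated_arms_are_deterministic(self, toy_spec, toy_params):
        data = _toy_data(toy_spec, toy_params, n=40, seed=2)
        r = posterior_compliance(toy_params, data, toy_spec)
        assert np.all(r[(data.arm == 1) & (data.receipt == 1)] == 1.0)
        assert np.all(r[(data.arm == 1) & (data.receipt == 0)] == 0.0)

    def test_identical_components_return_prior(self, toy_spec, toy_params):
        """When the strata share all outcome parameters, the posterior is p_ci."""
        pv = toy_params.copy()
        for field in ("lambda0", "xi", "tau2"):
            d = getattr(pv, field)
            d["n"] = d["c"].copy()
        pv.beta["n"] = pv.beta["c"][:1].copy()  # shared t coefficient
        data = _toy_data(toy_spec, pv, n=30, seed=6)
        controls = data.arm == 0
        r = posterior_compliance(pv, data, toy_spec)
        p = compliance_probability(data.covariates, pv.eta)
        np.testing.assert_allclose(r[controls], p[controls], atol=1e-10)

    def test_hand_computed_bayes_ratio(self, toy_spec, toy_params):
        data = _toy_data(toy_spec, toy_params, n=20, seed=7)
        r = posterior_compliance(toy_params, data, toy_spec)
        stacked = data.stacked()
        p = compliance_probability(data.covariates, toy_params.eta)
        i = int(np.flatnonzero(data.arm == 0)[0])
        obs = np.flatnonzero(np.isfinite(stacked[i]))
        dens = {}
        for m in ("c", "n"):
            mom = moments_for(toy_params, toy_spec, data.times, m, 0)
            dens[m] = np.exp(mvn_logdensity_observed(stacked[i][obs], mom, obs))
        expected = p[i] * dens["c"] / (p[i] * dens["c"] + (1 - p[i]) * dens["n"])
        assert r[i] == pytest.approx(expected, rel=1e-10)
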