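"""Closed-form marginal moments against independent scalar-loop oracles."""

import numpy as np
import pytest

import mcace
from mcace import compute_mu, compute_sigma, moments_for
from mcace.marginal_moments import chol_psd
from mcace.model_spec import active_fixed_terms, build_designs, receipt_under, stratum_design
from mcace.model_spec import _eval_term


def scalar_mu_oracle(params, spec, times, m, a):
    """Element-wise evaluation mu_jk = lambda0_k + sum_q lambda_kq x_qij' beta_q."""
    lam = params.lambda_matrix(spec)
    j1 = spec.n_visits
    mu = np.zeros(spec.K * j1)
    beta_off = 0
    factor_means = np.zeros((spec.Q, j1))
    for q in range(spec.Q):
        terms = active_fixed_terms(spec, q, m)
        b = params.beta[m][beta_off : beta_off + len(terms)]
        for j in range(j1):
            x = np.array(
                [_eval_term(t, np.array([times[j]]), receipt_under(m, a))[0] for t in terms]
            )
            factor_means[q, j] = x @ b
        beta_off += len(terms)
    for k in range(spec.K):
        for j in range(j1):
            mu[k * j1 + j] = params.lambda0[m][k] + sum(
                lam[k, q] * factor_means[q, j] for q in range(spec.Q)
            )
    return mu


def scalar_sigma_oracle(params, spec, times, m):
    """Cov(Y_jk, Y_lh) assembled term by term from the model's independence
    structure: factor covariances through the loadings, xi on same-outcome
    pairs, tau2 on same-outcome same-visit pairs."""
    lam = params.lambda_matrix(spec)
    j1 = spec.n_visits
    eps = params.eps_variances(spec)
    # Cov(U_qj, U_rl) = 1(q==r) [ z_qj' Sigma_qv z_ql + 1(j==l) eps_q ]
    _, Z = build_designs(spec, times, 0, 0)
    cov_u = np.zeros((spec.Q, j1, spec.Q, j1))
    col = 0
    for q in range(spec.Q):
        r = len(spec.level2.random_terms[q])
        zq = Z[q * j1 : (q + 1) * j1, col : col + r]
        cov_u[q, :, q, :] = zq @ params.sigma_v[q] @ zq.T + eps[q] * np.eye(j1)
        col += r
    n = spec.K * j1
    sig = np.zeros((n, n))
    for k in range(spec.K):
        for j in range(j1):
            for h in range(spec.K):
                for l in range(j1):
                    v = sum(
                        lam[k, q] * lam[h, r] * cov_u[q, j, r, l]
                        for q in range(spec.Q)
                        for r in range(spec.Q)
                    )
                    if k == h:
                        v += params.xi[m][k]
                        if j == l:
                            v += params.tau2[m][k]
                    sig[k * j1 + j, h * j1 + l] = v
    return sig


class TestClosedFormMoments:
    @pytest.mark.parametrize("m,a", [("c", 1), ("c", 0), ("n", 1)])
    def test_mu_matches_scalar_loop(self, default_cfg, m, a):
        spec, pv = default_cfg.spec, default_cfg.true_params
        times = default_cfg.times
        X = stratum_design(spec, times, m, a)
        np.testing.assert_allclose(
            compute_mu(pv, X, spec, m), scalar_mu_oracle(pv, spec, times, m, a), atol=1e-12
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_sigma_matches_scalar_loop_on_random_instances(self, default_cfg, seed):
        """Entrywise variance conservation, tolerance 1e-10."""
        from mcace.parameters import ParamLayout

        spec = default_cfg.spec
        layout = ParamLayout(spec)
        rng = np.random.default_rng(seed)
        pv = layout.unpack(layout.pack(default_cfg.true_params) + rng.normal(0, 0.4, layout.n_free))
        _, Z = build_designs(spec, default_cfg.times, 0, 0)
        for m in ("c", "n"):
            np.testing.assert_allclose(
                compute_sigma(pv, Z, spec, m),
                scalar_sigma_oracle(pv, spec, default_cfg.times, m),
                atol=1e-10,
            )

    def test_zero_loading_mean_is_repeated_intercept(self, default_cfg):
        pv = default_cfg.true_params.copy()
        pv.loadings = np.zeros_like(pv.loadings)
        mom = moments_for(pv, default_cfg.spec, default_cfg.times, "c", 1)
        np.testing.assert_allclose(
            mom.mu, np.kron(pv.lambda0["c"], np.ones(default_cfg.spec.n_visits))
        )

    def test_zero_beta_mean_is_repeated_intercept(self, default_cfg):
        pv = default_cfg.true_params.copy()
        pv.beta = {m: np.zeros_like(v) for m, v in pv.beta.items()}
        mom = moments_for(pv, default_cfg.spec, default_cfg.times, "n", 0)
        np.testing.assert_allclose(
            mom.mu, np.kron(pv.lambda0["n"], np.ones(default_cfg.spec.n_visits))
        )

    def test_pure_measurement_noise_limit(self, toy_spec, toy_params):
        """With Lambda = 0, xi = 0 and Sigma_v = 0, Sigma = diag(tau2) (x) I."""
        pv = toy_params.copy()
        pv.loadings = np.zeros_like(pv.loadings)
        pv.xi = {m: np.zeros_like(v) for m, v in pv.xi.items()}
        pv.sigma_v = [np.zeros((1, 1))]
        times = np.array([0.0, 1.0])
        _, Z = build_designs(toy_spec, times, 0, 0)
        sig = compute_sigma(pv, Z, toy_spec, "c")
        np.testing.assert_allclose(sig, np.kron(np.diag(pv.tau2["c"]), np.eye(2)), atol=1e-12)

    def test_same_visit_cross_outcome_covariance_excludes_noise(self, default_cfg):
        """Cross-outcome covariance carries no xi or tau2 contribution."""
        spec, pv = default_cfg.spec, default_cfg.true_params
        j1 = spec.n_visits
        mom = moments_for(pv, spec, default_cfg.times, "c", 0)
        oracle = scalar_sigma_oracle(pv, spec, default_cfg.times, "c")
        # zeroing xi and tau2 must leave every (k != h) entry unchanged
        pv0 = pv.copy()
        pv0.xi = {m: np.zeros_like(v) for m, v in pv.xi.items()}
        pv0.tau2 = {m: np.full_like(v, 1e-8) for m, v in pv.tau2.items()}
        mom0 = moments_for(pv0, spec, default_cfg.times, "c", 0)
        for k in range(spec.K):
            for h in range(spec.K):
                if k == h:
                    continue
                blk = np.s_[k * j1 : (k + 1) * j1, h * j1 : (h + 1) * j1]
                np.testing.assert_allclose(mom.sigma[blk], mom0.sigma[blk], atol=1e-7)
        np.testing.assert_allclose(mom.sigma, oracle, atol=1e-10)

    def test_cholesky_succeeds_down_to_tiny_residual_variance(self, default_cfg):
        pv = default_cfg.true_params.copy()
        pv.tau2 = {m: np.full_like(v, 1e-8) for m, v in pv.tau2.items()}
        pv.xi = {m: np.zeros_like(v) for m, v in pv.xi.items()}
        mom = moments_for(pv, default_cfg.spec, default_cfg.times, "n", 0)
        L = chol_psd(mom.sigma)
        assert np.all(np.isfinite(L))


class TestSimulationClosure:
    def test_simulated_moments_match_closed_form(self, default_cfg):
        """Empirical moments of generated potential outcomes reproduce the
        analytic collapse (reduced-n version of the full closure check)."""
        n = 40000
        cfg = default_cfg.resize(n)
        from dataclasses import replace

        cfg = replace(cfg, missingness=None)
        data, truth = mcace.simulate_trial(cfg, seed=9)
        spec = cfg.spec
        j1 = spec.n_visits
        for m in ("c", "n"):
            for a in (0, 1):
                sel = truth.stratum == m
                ys = truth.y_potential[a][sel].transpose(0, 2, 1).reshape(sel.sum(), -1)
                mom = moments_for(cfg.true_params, spec, cfg.times, m, a)
                n_m = sel.sum()
                sd = np.sqrt(np.diag(mom.sigma))
                np.testing.assert_allclose(
                    ys.mean(axis=0), mom.mu, atol=5 * sd.max() / np.sqrt(n_m)
                )
                emp = np.cov(ys, rowvar=False)
                scale = np.sqrt(np.outer(np.diag(mom.sigma), np.diag(mom.sigma)))
                assert np.max(np.abs(emp - mom.sigma) / scale) < 6.0 / np.sqrt(n_m) * 3
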