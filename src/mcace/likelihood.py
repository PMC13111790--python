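"""Observed-data log-likelihood of the latent-factor MCACE model.

Three observed (arm, receipt) patterns partition the subjects: treated
compliers S(1,1), treated never-takers S(1,0), and controls S(0,0), whose
stratum is latent.  The likelihood is the product L11 * L10 * L00 of
Gaussian kernels under the closed-form marginal moments, with the control
arm a two-component complier/never-taker mixture weighted by the logistic
compliance probabilities, and missing outcome entries marginalized by
restricting each subject's MVN to its observed coordinates (valid under
MAR without modelling the missingness mechanism).  Because the two
potential-outcome vectors are never jointly observed, no cross-world
correlation enters the likelihood.

Subjects are bucketed by (pattern group, missingness pattern, level-2
covariate values) so each distinct observed sub-covariance is factorized
once per evaluation.  The same pass optionally accumulates the analytic
gradient: MVN score contributions in (mu, Sigma) are collected bucket-wise
per stratum/arm and chained through the moment composition to the
structural parameters.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
import scipy.special

from .marginal_moments import MarginalMoments, chol_psd, compute_mu, compute_sigma
from .model_spec import (
    COMPLIER,
    NEVER_TAKER,
    STRATA,
    ModelSpec,
    TrialData,
    build_designs,
    stratum_design,
)
from .parameters import ParamLayout, ParamVector

__all__ = [
    "LikelihoodWorkspace",
    "compliance_probability",
    "mvn_logdensity_observed",
    "total_loglik",
    "loglik_and_grad",
    "posterior_compliance",
]

_LOG2PI = float(np.log(2.0 * np.pi))

S11, S10, S00 = "S11", "S10", "S00"


def compliance_probability(W_i: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """P(C = complier | W) under the logistic compliance model.

    Overflow-safe for large |W'eta|.
    """
    lp = np.asarray(W_i, dtype=float) @ np.asarray(eta, dtype=float)
    return scipy.special.expit(lp)


def _log_sigmoid(lp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(log p, log(1-p)) for p = expit(lp), overflow-safe."""
    return -np.logaddexp(0.0, -lp), -np.logaddexp(0.0, lp)


def mvn_logdensity_observed(
    y_obs: np.ndarray, moments: MarginalMoments, observed_index: np.ndarray
) -> float:
    """Log-density of the observed sub-vector under (mu, Sigma).

    Computed through the Cholesky factor of the observed sub-covariance;
    no explicit inverse is formed.  The normalizing dimension is that of
    the observed sub-vector.
    """
    idx = np.asarray(observed_index, dtype=int)
    mu = moments.mu[idx]
    sig = moments.sigma[np.ix_(idx, idx)]
    L = chol_psd(sig)
    resid = np.asarray(y_obs, dtype=float) - mu
    alpha = scipy.linalg.solve_triangular(L, resid, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return -0.5 * (len(idx) * _LOG2PI + logdet + float(alpha @ alpha))


class _Bucket:
    __slots__ = ("group", "idx", "obs", "y", "cov_key")

    def __init__(self, group, idx, obs, y, cov_key):
        self.group = group
        self.idx = idx
        self.obs = obs
        self.y = y
        self.cov_key = cov_key


class LikelihoodWorkspace:
    """Pre-indexed view of a dataset for repeated likelihood evaluation.

    Holds the stacked outcomes, the (group, missingness-pattern) buckets,
    the per-stratum design matrices and the parameter layout.  Building it
    once per dataset makes each likelihood/gradient evaluation a handful
    of small Cholesky factorizations plus vectorized solves.
    """

    def __init__(self, data: TrialData, spec: ModelSpec):
        self.data = data
        self.spec = spec
        self.layout = ParamLayout(spec)
        n = data.n_subjects
        y = data.stacked()
        obs_mask = np.isfinite(y)
        group = np.where(data.arm == 0, S00, np.where(data.receipt == 1, S11, S10))
        self.group = group
        self.W = data.covariates

        uses_cov = spec.uses_level2_covariates()
        cov_cols: dict[str, np.ndarray] = {}
        if uses_cov:
            names = data.covariate_names or spec.compliance_covariates
            cov_cols = {
                name: data.covariates[:, 1 + i] for i, name in enumerate(names)
            }
        self._cov_names = sorted(cov_cols)

        keys: dict[tuple, list[int]] = {}
        for i in range(n):
            ck = (
                tuple(float(cov_cols[c][i]) for c in self._cov_names)
                if uses_cov
                else None
            )
            keys.setdefault((group[i], obs_mask[i].tobytes(), ck), []).append(i)
        self.buckets: list[_Bucket] = []
        for (g, _, ck), idx in keys.items():
            idx = np.asarray(idx, dtype=int)
            obs = np.flatnonzero(obs_mask[idx[0]])
            if obs.size == 0:
                raise ValueError(
                    f"subjects {data.subject_ids[idx].tolist()} have no observed outcomes"
                )
            self.buckets.append(_Bucket(g, idx, obs, y[idx][:, obs], ck))

        # stratum designs per distinct covariate key (one key when the
        # level-2 model has no baseline covariates — the common case)
        self.cov_keys = list(dict.fromkeys(b.cov_key for b in self.buckets))
        self.designs: dict = {}
        for ck in self.cov_keys:
            cov = dict(zip(self._cov_names, ck)) if ck is not None else None
            X = {
                (m, a): stratum_design(spec, data.times, m, a, cov)
                for m in STRATA
                for a in (0, 1)
            }
            _, Z = build_designs(spec, data.times, 0, 0, cov)
            self.designs[ck] = (X, Z)

    # ------------------------------------------------------------------
    def loglik(self, params: ParamVector) -> float:
        return self._evaluate(params, want_grad=False)[0]

    def loglik_and_grad(self, params: ParamVector) -> tuple[float, np.ndarray]:
        """(log-likelihood, gradient on the original parameter scale)."""
        total, grad, _ = self._evaluate(params, want_grad=True)
        return total, grad

    def posterior_complier(self, params: ParamVector) -> np.ndarray:
        """Per-subject posterior probability of complier membership."""
        return self._evaluate(params, want_grad=False, want_posterior=True)[2]

    # ------------------------------------------------------------------
    def _evaluate(self, params, want_grad=False, want_posterior=False):
        spec = self.spec
        n_stack = spec.stacked_dim
        j1, K, Q = spec.n_visits, spec.K, spec.Q
        lp = self.W @ params.eta
        log_p, log_1mp = _log_sigmoid(lp)

        total = 0.0
        track_r = want_grad or want_posterior
        r_post = np.where(self.group == S11, 1.0, 0.0) if track_r else None

        grad = np.zeros(self.layout.n_free) if want_grad else None
        lam = params.lambda_matrix(spec)
        A = np.kron(lam, np.eye(j1))
        ks_free, qs_free = np.nonzero(spec.loading.mask)
        s = self.layout.slices

        for ck in self.cov_keys:
            X, Z = self.designs[ck]
            mu = {
                (m, a): compute_mu(params, X[(m, a)], spec, m)
                for m in STRATA
                for a in (0, 1)
            }
            sigma = {m: compute_sigma(params, Z, spec, m) for m in STRATA}
            chol_cache: dict[tuple, tuple] = {}
            if want_grad:
                g_mu = {(m, a): np.zeros(n_stack) for m in STRATA for a in (0, 1)}
                G_sig = {m: np.zeros((n_stack, n_stack)) for m in STRATA}

            def component(bucket, m, a):
                key = (m, id(bucket))
                if key not in chol_cache:
                    sub = sigma[m][np.ix_(bucket.obs, bucket.obs)]
                    L = chol_psd(sub)
                    chol_cache[key] = (L, 2.0 * float(np.sum(np.log(np.diag(L)))))
                L, logdet = chol_cache[key]
                resid = bucket.y - mu[(m, a)][bucket.obs]
                alpha = scipy.linalg.solve_triangular(L, resid.T, lower=True)
                quad = np.einsum("ij,ij->j", alpha, alpha)
                ll = -0.5 * (len(bucket.obs) * _LOG2PI + logdet + quad)
                return ll, L, alpha

            def accumulate(bucket, m, a, L, alpha, w):
                sres = scipy.linalg.solve_triangular(L.T, alpha, lower=False)
                g_mu[(m, a)][bucket.obs] += sres @ w
                inv = scipy.linalg.cho_solve((L, True), np.eye(L.shape[0]))
                outer = sres @ (w[:, None] * sres.T)
                G_sig[m][np.ix_(bucket.obs, bucket.obs)] += 0.5 * (
                    outer - float(w.sum()) * inv
                )

            for bucket in self.buckets:
                if bucket.cov_key != ck:
                    continue
                idx = bucket.idx
                if bucket.group == S11:
                    ll, L, alpha = component(bucket, COMPLIER, 1)
                    total += float(np.sum(log_p[idx] + ll))
                    if want_grad:
                        accumulate(bucket, COMPLIER, 1, L, alpha, np.ones(len(idx)))
                elif bucket.group == S10:
                    ll, L, alpha = component(bucket, NEVER_TAKER, 1)
                    total += float(np.sum(log_1mp[idx] + ll))
                    if want_grad:
                        accumulate(bucket, NEVER_TAKER, 1, L, alpha, np.ones(len(idx)))
                else:  # control-arm mixture, combined in log space
                    ll_c, L_c, a_c = component(bucket, COMPLIER, 0)
                    ll_n, L_n, a_n = component(bucket, NEVER_TAKER, 0)
                    comp_c = log_p[idx] + ll_c
                    comp_n = log_1mp[idx] + ll_n
                    tot_i = np.logaddexp(comp_c, comp_n)
                    total += float(np.sum(tot_i))
                    if track_r:
                        r = np.exp(comp_c - tot_i)
                        r_post[idx] = r
                        if want_grad:
                            accumulate(bucket, COMPLIER, 0, L_c, a_c, r)
                            accumulate(bucket, NEVER_TAKER, 0, L_n, a_n, 1.0 - r)

            if not want_grad:
                continue

            # ---- chain rule for this covariate key's designs ----
            M = (
                Z @ scipy.linalg.block_diag(*params.sigma_v) @ Z.T
                if Z.shape[1]
                else np.zeros((Q * j1, Q * j1))
            )
            M = M + np.kron(np.diag(params.eps_variances(spec)), np.eye(j1))
            for m in STRATA:
                for a in (0, 1):
                    g = g_mu[(m, a)]
                    if not np.any(g):
                        continue
                    grad[s[f"lambda0_{m}"]] += g.reshape(K, j1).sum(axis=1)
                    grad[s[f"beta_{m}"]] += X[(m, a)].T @ (A.T @ g)
                    u = (X[(m, a)] @ params.beta[m]).reshape(Q, j1)
                    grad[s["loadings"]] += (g.reshape(K, j1) @ u.T)[ks_free, qs_free]
                G = G_sig[m]
                Gblk = G.reshape(K, j1, K, j1)
                grad[s[f"xi_{m}"]] += np.einsum("kakb->k", Gblk)
                grad[s[f"tau2_{m}"]] += np.einsum("kaka->k", Gblk)
                B = 2.0 * G @ A @ M
                grad[s["loadings"]] += np.einsum(
                    "kjqj->kq", B.reshape(K, j1, Q, j1)
                )[ks_free, qs_free]
                AtGA = A.T @ G @ A
                if spec.eps_mode == "free":
                    grad[s["eps_var"]] += np.einsum(
                        "qaqa->q", AtGA.reshape(Q, j1, Q, j1)
                    )
                if Z.shape[1]:
                    C = Z.T @ AtGA @ Z
                    off = s["sigma_v"].start
                    col = 0
                    for r_q in self.layout.rand_dims:
                        rows, cols = np.tril_indices(r_q)
                        blk = C[col : col + r_q, col : col + r_q]
                        vals = np.where(
                            rows == cols, blk[rows, cols], 2.0 * blk[rows, cols]
                        )
                        grad[off : off + len(rows)] += vals
                        off += len(rows)
                        col += r_q

        if want_grad:
            p = scipy.special.expit(lp)
            grad[s["eta"]] += self.W.T @ (r_post - p)
        return total, grad, r_post


def total_loglik(
    params: ParamVector,
    data: TrialData,
    spec: ModelSpec,
    workspace: LikelihoodWorkspace | None = None,
) -> float:
    """Observed-data log-likelihood log(L11 * L10 * L00)."""
    ws = workspace if workspace is not None else LikelihoodWorkspace(data, spec)
    return ws.loglik(params)


def loglik_and_grad(
    params: ParamVector,
    data: TrialData,
    spec: ModelSpec,
    workspace: LikelihoodWorkspace | None = None,
) -> tuple[float, np.ndarray]:
    """Log-likelihood and its gradient on the original parameter scale."""
    ws = workspace if workspace is not None else LikelihoodWorkspace(data, spec)
    return ws.loglik_and_grad(params)


def posterior_compliance(
    params: ParamVector,
    data: TrialData,
    spec: ModelSpec,
    workspace: LikelihoodWorkspace | None = None,
) -> np.ndarray:
    """Posterior complier probabilities: 1 for S(1,1), 0 for S(1,0), and the
    Bayes ratio of the two mixture components for control subjects."""
    ws = workspace if workspace is not None else LikelihoodWorkspace(data, spec)
    return ws.posterior_complier(params)
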