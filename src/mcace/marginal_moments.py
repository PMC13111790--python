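"""Closed-form marginal moments of the stacked potential-outcome vector.

Integrating the latent factors and all random effects out of the two-level
model leaves, within a (stratum m, arm a), a multivariate normal for the
stacked K*(J+1) outcome vector with

    mu_mia    = lambda_m0 (x) 1_{J+1} + (Lambda (x) I_{J+1}) X_{i,a} beta_m
    Sigma_mi  = (Lambda (x) I) Z Sigma_v Z' (Lambda (x) I)'
                + (Lambda (x) I) D_eps (Lambda (x) I)'
                + diag(xi_m) (x) 1 1' + diag(tau2_m) (x) I

where D_eps is the level-2 disturbance covariance (identity under the
scale normalization Var(eps) = 1).  The four summands are the random-effect,
factor-disturbance, outcome-level random-intercept and measurement-noise
contributions.  Sigma does not depend on the arm (Z is assignment-free),
and for never-takers mu is also arm-free since D = 0 in both arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .model_spec import ModelSpec, receipt_under, stratum_design, build_designs
from .parameters import ParamVector

__all__ = ["MarginalMoments", "compute_mu", "compute_sigma", "moments_for", "chol_psd"]


@dataclass
class MarginalMoments:
    mu: np.ndarray
    sigma: np.ndarray
    stratum: str
    arm: int


def _lambda_kron(lam: np.ndarray, j1: int) -> np.ndarray:
    return np.kron(lam, np.eye(j1))


def compute_mu(
    params: ParamVector, X_ia: np.ndarray, spec: ModelSpec, m: str
) -> np.ndarray:
    """Marginal mean of the stacked outcomes for stratum ``m``.

    ``X_ia`` must be the stratum's *active-column* fixed design (rows
    factor-major over Q*(J+1)), conformable with ``params.beta[m]``.
    """
    j1 = spec.n_visits
    beta = params.beta[m]
    if X_ia.shape[1] != beta.shape[0]:
        raise ValueError(
            f"design has {X_ia.shape[1]} columns but beta[{m}] has {beta.shape[0]}"
        )
    lam = params.lambda_matrix(spec)
    u_mean = X_ia @ beta  # stacked factor means, (Q*(J+1),)
    return np.kron(params.lambda0[m], np.ones(j1)) + _lambda_kron(lam, j1) @ u_mean


def compute_sigma(
    params: ParamVector, Z_i: np.ndarray, spec: ModelSpec, m: str
) -> np.ndarray:
    """Marginal covariance of the stacked outcomes for stratum ``m``."""
    j1 = spec.n_visits
    lam = params.lambda_matrix(spec)
    A = _lambda_kron(lam, j1)
    # level-2 covariance of the stacked factor vector: Z Sigma_v Z' + D_eps
    M = Z_i @ scipy.linalg.block_diag(*params.sigma_v) @ Z_i.T if Z_i.shape[1] else np.zeros((spec.Q * j1,) * 2)
    M = M + np.kron(np.diag(params.eps_variances(spec)), np.eye(j1))
    ones = np.ones((j1, j1))
    sigma = (
        A @ M @ A.T
        + np.kron(np.diag(params.xi[m]), ones)
        + np.kron(np.diag(params.tau2[m]), np.eye(j1))
    )
    return 0.5 * (sigma + sigma.T)


def moments_for(
    params: ParamVector,
    spec: ModelSpec,
    times: np.ndarray,
    m: str,
    a: int,
    covariates=None,
) -> MarginalMoments:
    """Convenience wrapper building the designs and both moments."""
    X = stratum_design(spec, times, m, a, covariates)
    _, Z = build_designs(spec, times, a, receipt_under(m, a), covariates)
    return MarginalMoments(
        mu=compute_mu(params, X, spec, m),
        sigma=compute_sigma(params, Z, spec, m),
        stratum=m,
        arm=a,
    )


def chol_psd(sigma: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor with a single jitter retry.

    Finite-difference probes of the information matrix can push variance
    parameters to the PSD boundary; one shot of relative jitter
    (1e-10 * mean diagonal) keeps those evaluations alive without masking
    genuinely indefinite inputs.
    """
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * float(np.mean(np.diag(sigma)))
        return np.linalg.cholesky(sigma + max(jitter, 1e-300) * np.eye(sigma.shape[0]))
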