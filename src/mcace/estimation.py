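"""Maximum-likelihood fitting of the MCACE model.

The observed-data log-likelihood is maximized with a quasi-Newton
(limited-memory BFGS) search over the unconstrained packed parameter
space (log variances, log-Cholesky random-effect covariance blocks,
positive sign-anchor loadings).  Analytic gradients are supplied to the
optimizer and are chained from the original-scale score; the best of a
configurable number of jittered restarts is returned.  The covariance of
the estimates is the inverse observed information — the negative Hessian
of the log-likelihood at the MLE, obtained by central finite differences
of the analytic gradient on the original parameter scale (falling back
to the transformed scale with a delta-method correction when a variance
estimate sits on the boundary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .likelihood import LikelihoodWorkspace
from .model_spec import COMPLIER, STRATA, ModelSpec, TrialData, validate_spec
from .parameters import ParamLayout, ParamVector

__all__ = ["FitOptions", "FitResult", "initial_values", "fit_mle", "observed_information"]


@dataclass
class FitOptions:
    max_iter: int = 2000
    grad_tol: float = 1e-5
    rel_tol: float = 1e-9
    n_restarts: int = 3
    seed: int = 0
    hessian_step: float = 1e-4
    compute_vcov: bool = True

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if min(self.grad_tol, self.rel_tol, self.hessian_step) <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class FitResult:
    params_hat: ParamVector
    loglik: float
    converged: bool
    n_free: int
    n_subjects: int
    layout: ParamLayout
    spec: ModelSpec
    grad_norm: float
    restart_trace: list = field(default_factory=list)
    vcov: np.ndarray | None = None
    vcov_flags: list = field(default_factory=list)
    boundary_params: list = field(default_factory=list)
    label: str = ""

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_free

    @property
    def bic(self) -> float:
        # subjects are the independent units of the likelihood product
        return -2.0 * self.loglik + np.log(self.n_subjects) * self.n_free

    def se(self, name: str) -> float:
        if self.vcov is None:
            raise ValueError("fit has no covariance; rerun with compute_vcov=True")
        i = self.layout.names.index(name)
        return float(np.sqrt(max(self.vcov[i, i], 0.0)))

    def param_table(self):
        """Parameter names, estimates and (if available) standard errors."""
        import pandas as pd

        est = self.layout.to_original(self.params_hat)
        se = (
            np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))
            if self.vcov is not None
            else np.full_like(est, np.nan)
        )
        return pd.DataFrame({"parameter": self.layout.names, "estimate": est, "se": se})


def initial_values(data: TrialData, spec: ModelSpec, seed: int = 0) -> ParamVector:
    """Deterministic moment-based starting values.

    Baseline outcome means seed the level-1 intercepts; outcome variances
    are split between the random-intercept and residual components; the
    leading principal components of the baseline outcomes (restricted to
    the loading mask, anchors forced positive) seed the free loadings; the
    treated-arm compliance fraction seeds the logistic intercept.
    """
    rng = np.random.default_rng(seed)
    _ = rng  # determinism contract; jitter happens at restart time
    y0 = data.outcomes[:, 0, :]
    base_mean = np.nanmean(y0, axis=0)
    var_k = np.nanvar(data.outcomes.reshape(-1, spec.K), axis=0)
    if np.any(~np.isfinite(var_k)) or np.any(var_k <= 0):
        bad = [spec.outcome_names[k] for k in np.flatnonzero(~(var_k > 0))]
        raise ValueError(f"degenerate (constant or empty) outcome columns: {bad}")

    loadings = np.zeros(spec.loading.n_free)
    y0c = y0 - base_mean
    y0c = np.where(np.isfinite(y0c), y0c, 0.0)
    cov0 = np.cov(y0c, rowvar=False) if y0.shape[0] > spec.K else np.diag(var_k)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov0))
    order = np.argsort(evals)[::-1]
    pcs = evecs[:, order[: spec.Q]] * np.sqrt(np.maximum(evals[order[: spec.Q]], 0.1))
    # orient each component so its factor's sign anchor starts positive;
    # otherwise the positivity constraint can trap the anchor at zero
    for q in range(min(spec.Q, pcs.shape[1])):
        a = spec.loading.sign_anchor[q]
        if a >= 0 and pcs[a, q] < 0:
            pcs[:, q] = -pcs[:, q]
    for i, (k, q) in enumerate(spec.loading.free_entries()):
        v = pcs[k, q] if q < pcs.shape[1] else 0.3
        if spec.loading.sign_anchor[q] == k:
            v = max(abs(v), 0.2)
        loadings[i] = v if abs(v) > 1e-3 else 0.3

    treated = data.arm == 1
    frac = float(np.mean(data.receipt[treated])) if treated.any() else 0.5
    frac = min(max(frac, 0.05), 0.95)
    eta = np.zeros(spec.n_eta)
    eta[0] = float(np.log(frac / (1.0 - frac)))

    layout = ParamLayout(spec)
    return ParamVector(
        lambda0={m: base_mean.copy() for m in STRATA},
        loadings=loadings,
        xi={m: 0.5 * var_k.copy() for m in STRATA},
        tau2={m: 0.5 * var_k.copy() for m in STRATA},
        beta={m: np.zeros(layout.beta_len[m]) for m in STRATA},
        sigma_v=[0.1 * np.eye(r) for r in layout.rand_dims],
        eta=eta,
        eps_var=np.full(spec.Q, float(np.mean(var_k)) * 0.25)
        if spec.eps_mode == "free"
        else None,
    )


def _jitter(layout: ParamLayout, packed: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Restart perturbation: log-normal (sd 0.2) on log-variance coordinates,
    additive normal elsewhere (sd 0.25|x| + 0.05)."""
    out = packed.copy()
    s = layout.slices
    log_idx = np.zeros(layout.n_free, dtype=bool)
    for m in STRATA:
        log_idx[s[f"xi_{m}"]] = True
        log_idx[s[f"tau2_{m}"]] = True
    if layout.n_eps:
        log_idx[s["eps_var"]] = True
    out[log_idx] += rng.normal(0.0, 0.2, int(log_idx.sum()))
    rest = ~log_idx
    out[rest] += rng.normal(0.0, 0.25 * np.abs(out[rest]) + 0.05)
    return out


def fit_mle(
    data: TrialData,
    spec: ModelSpec,
    options: FitOptions | None = None,
    start: ParamVector | None = None,
    workspace: LikelihoodWorkspace | None = None,
    label: str = "",
) -> FitResult:
    """Maximize the observed-data likelihood; best of ``n_restarts`` starts."""
    options = options or FitOptions()
    findings = [f for f in validate_spec(spec, data) if not f.startswith("warning:")]
    if findings:
        raise ValueError("invalid model specification: " + "; ".join(findings))
    ws = workspace if workspace is not None else LikelihoodWorkspace(data, spec)
    layout = ws.layout
    x0 = layout.pack(start if start is not None else initial_values(data, spec, options.seed))
    rng = np.random.default_rng(options.seed)

    def objective(x):
        pv = layout.unpack(x)
        ll, g_orig = ws.loglik_and_grad(pv)
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(x)
        return -ll, -layout.chain_to_packed(g_orig, x)

    trace = []
    best = None
    for restart in range(options.n_restarts):
        xs = x0 if restart == 0 else _jitter(layout, x0, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = scipy.optimize.minimize(
                objective,
                xs,
                jac=True,
                method="L-BFGS-B",
                options={
                    "maxiter": options.max_iter,
                    "ftol": options.rel_tol,
                    "gtol": options.grad_tol,
                    "maxcor": 25,
                },
            )
        trace.append((float(-res.fun), bool(res.success)))
        if best is None or -res.fun > -best.fun:
            best = res

    params_hat = layout.unpack(best.x)
    gnorm = float(np.max(np.abs(best.jac)))
    fit = FitResult(
        params_hat=params_hat,
        loglik=float(-best.fun),
        converged=bool(best.success),
        n_free=layout.n_free,
        n_subjects=data.n_subjects,
        layout=layout,
        spec=spec,
        grad_norm=gnorm,
        restart_trace=trace,
        boundary_params=layout.boundary_flags(best.x),
        label=label,
    )
    if not fit.converged and gnorm <= 10 * options.grad_tol:
        # L-BFGS sometimes stops on ftol without setting success at a point
        # whose gradient is effectively zero; accept it.
        fit.converged = True
    if options.compute_vcov:
        try:
            fit.vcov, fit.vcov_flags = observed_information(
                params_hat, data, spec, options, workspace=ws
            )
        except np.linalg.LinAlgError as err:  # pragma: no cover - diagnostic path
            fit.vcov = None
            fit.vcov_flags = [f"information matrix not invertible: {err}"]
    return fit


def observed_information(
    params_hat: ParamVector,
    data: TrialData,
    spec: ModelSpec,
    options: FitOptions | None = None,
    workspace: LikelihoodWorkspace | None = None,
) -> tuple[np.ndarray, list]:
    """Covariance of the MLEs: inverse negative Hessian at the optimum.

    The Hessian is the central finite difference of the analytic gradient
    in the *original* parameterization (variances as variances), which is
    what Wald tables report.  If a variance parameter is at the boundary,
    the Hessian is instead taken on the transformed scale and mapped back
    by the delta method (finite differences across a boundary are invalid).
    Returns ``(vcov, flags)``; a non-PD Hessian is projected to the nearest
    PSD matrix and flagged.  A singular information matrix raises, naming
    the null-space parameters (weak-identification diagnostic).
    """
    options = options or FitOptions()
    ws = workspace if workspace is not None else LikelihoodWorkspace(data, spec)
    layout = ws.layout
    flags: list[str] = []
    packed_hat = layout.pack(params_hat)
    boundary = layout.boundary_flags(packed_hat)

    if boundary:
        flags.append(f"boundary variance parameters {boundary}; transformed-scale Hessian")
        H_t = _fd_hessian(
            lambda x: layout.chain_to_packed(
                ws.loglik_and_grad(layout.unpack(x))[1], x
            ),
            packed_hat,
            options.hessian_step,
        )
        # delta method: vcov_orig = J vcov_packed J' with J = d orig / d packed
        J = _orig_by_packed_jacobian(layout, packed_hat)
        vcov_p, sub_flags = _invert_neg_hessian(H_t, layout.names)
        flags.extend(sub_flags)
        return J @ vcov_p @ J.T, flags

    x_hat = layout.to_original(params_hat)

    def grad_orig(x):
        return ws.loglik_and_grad(layout.from_original(x))[1]

    H = _fd_hessian(grad_orig, x_hat, options.hessian_step)
    vcov, sub_flags = _invert_neg_hessian(H, layout.names)
    flags.extend(sub_flags)
    return vcov, flags


def _fd_hessian(grad_fn, x: np.ndarray, rel_step: float) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        h = rel_step * max(abs(x[i]), 1.0)
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        H[i] = (grad_fn(xp) - grad_fn(xm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def _invert_neg_hessian(H: np.ndarray, names: list[str]) -> tuple[np.ndarray, list]:
    flags: list[str] = []
    info = -H
    evals, evecs = np.linalg.eigh(info)
    tol = max(1e-10 * float(np.max(np.abs(evals))), 1e-12)
    null = evals < tol
    if null.all():
        raise np.linalg.LinAlgError("information matrix has no positive curvature")
    if null.any():
        weights = np.abs(evecs[:, null]).sum(axis=1)
        weak = [names[i] for i in np.argsort(weights)[::-1][: int(null.sum())]]
        if (evals < -tol).any():
            flags.append(f"information matrix not PSD; projected (directions near {weak})")
        else:
            raise np.linalg.LinAlgError(
                f"singular information matrix; weakly identified parameters: {weak}"
            )
        evals = np.maximum(evals, tol)
    vcov = (evecs / evals) @ evecs.T
    return 0.5 * (vcov + vcov.T), flags


def _orig_by_packed_jacobian(layout: ParamLayout, packed: np.ndarray) -> np.ndarray:
    n = layout.n_free
    J = np.empty((n, n))
    eps = 1e-6
    base = layout.to_original(layout.unpack(packed))
    for i in range(n):
        xp = packed.copy()
        xp[i] += eps
        J[:, i] = (layout.to_original(layout.unpack(xp)) - base) / eps
    return J
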