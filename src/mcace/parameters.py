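"""Free-parameter bookkeeping: the structured parameter vector and its
unconstrained transform.

The full parameter collection is
``pi = (beta_c, beta_n, lambda, lambda_c0, lambda_n0, sigma_v, psi_c, psi_n, eta)``
with ``psi_m = (xi_m1..xi_mK, tau2_m1..tau2_mK)``.  Two flat coordinate
systems are maintained over the same ordering:

* the *original* scale — variances as variances, the random-effect
  covariance blocks by their lower-triangular (covariance) entries.  Wald
  reporting and the observed-information Hessian live here.
* the *packed* scale — an unconstrained vector for quasi-Newton
  optimization: log variances, log-Cholesky factors for the Sigma_v
  blocks, log on the per-factor sign-anchor loadings (which enforces the
  positivity that resolves the sign indeterminacy).

Block order: lambda0_c, lambda0_n, free loadings, xi_c, xi_n, tau2_c,
tau2_n, beta_c, beta_n, sigma_v blocks, (eps variances,) eta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_spec import (
    COMPLIER,
    NEVER_TAKER,
    STRATA,
    ModelSpec,
    active_fixed_terms,
)

__all__ = ["ParamVector", "ParamLayout"]

_LOG_FLOOR = -12.0  # log-variance below this is treated as a boundary hit


@dataclass
class ParamVector:
    """Structured container for all free parameters of the MCACE model.

    The level-2 disturbance variance is fixed at 1 by the scale
    normalization and is *not* stored here unless the spec frees it
    (``eps_mode == "free"``).
    """

    lambda0: dict  # stratum -> (K,)
    loadings: np.ndarray  # (n_free,) free entries of Lambda, row-major
    xi: dict  # stratum -> (K,) random-intercept variances
    tau2: dict  # stratum -> (K,) residual variances
    beta: dict  # stratum -> flat fixed-effect vector (factor-major)
    sigma_v: list  # per-factor (r_q, r_q) covariance blocks
    eta: np.ndarray  # compliance coefficients, intercept first
    eps_var: np.ndarray | None = None  # (Q,) when eps_mode == "free"

    def copy(self) -> "ParamVector":
        return ParamVector(
            lambda0={m: v.copy() for m, v in self.lambda0.items()},
            loadings=self.loadings.copy(),
            xi={m: v.copy() for m, v in self.xi.items()},
            tau2={m: v.copy() for m, v in self.tau2.items()},
            beta={m: v.copy() for m, v in self.beta.items()},
            sigma_v=[s.copy() for s in self.sigma_v],
            eta=self.eta.copy(),
            eps_var=None if self.eps_var is None else self.eps_var.copy(),
        )

    def lambda_matrix(self, spec: ModelSpec) -> np.ndarray:
        """Assemble the full K x Q loading matrix."""
        lam = spec.loading.fixed_values.copy()
        ks, qs = np.nonzero(spec.loading.mask)
        lam[ks, qs] = self.loadings
        return lam

    def eps_variances(self, spec: ModelSpec) -> np.ndarray:
        """Per-factor level-2 disturbance variances under the spec's mode."""
        if spec.eps_mode == "fixed":
            return np.ones(spec.Q)
        if spec.eps_mode == "zero":
            return np.zeros(spec.Q)
        return np.asarray(self.eps_var, dtype=float)


def _tril_indices(r: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(r)


class ParamLayout:
    """Index map between ``ParamVector`` and the two flat coordinate systems."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        K, Q = spec.K, spec.Q
        self.beta_terms = {
            m: [active_fixed_terms(spec, q, m) for q in range(Q)] for m in STRATA
        }
        self.beta_len = {
            m: sum(len(ts) for ts in self.beta_terms[m]) for m in STRATA
        }
        self.rand_dims = [len(spec.level2.random_terms[q]) for q in range(Q)]
        self.n_eps = Q if spec.eps_mode == "free" else 0
        self.anchor_flags = spec.loading.anchor_flags()

        names: list[str] = []
        slices: dict[str, slice] = {}

        def block(tag: str, labels: list[str]) -> None:
            start = len(names)
            names.extend(labels)
            slices[tag] = slice(start, len(names))

        onames = spec.outcome_names
        fnames = spec.factor_names
        for m in STRATA:
            block(f"lambda0_{m}", [f"lambda0[{m},{o}]" for o in onames])
        block(
            "loadings",
            [f"lambda[{onames[k]},{fnames[q]}]" for k, q in spec.loading.free_entries()],
        )
        for m in STRATA:
            block(f"xi_{m}", [f"xi[{m},{o}]" for o in onames])
        for m in STRATA:
            block(f"tau2_{m}", [f"tau2[{m},{o}]" for o in onames])
        for m in STRATA:
            labels = [
                f"beta[{m},{fnames[q]},{t}]"
                for q in range(Q)
                for t in self.beta_terms[m][q]
            ]
            block(f"beta_{m}", labels)
        sv_labels = []
        for q, r in enumerate(self.rand_dims):
            rows, cols = _tril_indices(r)
            sv_labels.extend(
                f"Sigma_v[{fnames[q]},{spec.level2.random_terms[q][i]},"
                f"{spec.level2.random_terms[q][j]}]"
                for i, j in zip(rows, cols)
            )
        block("sigma_v", sv_labels)
        if self.n_eps:
            block("eps_var", [f"eps_var[{f}]" for f in fnames])
        block("eta", ["eta[intercept]"] + [f"eta[{c}]" for c in spec.compliance_covariates])

        self.names = names
        self.slices = slices
        self.n_free = len(names)

    # ------------------------------------------------------------------
    # original-scale flat vector
    # ------------------------------------------------------------------
    def to_original(self, pv: ParamVector) -> np.ndarray:
        x = np.empty(self.n_free)
        s = self.slices
        for m in STRATA:
            x[s[f"lambda0_{m}"]] = pv.lambda0[m]
        x[s["loadings"]] = pv.loadings
        for m in STRATA:
            x[s[f"xi_{m}"]] = pv.xi[m]
            x[s[f"tau2_{m}"]] = pv.tau2[m]
            x[s[f"beta_{m}"]] = pv.beta[m]
        sv = []
        for q, r in enumerate(self.rand_dims):
            rows, cols = _tril_indices(r)
            sv.extend(pv.sigma_v[q][rows, cols])
        x[s["sigma_v"]] = sv
        if self.n_eps:
            x[s["eps_var"]] = pv.eps_var
        x[s["eta"]] = pv.eta
        return x

    def from_original(self, x: np.ndarray) -> ParamVector:
        x = np.asarray(x, dtype=float)
        s = self.slices
        sigma_v = []
        off = s["sigma_v"].start
        for r in self.rand_dims:
            rows, cols = _tril_indices(r)
            blk = np.zeros((r, r))
            n = len(rows)
            blk[rows, cols] = x[off : off + n]
            blk[cols, rows] = blk[rows, cols]
            sigma_v.append(blk)
            off += n
        return ParamVector(
            lambda0={m: x[s[f"lambda0_{m}"]].copy() for m in STRATA},
            loadings=x[s["loadings"]].copy(),
            xi={m: x[s[f"xi_{m}"]].copy() for m in STRATA},
            tau2={m: x[s[f"tau2_{m}"]].copy() for m in STRATA},
            beta={m: x[s[f"beta_{m}"]].copy() for m in STRATA},
            sigma_v=sigma_v,
            eta=x[s["eta"]].copy(),
            eps_var=x[s["eps_var"]].copy() if self.n_eps else None,
        )

    # ------------------------------------------------------------------
    # packed (unconstrained) vector
    # ------------------------------------------------------------------
    def pack(self, pv: ParamVector) -> np.ndarray:
        x = self.to_original(pv).copy()
        s = self.slices
        anchors = np.flatnonzero(self.anchor_flags) + s["loadings"].start
        x[anchors] = np.log(np.maximum(x[anchors], np.exp(_LOG_FLOOR)))
        for m in STRATA:
            for tag in (f"xi_{m}", f"tau2_{m}"):
                x[s[tag]] = np.log(np.maximum(x[s[tag]], np.exp(_LOG_FLOOR)))
        off = s["sigma_v"].start
        for q, r in enumerate(self.rand_dims):
            rows, cols = _tril_indices(r)
            n = len(rows)
            blk = pv.sigma_v[q]
            L = np.linalg.cholesky(blk + 1e-12 * np.eye(r)) if r else np.zeros((0, 0))
            vals = L[rows, cols].copy()
            diag = rows == cols
            vals[diag] = np.log(np.maximum(vals[diag], np.exp(_LOG_FLOOR)))
            x[off : off + n] = vals
            off += n
        if self.n_eps:
            x[s["eps_var"]] = np.log(np.maximum(x[s["eps_var"]], np.exp(_LOG_FLOOR)))
        return x

    def unpack(self, x: np.ndarray) -> ParamVector:
        x = np.asarray(x, dtype=float).copy()
        s = self.slices
        anchors = np.flatnonzero(self.anchor_flags) + s["loadings"].start
        x[anchors] = np.exp(x[anchors])
        for m in STRATA:
            for tag in (f"xi_{m}", f"tau2_{m}"):
                x[s[tag]] = np.exp(x[s[tag]])
        # rebuild sigma_v covariance entries from the log-Cholesky params
        off = s["sigma_v"].start
        for q, r in enumerate(self.rand_dims):
            rows, cols = _tril_indices(r)
            n = len(rows)
            vals = x[off : off + n].copy()
            L = np.zeros((r, r))
            L[rows, cols] = vals
            np.fill_diagonal(L, np.exp(np.diag(L)))
            blk = L @ L.T
            x[off : off + n] = blk[rows, cols]
            off += n
        if self.n_eps:
            x[s["eps_var"]] = np.exp(x[s["eps_var"]])
        return self.from_original(x)

    def chain_to_packed(self, grad_orig: np.ndarray, packed: np.ndarray) -> np.ndarray:
        """Map an original-scale gradient to the packed coordinates.

        ``packed`` is the point (packed scale) at which the gradient was
        taken.  Log-parameters pick up a factor of their value; the
        Sigma_v blocks chain through Sigma = L L'.
        """
        g = np.asarray(grad_orig, dtype=float).copy()
        s = self.slices
        anchors = np.flatnonzero(self.anchor_flags) + s["loadings"].start
        g[anchors] *= np.exp(packed[anchors])
        for m in STRATA:
            for tag in (f"xi_{m}", f"tau2_{m}"):
                g[s[tag]] *= np.exp(packed[s[tag]])
        off = s["sigma_v"].start
        for q, r in enumerate(self.rand_dims):
            rows, cols = _tril_indices(r)
            n = len(rows)
            # original-scale grad holds d/d sigma_rs for lower-tri entries,
            # off-diagonals already summed over the two symmetric positions.
            G = np.zeros((r, r))
            G[rows, cols] = g[off : off + n]
            # off-diagonal tril grads carry both symmetric positions, so the
            # full-matrix derivative is the symmetrized half
            Gfull = 0.5 * (G + G.T)
            L = np.zeros((r, r))
            L[rows, cols] = packed[off : off + n]
            np.fill_diagonal(L, np.exp(np.diag(L)))
            dL = 2.0 * Gfull @ L
            vals = dL[rows, cols]
            diag = rows == cols
            vals = vals.copy()
            vals[diag] *= np.diag(L)
            g[off : off + n] = vals
            off += n
        if self.n_eps:
            g[s["eps_var"]] *= np.exp(packed[s["eps_var"]])
        return g

    def boundary_flags(self, packed: np.ndarray) -> list[str]:
        """Names of variance parameters at the transform floor."""
        s = self.slices
        flagged = []
        for m in STRATA:
            for tag in (f"xi_{m}", f"tau2_{m}"):
                for i in range(*s[tag].indices(self.n_free)):
                    if packed[i] < _LOG_FLOOR:
                        flagged.append(self.names[i])
        return flagged

    def beta_offset(self, stratum: str, q: int, term: str) -> int:
        """Global index (layout order) of a beta coefficient."""
        base = self.slices[f"beta_{stratum}"].start
        off = 0
        for fq in range(q):
            off += len(self.beta_terms[stratum][fq])
        terms = self.beta_terms[stratum][q]
        if term not in terms:
            raise KeyError(f"beta[{stratum},{q},{term}] is not a free parameter")
        return base + off + terms.index(term)
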