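"""Domain types and design-matrix construction for the latent-factor MCACE model.

The model is a two-level latent-factor / mixed-effects model fitted within
principal strata of treatment compliance.  Level 1 links the K observed
endpoints at each visit to Q latent factors through a loading matrix shared
across time, strata and arms; level 2 gives each factor a linear mixed model
in time, treatment receipt and their interactions.  Compliance-stratum
membership (complier vs never-taker) follows a logistic model in baseline
covariates.  This module holds the configuration objects (loading structure,
level-2 terms, constraints), the trial-data container, and the construction
of the fixed/random-effect design matrices for the stacked factor vector.

Stacking conventions (used consistently everywhere):

* the stacked outcome vector of length K*(J+1) is outcome-major,
  time-minor: entry ``k*(J+1) + j`` is endpoint ``k`` at visit ``j`` —
  the convention under which the marginal covariance is exactly the
  Kronecker composition ``(Lambda (x) I_{J+1}) ...``;
* the stacked latent-factor vector of length Q*(J+1) is factor-major,
  time-minor, matching the concatenation of per-factor random effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "COMPLIER",
    "NEVER_TAKER",
    "STRATA",
    "ComplianceStratum",
    "TrialData",
    "LoadingSpec",
    "Level2Spec",
    "ModelSpec",
    "build_designs",
    "stratum_design",
    "active_fixed_terms",
    "receipt_under",
    "validate_spec",
]


class ComplianceStratum(str, Enum):
    """The two compliance principal strata.

    With no treatment access in the control arm, D(0) = 0 for everyone,
    which rules out always-takers and defiers; compliers (D(1), D(0)) =
    (1, 0) and never-takers (0, 0) are the only strata.
    """

    complier = "c"
    never_taker = "n"


COMPLIER = ComplianceStratum.complier.value
NEVER_TAKER = ComplianceStratum.never_taker.value
STRATA = (COMPLIER, NEVER_TAKER)

# Term vocabulary for the level-2 model.  ``D`` denotes treatment receipt
# D_i(a); anything not listed here is looked up as a baseline covariate.
_TIME_TERMS = {"t": lambda t: t, "t2": lambda t: t**2}
_D_TERMS = {
    "D": lambda t: np.ones_like(t),
    "D:t": lambda t: t,
    "D:t2": lambda t: t**2,
}
_INTERCEPT_ALIASES = {"1", "intercept", "const", "Intercept"}


def is_d_term(term: str) -> bool:
    return term in _D_TERMS


@dataclass
class TrialData:
    """Observed data from a two-arm trial with noncompliance.

    Parameters
    ----------
    arm : (N,) int array
        Randomization indicator A_i (1 = intervention).
    receipt : (N,) int array
        Treatment receipt D_i.  Meaningful only in the treated arm; control
        subjects have no treatment access, so any control-arm entry is
        ignored and treated as 0.
    outcomes : (N, J+1, K) float array
        Continuous endpoints; NaN marks a missing cell.
    times : (J+1,) float array
        Shared visit schedule.
    covariates : (N, p) float array
        Compliance-model design W_i, intercept column included.
    """

    arm: np.ndarray
    receipt: np.ndarray
    outcomes: np.ndarray
    times: np.ndarray
    covariates: np.ndarray
    covariate_names: tuple[str, ...] = ()
    outcome_names: tuple[str, ...] = ()
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.arm = np.asarray(self.arm, dtype=int)
        self.receipt = np.asarray(self.receipt, dtype=int)
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.outcomes.ndim != 3:
            raise ValueError("outcomes must be an (N, J+1, K) array")
        n = self.outcomes.shape[0]
        if not (len(self.arm) == len(self.receipt) == self.covariates.shape[0] == n):
            raise ValueError("inconsistent subject dimensions")
        if self.outcomes.shape[1] != len(self.times):
            raise ValueError("visit dimension does not match times")
        # receipt is undefined off the treated arm
        self.receipt = np.where(self.arm == 1, self.receipt, 0)
        if self.subject_ids is None:
            self.subject_ids = np.arange(n)

    @property
    def n_subjects(self) -> int:
        return self.outcomes.shape[0]

    @property
    def n_visits(self) -> int:
        return self.outcomes.shape[1]

    @property
    def n_outcomes(self) -> int:
        return self.outcomes.shape[2]

    def stacked(self) -> np.ndarray:
        """(N, K*(J+1)) view of the outcomes, outcome-major / time-minor."""
        n, j1, k = self.outcomes.shape
        return self.outcomes.transpose(0, 2, 1).reshape(n, k * j1)

    def restrict_outcomes(self, keep: Sequence[int]) -> "TrialData":
        """A copy keeping only the endpoint columns in ``keep``."""
        keep = list(keep)
        names = tuple(self.outcome_names[i] for i in keep) if self.outcome_names else ()
        return TrialData(
            arm=self.arm.copy(),
            receipt=self.receipt.copy(),
            outcomes=self.outcomes[:, :, keep].copy(),
            times=self.times.copy(),
            covariates=self.covariates.copy(),
            covariate_names=self.covariate_names,
            outcome_names=names,
            subject_ids=self.subject_ids.copy(),
        )


@dataclass
class LoadingSpec:
    """Structure of the K x Q loading matrix Lambda.

    ``mask[k, q]`` flags a free loading; non-free entries hold
    ``fixed_values[k, q]`` (typically 0, or 1 for a unit-loading model).
    In exploratory mode identifiability requires lambda_kq = 0 for q > k;
    in confirmatory mode the zero pattern encodes substantive knowledge.
    One loading per factor (the sign anchor) is constrained positive to
    resolve the sign indeterminacy that the zero restrictions leave open.
    """

    mask: np.ndarray
    fixed_values: np.ndarray | None = None
    mode: str = "confirmatory"
    sign_anchor: tuple[int, ...] | None = None  # per-factor row index

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.fixed_values is None:
            self.fixed_values = np.zeros_like(self.mask, dtype=float)
        else:
            self.fixed_values = np.asarray(self.fixed_values, dtype=float)
        if self.sign_anchor is None:
            anchors = []
            for q in range(self.mask.shape[1]):
                rows = np.flatnonzero(self.mask[:, q])
                anchors.append(int(rows[0]) if rows.size else -1)
            self.sign_anchor = tuple(anchors)

    @property
    def n_free(self) -> int:
        return int(self.mask.sum())

    def free_entries(self) -> list[tuple[int, int]]:
        """(k, q) positions of free loadings, row-major order."""
        ks, qs = np.nonzero(self.mask)
        return list(zip(ks.tolist(), qs.tolist()))

    def anchor_flags(self) -> np.ndarray:
        """Boolean over free entries marking the per-factor sign anchors."""
        flags = np.zeros(self.n_free, dtype=bool)
        for i, (k, q) in enumerate(self.free_entries()):
            if self.sign_anchor[q] == k:
                flags[i] = True
        return flags


@dataclass
class Level2Spec:
    """Per-factor fixed and random effect terms of the latent-factor model.

    Terms come from the vocabulary ``t, t2, D, D:t, D:t2`` plus named
    baseline covariates.  Neither list may contain an intercept (the level-1
    intercepts and random intercepts already carry location).  Setting
    ``baseline_balance`` removes the D main effect (beta_qm01 = 0), the
    usual randomized-trial constraint of no baseline difference between
    assigned arms within a stratum.  ``zero_constraints`` lists
    (stratum, factor, term) coefficients pinned to zero — the mechanism for
    nested null models in likelihood-ratio tests.
    """

    fixed_terms: tuple[tuple[str, ...], ...]
    random_terms: tuple[tuple[str, ...], ...]
    baseline_balance: bool = True
    zero_constraints: tuple[tuple[str, int, str], ...] = ()

    def __post_init__(self) -> None:
        self.fixed_terms = tuple(tuple(ts) for ts in self.fixed_terms)
        self.random_terms = tuple(tuple(ts) for ts in self.random_terms)
        self.zero_constraints = tuple(tuple(zc) for zc in self.zero_constraints)

    def with_zero_constraints(
        self, extra: Sequence[tuple[str, int, str]]
    ) -> "Level2Spec":
        return Level2Spec(
            fixed_terms=self.fixed_terms,
            random_terms=self.random_terms,
            baseline_balance=self.baseline_balance,
            zero_constraints=self.zero_constraints + tuple(tuple(e) for e in extra),
        )


@dataclass
class ModelSpec:
    """Complete configuration of a latent-factor MCACE model.

    ``eps_mode`` controls the level-2 disturbance variance: ``"fixed"``
    pins Var(eps) = 1 (the scale normalization that identifies the latent
    factors), ``"free"`` estimates one variance per factor, and ``"zero"``
    removes the disturbance (used by the single-outcome comparator, where
    it is not separately identified from the residual variance).
    """

    K: int
    Q: int
    n_visits: int
    loading: LoadingSpec
    level2: Level2Spec
    compliance_covariates: tuple[str, ...] = ()
    eps_mode: str = "fixed"
    outcome_names: tuple[str, ...] = ()
    factor_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.compliance_covariates = tuple(self.compliance_covariates)
        if not self.outcome_names:
            self.outcome_names = tuple(f"y{k + 1}" for k in range(self.K))
        if not self.factor_names:
            self.factor_names = tuple(f"f{q + 1}" for q in range(self.Q))

    @property
    def n_eta(self) -> int:
        return 1 + len(self.compliance_covariates)

    @property
    def stacked_dim(self) -> int:
        return self.K * self.n_visits

    def uses_level2_covariates(self) -> bool:
        vocab = set(_TIME_TERMS) | set(_D_TERMS)
        for terms in self.level2.fixed_terms + self.level2.random_terms:
            if any(t not in vocab for t in terms):
                return True
        return False

    def null_spec(self, constrained: Sequence[tuple[str, int, str]]) -> "ModelSpec":
        """Nested spec with extra coefficients pinned to zero."""
        return ModelSpec(
            K=self.K,
            Q=self.Q,
            n_visits=self.n_visits,
            loading=self.loading,
            level2=self.level2.with_zero_constraints(constrained),
            compliance_covariates=self.compliance_covariates,
            eps_mode=self.eps_mode,
            outcome_names=self.outcome_names,
            factor_names=self.factor_names,
        )


def receipt_under(stratum: str, arm: int) -> int:
    """Treatment receipt D_i(a) implied by stratum membership."""
    return 1 if (stratum == COMPLIER and arm == 1) else 0


def _eval_term(term: str, times: np.ndarray, d: int, covariates=None) -> np.ndarray:
    if term in _TIME_TERMS:
        return _TIME_TERMS[term](times)
    if term in _D_TERMS:
        return float(d) * _D_TERMS[term](times)
    if term in _INTERCEPT_ALIASES:
        raise ValueError(
            "intercept terms are not allowed in the level-2 model "
            "(location is carried by the level-1 intercepts)"
        )
    if covariates is not None and term in covariates:
        return np.full_like(times, float(covariates[term]))
    raise ValueError(f"unknown level-2 term {term!r}")


def _factor_terms(spec: ModelSpec, q: int) -> tuple[str, ...]:
    terms = spec.level2.fixed_terms[q]
    if spec.level2.baseline_balance:
        terms = tuple(t for t in terms if t != "D")
    return terms


def active_fixed_terms(spec: ModelSpec, q: int, stratum: str) -> tuple[str, ...]:
    """Fixed-effect terms carrying a free coefficient for (factor, stratum).

    Never-takers have D_i(a) = 0 in both arms, so D-interaction columns are
    identically zero there; the corresponding coefficients are structurally
    unidentified and are excluded from the parameter vector.
    """
    terms = _factor_terms(spec, q)
    if stratum == NEVER_TAKER:
        terms = tuple(t for t in terms if not is_d_term(t))
    zeroed = {
        (m, fq, t) for (m, fq, t) in spec.level2.zero_constraints if m == stratum
    }
    return tuple(t for t in terms if (stratum, q, t) not in zeroed)


def build_designs(
    spec: ModelSpec,
    times: np.ndarray,
    arm: int,
    receipt: int,
    covariates=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked fixed- and random-effect design matrices (X_ia, Z_i).

    Rows run factor-major, time-minor over the stacked factor vector
    (Q*(J+1) rows).  X columns are grouped by factor and evaluate that
    factor's fixed terms with D = ``receipt``; the control arm has
    D_i(0) = 0, so all treatment columns vanish there.  Z is arm-free
    (random terms may not involve D).
    """
    times = np.asarray(times, dtype=float)
    j1 = len(times)
    d = int(receipt) if int(arm) == 1 else 0
    x_blocks, z_blocks = [], []
    for q in range(spec.Q):
        fterms = _factor_terms(spec, q)
        xb = (
            np.column_stack([_eval_term(t, times, d, covariates) for t in fterms])
            if fterms
            else np.zeros((j1, 0))
        )
        rterms = spec.level2.random_terms[q]
        zb = (
            np.column_stack([_eval_term(t, times, 0, covariates) for t in rterms])
            if rterms
            else np.zeros((j1, 0))
        )
        x_blocks.append(xb)
        z_blocks.append(zb)
    return _block_diag(x_blocks), _block_diag(z_blocks)


def stratum_design(
    spec: ModelSpec,
    times: np.ndarray,
    stratum: str,
    arm: int,
    covariates=None,
) -> np.ndarray:
    """Fixed-effect design for a stratum/arm, restricted to its free betas."""
    x_full, _ = build_designs(
        spec, times, arm, receipt_under(stratum, arm), covariates
    )
    cols, offset = [], 0
    for q in range(spec.Q):
        fterms = _factor_terms(spec, q)
        active = set(active_fixed_terms(spec, q, stratum))
        cols.extend(offset + i for i, t in enumerate(fterms) if t in active)
        offset += len(fterms)
    return x_full[:, cols]


def _block_diag(blocks: list[np.ndarray]) -> np.ndarray:
    rows = sum(b.shape[0] for b in blocks)
    cols = sum(b.shape[1] for b in blocks)
    out = np.zeros((rows, cols))
    r = c = 0
    for b in blocks:
        out[r : r + b.shape[0], c : c + b.shape[1]] = b
        r += b.shape[0]
        c += b.shape[1]
    return out


def validate_spec(spec: ModelSpec, data: TrialData | None = None) -> list[str]:
    """Structural identifiability and consistency checks.

    Returns a list of findings (empty when the configuration satisfies the
    identification constraints: no level-2 intercepts, exploratory
    upper-triangle zeros, sign anchors on free loadings, random terms
    nested in fixed terms and free of D).  Warnings are prefixed
    ``"warning:"``; anything else should be treated as an error.
    """
    findings: list[str] = []
    L = spec.loading
    if L.mask.shape != (spec.K, spec.Q):
        findings.append(f"loading mask shape {L.mask.shape} != (K, Q) = ({spec.K}, {spec.Q})")
        return findings
    if spec.Q >= spec.K and spec.K > 1:
        findings.append(f"warning: Q = {spec.Q} >= K = {spec.K}; factor model is not a reduction")
    if L.mode == "exploratory":
        for k, q in L.free_entries():
            if q > k:
                findings.append(
                    f"exploratory mode requires lambda_kq = 0 for q > k; "
                    f"entry (k={k + 1}, q={q + 1}) is free"
                )
    for q in range(spec.Q):
        if not L.mask[:, q].any():
            findings.append(
                f"warning: factor {q + 1} has no free loading; its scale is fixed entirely "
                "by the fixed values"
            )
        elif L.sign_anchor[q] < 0 or not L.mask[L.sign_anchor[q], q]:
            findings.append(f"sign anchor of factor {q + 1} does not point to a free loading")
    if len(spec.level2.fixed_terms) != spec.Q or len(spec.level2.random_terms) != spec.Q:
        findings.append("level-2 term lists must have one entry per factor")
        return findings
    for q in range(spec.Q):
        fixed = spec.level2.fixed_terms[q]
        for t in fixed:
            if t in _INTERCEPT_ALIASES:
                findings.append(
                    f"factor {q + 1}: intercept term {t!r} in the level-2 fixed effects "
                    "violates the location normalization (no level-2 intercepts)"
                )
        for t in spec.level2.random_terms[q]:
            if t in _INTERCEPT_ALIASES:
                findings.append(
                    f"factor {q + 1}: random intercept violates the location normalization"
                )
            elif is_d_term(t):
                findings.append(
                    f"factor {q + 1}: random term {t!r} involves treatment receipt; "
                    "random designs must be assignment-free"
                )
            elif t not in fixed:
                findings.append(
                    f"factor {q + 1}: random term {t!r} is not among the fixed terms"
                )
    if spec.eps_mode not in ("fixed", "free", "zero"):
        findings.append(f"unknown eps_mode {spec.eps_mode!r}")
    if data is not None:
        if data.n_outcomes != spec.K:
            findings.append(f"data has {data.n_outcomes} outcomes, spec K = {spec.K}")
        if data.n_visits != spec.n_visits:
            findings.append(f"data has {data.n_visits} visits, spec expects {spec.n_visits}")
        if data.covariates.shape[1] != spec.n_eta:
            findings.append(
                f"compliance design has {data.covariates.shape[1]} columns, "
                f"spec expects {spec.n_eta} (intercept + named covariates)"
            )
        bad = np.setdiff1d(np.unique(data.arm), [0, 1])
        if bad.size:
            findings.append(f"arm contains values other than 0/1: {bad.tolist()}")
        mask = np.isfinite(data.outcomes)
        if not mask.any(axis=(1, 2)).all():
            findings.append("some subjects have no observed outcome at any visit")
    return findings
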