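"""Causal estimands and inference: PCE/CACE, Wald tests, global LRT,
and information-criterion model comparison.

The principal causal effect on factor q at visit j within stratum m is the
fixed-effect contrast

    PCE_qmj = (x_qij(a=1) - x_qij(a=0))' beta_qm ,

i.e. the assignment effect on the latent-factor mean, with the random
effects and disturbances averaging out within the stratum.  The CACE is
the complier-stratum PCE; never-takers have PCE identically zero under the
exclusion restriction, since their receipt is 0 in both arms and every
treatment column of the contrast vanishes.  Standard errors follow by the
delta method (the estimand is linear, so the delta method is exact given
the covariance of the beta estimates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .estimation import FitResult
from .model_spec import COMPLIER, ModelSpec, active_fixed_terms, receipt_under
from .model_spec import _eval_term  # term evaluation shares one vocabulary

__all__ = [
    "EstimandReport",
    "TestResult",
    "pce",
    "cace",
    "wald_test",
    "global_lrt",
    "compare_models",
]

_Z95 = 1.959963984540054  # exact normal 97.5% quantile


@dataclass
class EstimandReport:
    factor: int
    stratum: str
    visit: int
    estimate: float
    se: float
    z: float
    p: float
    ci: tuple[float, float]
    label: str = ""

    def summary_row(self) -> dict:
        return {
            "factor": self.factor + 1,
            "stratum": self.stratum,
            "visit": self.visit,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "p": self.p,
        }


@dataclass
class TestResult:
    __test__ = False  # not a pytest class, despite the name

    statistic: float
    df: int
    p: float
    alpha: float = 0.05

    @property
    def reject(self) -> bool:
        return self.p < self.alpha


def wald_test(estimate: float, se: float) -> tuple[float, float]:
    """Two-sided Wald z-statistic and p-value."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = estimate / se
    return z, 2.0 * scipy.stats.norm.sf(abs(z))


def _contrast(
    fit_layout, spec: ModelSpec, q: int, m: str, j: int, times: np.ndarray
) -> tuple[np.ndarray, list[int]]:
    """Contrast c = x_qij(1) - x_qij(0) over stratum m's free betas, plus the
    global layout indices of those betas."""
    if j < 0 or j >= len(times):
        raise ValueError(f"visit {j} outside schedule of {len(times)} visits")
    t = np.asarray([times[j]], dtype=float)
    terms = active_fixed_terms(spec, q, m)
    c = np.zeros(len(terms))
    for i, term in enumerate(terms):
        x1 = _eval_term(term, t, receipt_under(m, 1))[0]
        x0 = _eval_term(term, t, receipt_under(m, 0))[0]
        c[i] = x1 - x0
    idx = [fit_layout.beta_offset(m, q, term) for term in terms]
    return c, idx


def pce(
    fit: FitResult, spec: ModelSpec, q: int, m: str, j: int, times=None
) -> EstimandReport:
    """Principal causal effect on factor q at visit j within stratum m."""
    times = np.asarray(times if times is not None else np.arange(spec.n_visits), float)
    c, idx = _contrast(fit.layout, spec, q, m, j, times)
    beta_full = fit.layout.to_original(fit.params_hat)
    est = float(c @ beta_full[idx])
    if np.allclose(c, 0.0):
        # no treatment column moves (never-takers, or baseline visit)
        return EstimandReport(q, m, j, 0.0, 0.0, 0.0, 1.0, (0.0, 0.0))
    if fit.vcov is None:
        raise ValueError("fit carries no covariance; rerun with compute_vcov=True")
    V = fit.vcov[np.ix_(idx, idx)]
    se = float(np.sqrt(max(c @ V @ c, 0.0)))
    if se == 0.0:
        z, p = (0.0, 1.0) if est == 0.0 else (np.inf, 0.0)
    else:
        z, p = wald_test(est, se)
    ci = (est - _Z95 * se, est + _Z95 * se)
    return EstimandReport(q, m, j, est, se, z, p, ci)


def cace(fit: FitResult, spec: ModelSpec, q: int, j: int, times=None) -> EstimandReport:
    """Complier average causal effect: the complier-stratum PCE."""
    rep = pce(fit, spec, q, COMPLIER, j, times)
    rep.label = spec.factor_names[q]
    return rep


def global_lrt(
    fit_full: FitResult,
    fit_null: FitResult,
    constrained,
    alpha: float = 0.05,
) -> TestResult:
    """Single global likelihood-ratio test of the nested null model.

    ``constrained`` is the list of constrained parameter names (or an
    integer count).  A materially negative deviance signals an
    optimization failure upstream and raises; tiny negatives from
    optimizer tolerance are clipped to zero.
    """
    df = constrained if isinstance(constrained, int) else len(constrained)
    stat = 2.0 * (fit_full.loglik - fit_null.loglik)
    if stat < -1e-6:
        raise RuntimeError(
            f"null log-likelihood exceeds full ({fit_null.loglik:.6f} > "
            f"{fit_full.loglik:.6f}); refit the full model"
        )
    stat = max(stat, 0.0)
    p = float(scipy.stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return TestResult(statistic=stat, df=df, p=p, alpha=alpha)


def compare_models(fits: list[FitResult], labels=None) -> pd.DataFrame:
    """AIC-ranked comparison table for candidate factor structures.

    Ties on AIC break by BIC, then by fewer free parameters.  Fits must be
    on the same data (checked by subject count).
    """
    if labels is None:
        labels = [f.label or f"model_{i + 1}" for i, f in enumerate(fits)]
    ns = {f.n_subjects for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits are on different datasets (subject counts {sorted(ns)})")
    rows = [
        {
            "model": lab,
            "logL": f.loglik,
            "n_free": f.n_free,
            "AIC": f.aic,
            "BIC": f.bic,
        }
        for lab, f in zip(labels, fits)
    ]
    table = pd.DataFrame(rows).sort_values(
        ["AIC", "BIC", "n_free"], kind="mergesort", ignore_index=True
    )
    return table
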