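"""Delimited-text I/O for trial data, model configs and fit results.

Data travel as two CSV files: a long-format outcomes table (one row per
subject-visit, columns ``id, arm, receipt, visit, time, y1..yK``, empty
cells for missing outcomes) and a one-row-per-subject baseline covariate
table (``id`` plus named columns; the intercept is implicit).  Model
configuration and serialized fit results use YAML.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .estimation import FitResult
from .model_spec import ModelSpec, TrialData
from .simulator import SimConfig, _spec_from_dict

__all__ = [
    "write_trial_data",
    "read_trial_data",
    "read_model_config",
    "write_fit_result",
    "fit_report",
]


def write_trial_data(data: TrialData, outcomes_path, covariates_path=None) -> None:
    n, j1, k = data.outcomes.shape
    names = list(data.outcome_names) or [f"y{i + 1}" for i in range(k)]
    rows = []
    for i in range(n):
        for j in range(j1):
            row = {
                "id": data.subject_ids[i],
                "arm": data.arm[i],
                "receipt": data.receipt[i],
                "visit": j,
                "time": data.times[j],
            }
            for c, nm in enumerate(names):
                v = data.outcomes[i, j, c]
                row[nm] = v if np.isfinite(v) else None
            rows.append(row)
    pd.DataFrame(rows).to_csv(outcomes_path, index=False)
    if covariates_path is not None:
        cov = pd.DataFrame(
            data.covariates[:, 1:], columns=list(data.covariate_names)
        )
        cov.insert(0, "id", data.subject_ids)
        cov.to_csv(covariates_path, index=False)


def read_trial_data(
    outcomes_path, covariates_path=None, outcome_columns=None
) -> TrialData:
    df = pd.read_csv(outcomes_path)
    required = {"id", "arm", "receipt", "visit", "time"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"outcomes file lacks columns {sorted(missing)}")
    ycols = outcome_columns or [c for c in df.columns if c not in required]
    df = df.sort_values(["id", "visit"], kind="mergesort")
    ids = df["id"].unique()
    visits = np.sort(df["visit"].unique())
    n, j1, k = len(ids), len(visits), len(ycols)
    outcomes = np.full((n, j1, k), np.nan)
    arm = np.zeros(n, dtype=int)
    receipt = np.zeros(n, dtype=int)
    id_pos = {v: i for i, v in enumerate(ids)}
    visit_pos = {v: j for j, v in enumerate(visits)}
    times = np.zeros(j1)
    for _, row in df.iterrows():
        i, j = id_pos[row["id"]], visit_pos[row["visit"]]
        arm[i] = int(row["arm"])
        receipt[i] = int(row["receipt"]) if np.isfinite(row["receipt"]) else 0
        times[j] = float(row["time"])
        outcomes[i, j, :] = [row[c] for c in ycols]
    if covariates_path is not None:
        cov_df = pd.read_csv(covariates_path).set_index("id").loc[ids]
        names = tuple(cov_df.columns)
        W = np.column_stack([np.ones(n), cov_df.to_numpy(dtype=float)])
    else:
        names = ()
        W = np.ones((n, 1))
    return TrialData(
        arm=arm,
        receipt=receipt,
        outcomes=outcomes,
        times=times,
        covariates=W,
        covariate_names=names,
        outcome_names=tuple(ycols),
        subject_ids=ids,
    )


def read_model_config(path) -> ModelSpec:
    """ModelSpec from a YAML config (same schema as scenario files)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return _spec_from_dict(d)


def write_fit_result(fit: FitResult, path) -> None:
    table = fit.param_table()
    payload = {
        "label": fit.label,
        "loglik": float(fit.loglik),
        "n_free": int(fit.n_free),
        "n_subjects": int(fit.n_subjects),
        "aic": float(fit.aic),
        "bic": float(fit.bic),
        "converged": bool(fit.converged),
        "grad_norm": float(fit.grad_norm),
        "boundary_params": list(fit.boundary_params),
        "vcov_flags": list(fit.vcov_flags),
        "parameters": [
            {
                "name": str(r.parameter),
                "estimate": float(r.estimate),
                "se": None if not np.isfinite(r.se) else float(r.se),
            }
            for r in table.itertuples()
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def fit_report(fit: FitResult, spec: ModelSpec, times=None) -> str:
    """Human-readable summary: fit block, treatment effects, factor CACEs."""
    from .estimands import cace
    from .model_spec import COMPLIER, is_d_term

    lines = [
        f"Latent-factor MCACE fit{': ' + fit.label if fit.label else ''}",
        f"  subjects {fit.n_subjects}   free parameters {fit.n_free}",
        f"  logL {fit.loglik:.3f}   AIC {fit.aic:.2f}   BIC {fit.bic:.2f}",
        "",
        "Treatment-effect coefficients (compliers)",
        f"  {'parameter':<34}{'estimate':>10}{'se':>9}{'95% CI':>22}{'p':>8}",
    ]
    est = fit.layout.to_original(fit.params_hat)
    z = 1.959963984540054
    import scipy.stats

    for q in range(spec.Q):
        for term in fit.layout.beta_terms[COMPLIER][q]:
            if not is_d_term(term):
                continue
            i = fit.layout.beta_offset(COMPLIER, q, term)
            e = est[i]
            if fit.vcov is not None:
                s = float(np.sqrt(max(fit.vcov[i, i], 0.0)))
                p = 2.0 * scipy.stats.norm.sf(abs(e / s)) if s > 0 else np.nan
                ci = f"({e - z * s:.3f}, {e + z * s:.3f})"
                lines.append(
                    f"  {fit.layout.names[i]:<34}{e:>10.3f}{s:>9.3f}{ci:>22}{p:>8.3f}"
                )
            else:
                lines.append(f"  {fit.layout.names[i]:<34}{e:>10.3f}")
    if fit.vcov is not None:
        lines += ["", "Factor CACEs at the final visit"]
        j = spec.n_visits - 1
        for q in range(spec.Q):
            rep = cace(fit, spec, q, j, times=times)
            lines.append(
                f"  {spec.factor_names[q]:<24}{rep.estimate:>10.3f}{rep.se:>9.3f}"
                f"   p = {rep.p:.3f}"
            )
    return "\n".join(lines)
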