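"""Agreement between estimated and reference quality scores.

Reports MAE, the SD and IQR of the absolute error, Spearman's rho, an
ordinary least-squares fit of eQS on rQS with a pointwise 95% prediction
interval (cases outside it are flagged as outliers), and the Bland-Altman
mean difference. Estimated scores are expected to be clamped to [0, 100]
before evaluation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EvaluationReport", "evaluate", "subgroup_report"]


@dataclass(frozen=True)
class EvaluationReport:
    n: int
    mae: float
    sd_abs_error: float
    iqr_abs_error: float
    spearman_rho: float
    spearman_p: float
    fit_slope: float
    fit_intercept: float
    residual_sd: float
    t_crit: float
    mean_difference: float
    outlier_ids: tuple = ()

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _prediction_interval(x, y, level=0.95):
    """OLS of y on x with the standard pointwise prediction-interval band."""
    n = len(x)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    dof = n - 2
    s = float(np.sqrt((resid**2).sum() / dof)) if dof > 0 else 0.0
    t = float(stats.t.ppf(0.5 + level / 2, dof)) if dof > 0 else float("inf")
    xbar = x.mean()
    sxx = ((x - xbar) ** 2).sum()
    half = t * s * np.sqrt(1.0 + 1.0 / n + (x - xbar) ** 2 / max(sxx, 1e-300))
    lower = slope * x + intercept - half
    upper = slope * x + intercept + half
    return slope, intercept, s, t, lower, upper


def evaluate(eqs, rqs, ids=None) -> EvaluationReport:
    """Full agreement report between estimated and reference scores."""
    e = np.asarray(eqs, dtype=float)
    r = np.asarray(rqs, dtype=float)
    if len(e) != len(r):
        raise ValueError("eqs and rqs differ in length")
    n = len(e)
    if n < 3:
        raise ValueError("evaluation needs at least 3 cases")
    if ids is None:
        ids = list(range(n))
    abs_err = np.abs(e - r)
    q1, q3 = np.percentile(abs_err, [25, 75])
    if np.std(e) == 0 or np.std(r) == 0:
        rho, p = (1.0, 0.0) if np.allclose(e, r) else (0.0, 1.0)
    else:
        rho, p = stats.spearmanr(e, r)
    slope, intercept, s, t, lower, upper = _prediction_interval(r, e)
    outliers = tuple(i for i, (v, lo, hi) in zip(ids, zip(e, lower, upper)) if v < lo or v > hi)
    return EvaluationReport(
        n=n,
        mae=float(abs_err.mean()),
        sd_abs_error=float(abs_err.std(ddof=1)),
        iqr_abs_error=float(q3 - q1),
        spearman_rho=float(rho),
        spearman_p=float(p),
        fit_slope=float(slope),
        fit_intercept=float(intercept),
        residual_sd=s,
        t_crit=t,
        mean_difference=float((e - r).mean()),
        outlier_ids=outliers,
    )


def subgroup_report(
    table: pd.DataFrame,
    eqs_col: str = "eqs",
    rqs_col: str = "rqs",
    id_col: str = "case_id",
    group_cols: tuple[str, ...] = ("dataset", "method"),
) -> dict:
    """Per-(dataset, method) reports plus the pooled report.

    Combinations with fewer than 3 cases are skipped with a warning.
    Returns a dict keyed by the group tuple, with key ``"pooled"`` for the
    overall report.
    """
    for col in (eqs_col, rqs_col, *group_cols):
        if col not in table:
            raise ValueError(f"missing column {col!r}")
    out: dict = {}
    ids = table[id_col] if id_col in table else table.index
    out["pooled"] = evaluate(table[eqs_col], table[rqs_col], list(ids))
    for key, sub in table.groupby(list(group_cols), sort=True):
        if len(sub) < 3:
            warnings.warn(f"subgroup {key} has n={len(sub)} < 3; skipped", stacklevel=2)
            continue
        sub_ids = sub[id_col] if id_col in sub else sub.index
        out[key] = evaluate(sub[eqs_col], sub[rqs_col], list(sub_ids))
    return out
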