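"""Kaplan-Meier curves, log-rank testing and Cox proportional-hazards fits.

The Cox engine maximizes the Breslow partial likelihood by Newton
iteration (statsmodels ``PHReg``) and reports hazard ratios with 95% Wald
intervals; univariate and multivariate fits share the same engine.
Kaplan-Meier and the two-group log-rank test come from lifelines.
Categorical covariates enter as treatment-coded indicators with the
first level (alphabetically) as reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.duration.hazard_regression import PHReg

TIME_COL = "time_months"
EVENT_COL = "event"

#: |log HR| beyond which a monotone-likelihood (separation) warning is raised
SEPARATION_LOG_HR = 10.0


class ConvergenceError(RuntimeError):
    pass


@dataclass
class KMCurve:
    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


def km_curve(records: pd.DataFrame, group_by: str = "group",
             time_col: str = TIME_COL, event_col: str = EVENT_COL) -> dict[str, KMCurve]:
    """Product-limit survival estimate per group."""
    curves = {}
    for name, sub in records.groupby(group_by):
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col], label=str(name))
        times = kmf.survival_function_.index.to_numpy(float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(float)
        at_risk = kmf.event_table["at_risk"].to_numpy(float)
        curves[str(name)] = KMCurve(group=str(name), times=times,
                                    survival=surv, at_risk=at_risk)
    return curves


def logrank(records: pd.DataFrame, group_by: str = "group",
            time_col: str = TIME_COL, event_col: str = EVENT_COL) -> dict:
    """Two-group log-rank test (1-df chi-square)."""
    groups = sorted(records[group_by].unique())
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(groups)}")
    if records[event_col].sum() < 1:
        raise ValueError("log-rank needs at least one event")
    a = records[records[group_by] == groups[0]]
    b = records[records[group_by] == groups[1]]
    res = logrank_test(a[time_col], b[time_col], a[event_col], b[event_col])
    return {"chi_square": float(res.test_statistic), "p": float(res.p_value)}


def _design_matrix(records: pd.DataFrame, covariate_names: list[str]) -> pd.DataFrame:
    cols = {}
    for name in covariate_names:
        col = records[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                raise ValueError(f"covariate {name!r} is constant")
            for lev in levels[1:]:  # first level is the reference
                cols[f"{name}[{lev}]"] = (col.astype(str) == lev).astype(float)
        else:
            if col.nunique() < 2:
                raise ValueError(f"covariate {name!r} is constant")
            cols[name] = col.astype(float)
    return pd.DataFrame(cols, index=records.index)


def cox_fit(records: pd.DataFrame, covariate_names: list[str],
            time_col: str = TIME_COL, event_col: str = EVENT_COL) -> pd.DataFrame:
    """Cox proportional-hazards fit (Breslow ties, Newton iteration).

    Returns one row per design column: hazard_ratio, ci_low, ci_high
    (95% Wald), p_value, n, n_events.  A |log HR| above
    ``SEPARATION_LOG_HR`` triggers a monotone-likelihood warning and the
    estimate is reported as fitted (clamped by the optimizer's stopping
    rule rather than diverging).
    """
    if records[event_col].sum() < 1:
        raise ValueError("need at least one event")
    X = _design_matrix(records, covariate_names)
    model = PHReg(records[time_col].to_numpy(float), X.to_numpy(float),
                  status=records[event_col].to_numpy(int), ties="breslow")
    try:
        res = model.fit(maxiter=100, disp=False)
    except Exception as exc:  # pragma: no cover - statsmodels raises rarely
        raise ConvergenceError(str(exc)) from exc
    if not np.all(np.isfinite(res.params)):
        raise ConvergenceError("non-finite coefficients after 100 iterations")
    if np.any(np.abs(res.params) > SEPARATION_LOG_HR):
        warnings.warn("monotone partial likelihood (perfect separation); "
                      "hazard ratio estimate is unstable")
    z = 1.959963984540054
    out = pd.DataFrame({
        "covariate": X.columns,
        "hazard_ratio": np.exp(res.params),
        "ci_low": np.exp(res.params - z * res.bse),
        "ci_high": np.exp(res.params + z * res.bse),
        "p_value": res.pvalues,
        "n": len(records),
        "n_events": int(records[event_col].sum()),
    }).set_index("covariate")
    return out


def cox_score_test(records: pd.DataFrame, covariate: str,
                   time_col: str = TIME_COL, event_col: str = EVENT_COL) -> dict:
    """Score test of beta = 0 for a single covariate (asymptotically the
    log-rank test for a binary group indicator)."""
    from scipy.stats import chi2

    X = _design_matrix(records, [covariate])
    model = PHReg(records[time_col].to_numpy(float), X.to_numpy(float),
                  status=records[event_col].to_numpy(int), ties="breslow")
    beta0 = np.zeros(X.shape[1])
    u = model.score(beta0)
    info = -model.hessian(beta0)
    stat = float(u @ np.linalg.solve(info, u))
    return {"chi_square": stat, "p": float(chi2.sf(stat, df=X.shape[1]))}
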