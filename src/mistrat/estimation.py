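"""Target analysis and pooling.

The analysis model is the no-interaction outcome regression

    E[Y | X, C] = t0 + t1*X + t2*C1 + t3*C2 + t4*C3 + t5*C4 + t6*C5

whose exposure coefficient ``t1`` equals the average causal effect under
exchangeability, consistency, positivity and no effect modification. The
auxiliary variable ``A`` never enters the analysis model. Multiply-imputed
fits are pooled with Rubin's rules, with Barnard-Rubin small-sample degrees
of freedom by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, PoolingError

__all__ = [
    "ANALYSIS_PREDICTORS",
    "OLSFit",
    "EstimateRecord",
    "fit_outcome_regression",
    "cca_estimate",
    "pool_rubin",
    "apply_method",
]

#: Right-hand side of the analysis model, in design order (after the intercept).
ANALYSIS_PREDICTORS = ("X", "C1", "C2", "C3", "C4", "C5")
_N_PARAMS = len(ANALYSIS_PREDICTORS) + 1


@dataclass(frozen=True)
class OLSFit:
    params: pd.Series
    cov: pd.DataFrame
    df_resid: int
    sigma2: float
    nobs: int


@dataclass
class EstimateRecord:
    """Per-replicate, per-method estimate of the exposure coefficient."""

    method_label: str
    theta1_hat: float
    se: float
    df: float
    ci_low: float
    ci_high: float
    n_complete_cases: Optional[int] = None
    m_used: Optional[int] = None
    replicate: Optional[int] = None
    scenario: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ci_low < self.ci_high):
            raise EstimationError("confidence interval must have ci_low < ci_high")
        if not self.se > 0:
            raise EstimationError("standard error must be positive")
        if not self.df > 0:
            raise EstimationError("degrees of freedom must be positive")


def _ols_arrays(design: np.ndarray, y: np.ndarray):
    """Normal-equations OLS; returns (beta, cov, df_resid, sigma2)."""
    n, p = design.shape
    xtx = design.T @ design
    xty = design.T @ y
    try:
        chol = np.linalg.cholesky(xtx)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("singular analysis design (collinear columns)") from exc
    beta = np.linalg.solve(xtx, xty)
    resid = y - design @ beta
    df_resid = n - p
    if df_resid <= 0:
        raise EstimationError(f"need more than {p} records, got {n}")
    sigma2 = float(resid @ resid) / df_resid
    # (X'X)^{-1} via the Cholesky factor
    inv_chol = np.linalg.solve(chol, np.eye(p))
    xtx_inv = inv_chol.T @ inv_chol
    return beta, sigma2 * xtx_inv, df_resid, sigma2


def _analysis_design(frame_or_arrays) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(frame_or_arrays, pd.DataFrame):
        y = frame_or_arrays["Y"].to_numpy(dtype=np.float64)
        cols = [frame_or_arrays[v].to_numpy(dtype=np.float64) for v in ANALYSIS_PREDICTORS]
        design = np.column_stack([np.ones(len(y))] + cols)
        return design, y
    raise TypeError("expected a DataFrame with analysis columns")


def fit_outcome_regression(data: pd.DataFrame) -> OLSFit:
    """OLS of Y on (1, X, C1..C5); model-based covariance; df = n - 7."""
    if data[["Y", *ANALYSIS_PREDICTORS]].isna().any().any():
        raise EstimationError("analysis data contain missing values")
    design, y = _analysis_design(data)
    beta, cov, df_resid, sigma2 = _ols_arrays(design, y)
    names = ["const", *ANALYSIS_PREDICTORS]
    return OLSFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        df_resid=df_resid,
        sigma2=sigma2,
        nobs=len(y),
    )


def _theta1_from_matrix(matrix: np.ndarray, col: dict) -> tuple[float, float, int]:
    """Fast path: (theta1_hat, se, df_resid) from an (n x 8) column matrix."""
    n = matrix.shape[0]
    design = np.empty((n, _N_PARAMS))
    design[:, 0] = 1.0
    for j, v in enumerate(ANALYSIS_PREDICTORS, start=1):
        design[:, j] = matrix[:, col[v]]
    beta, cov, df_resid, _ = _ols_arrays(design, matrix[:, col["Y"]])
    return float(beta[1]), float(np.sqrt(cov[1, 1])), df_resid


def _t_interval(est: float, se: float, df: float) -> tuple[float, float]:
    half = stats.t.ppf(0.975, df) * se
    return est - half, est + half


def cca_estimate(data, replicate: Optional[int] = None, scenario: Optional[dict] = None) -> EstimateRecord:
    """Complete-case analysis: drop any record with a masked analysis variable."""
    keep = ~data.mask_any
    n_complete = int(keep.sum())
    if n_complete < _N_PARAMS + 1:
        raise EstimationError(f"too few complete cases for CCA ({n_complete})")
    theta1, se, df_resid = _theta1_from_matrix(data.true_values[keep], data.column_index)
    lo, hi = _t_interval(theta1, se, df_resid)
    return EstimateRecord(
        method_label="CCA",
        theta1_hat=theta1,
        se=se,
        df=float(df_resid),
        ci_low=lo,
        ci_high=hi,
        n_complete_cases=n_complete,
        replicate=replicate,
        scenario=dict(scenario or {}),
    )


def pool_rubin(
    estimates: Sequence[float],
    standard_errors: Sequence[float],
    df_complete: Optional[int] = None,
    df_method: str = "barnard-rubin",
) -> tuple[float, float, float]:
    """Rubin's rules: returns (pooled estimate, pooled SE, reference-t df).

    Total variance T = W + (1 + 1/m) B with W the mean squared standard error
    and B the between-imputation sample variance. ``df_method`` selects the
    Barnard-Rubin small-sample degrees of freedom (requires ``df_complete``)
    or Rubin's classical large-sample formula ("rubin").
    """
    q = np.asarray(estimates, dtype=np.float64)
    u = np.asarray(standard_errors, dtype=np.float64) ** 2
    m = q.size
    if m < 2 or u.size != m:
        raise PoolingError("pooling requires m >= 2 matched (estimate, se) pairs")
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    t_var = w + (1.0 + 1.0 / m) * b
    if t_var <= 0:
        raise PoolingError("non-positive total variance")
    lam = (1.0 + 1.0 / m) * b / t_var
    lam_sq = lam * lam
    if df_method == "rubin":
        df = (m - 1) / lam_sq if lam_sq > 0 else np.inf
    elif df_method == "barnard-rubin":
        if df_complete is None:
            raise PoolingError("Barnard-Rubin df requires df_complete")
        df_obs = (df_complete + 1.0) / (df_complete + 3.0) * df_complete * (1.0 - lam)
        if lam_sq > 0:
            df_old = (m - 1) / lam_sq
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_obs
    else:
        raise PoolingError(f"unknown df_method {df_method!r}")
    df = min(df, 1e12)  # finite df so the t quantile is always defined
    return qbar, float(np.sqrt(t_var)), float(df)


def apply_method(
    data,
    spec,
    seed,
    replicate: Optional[int] = None,
    scenario: Optional[dict] = None,
    df_method: str = "barnard-rubin",
) -> EstimateRecord:
    """Dispatch one missing-data method on one incomplete dataset.

    CCA goes straight to :func:`cca_estimate`; every MI variant runs the
    chained-equations engine, fits the analysis model on each completed
    dataset, and pools with Rubin's rules.
    """
    if spec.method_label == "CCA":
        return cca_estimate(data, replicate=replicate, scenario=scenario)
    from .fcs_imputer import impute_fcs

    stack = impute_fcs(data, spec, seed)
    col = data.column_index
    fits = [_theta1_from_matrix(mat, col) for mat in stack.arrays]
    thetas = [f[0] for f in fits]
    ses = [f[1] for f in fits]
    df_complete = data.n - _N_PARAMS
    qbar, se, df = pool_rubin(thetas, ses, df_complete=df_complete, df_method=df_method)
    lo, hi = _t_interval(qbar, se, df)
    return EstimateRecord(
        method_label=spec.method_label,
        theta1_hat=qbar,
        se=se,
        df=df,
        ci_low=lo,
        ci_high=hi,
        m_used=len(stack.arrays),
        replicate=replicate,
        scenario=dict(scenario or {}),
    )
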