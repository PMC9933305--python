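"""Monte-Carlo performance indicators for the simulation study.

For each (scenario x method) cell the summary reports the mean estimate,
bias (absolute and relative to the true effect), mean squared error,
empirical and average model-based standard errors, and the empirical
coverage of nominal 95% confidence intervals, each with its Monte-Carlo
standard error where the indicator has one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SummaryError

__all__ = ["PerformanceSummary", "summarize", "summarize_frame", "TRUE_THETA1"]

#: Design value of the target estimand in every scenario.
TRUE_THETA1 = 0.3


@dataclass
class PerformanceSummary:
    method_label: str
    n_sim: int
    mean_estimate: float
    mcse_mean: float
    bias: float
    relative_bias: float
    mse: float
    emp_se: float
    mcse_emp_se: float
    mod_se: float
    coverage: float
    mcse_coverage: float
    n_failures: int = 0
    scenario: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = asdict(self)
        row.update(row.pop("scenario"))
        return row


def summarize(
    records: Sequence,
    true_theta1: float = TRUE_THETA1,
    n_failures: int = 0,
    scenario: dict | None = None,
) -> PerformanceSummary:
    """Performance indicators for one (scenario x method) cell.

    Bias is mean estimate minus the true effect; MSE is squared bias plus
    the sample variance of the estimates; EmpSE is the sample SD; ModSE is
    the average model-based SE; coverage is the percentage of 95% intervals
    containing the true effect. MCSEs: EmpSE/sqrt(n) for the mean,
    EmpSE/sqrt(2(n-1)) for EmpSE, sqrt(p(1-p)/n) for coverage.
    """
    if len(records) < 2:
        raise SummaryError("need at least 2 replicate records to summarise")
    labels = {r.method_label for r in records}
    if len(labels) != 1:
        raise SummaryError(f"records mix methods: {sorted(labels)}")
    est = np.array([r.theta1_hat for r in records])
    ses = np.array([r.se for r in records])
    covered = np.array([r.ci_low <= true_theta1 <= r.ci_high for r in records])
    n = est.size
    mean = float(est.mean())
    var = float(est.var(ddof=1))
    emp_se = float(np.sqrt(var))
    bias = mean - true_theta1
    p_cov = float(covered.mean())
    return PerformanceSummary(
        method_label=labels.pop(),
        n_sim=n,
        mean_estimate=mean,
        mcse_mean=emp_se / np.sqrt(n),
        bias=bias,
        relative_bias=100.0 * bias / true_theta1,
        mse=bias**2 + var,
        emp_se=emp_se,
        mcse_emp_se=emp_se / np.sqrt(2.0 * (n - 1)),
        mod_se=float(ses.mean()),
        coverage=100.0 * p_cov,
        mcse_coverage=100.0 * float(np.sqrt(p_cov * (1.0 - p_cov) / n)),
        n_failures=n_failures,
        scenario=dict(scenario or {}),
    )


def summarize_frame(
    records: pd.DataFrame,
    true_theta1: float = TRUE_THETA1,
    group_cols: Sequence[str] = ("method",),
) -> pd.DataFrame:
    """Summarise a long-format per-replicate estimates table.

    Expects columns ``method``, ``estimate``, ``se``, ``ci_low``, ``ci_high``
    plus any scenario identifier columns named in ``group_cols``.
    """
    rows = []
    for key, grp in records.groupby(list(group_cols), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        est = grp["estimate"].to_numpy()
        n = est.size
        if n < 2:
            raise SummaryError(f"cell {key} has fewer than 2 records")
        mean = est.mean()
        var = est.var(ddof=1)
        emp_se = np.sqrt(var)
        bias = mean - true_theta1
        p_cov = ((grp["ci_low"] <= true_theta1) & (true_theta1 <= grp["ci_high"])).mean()
        rows.append(
            dict(zip(group_cols, key))
            | {
                "n_sim": n,
                "mean_estimate": mean,
                "mcse_mean": emp_se / np.sqrt(n),
                "bias": bias,
                "relative_bias": 100.0 * bias / true_theta1,
                "mse": bias**2 + var,
                "emp_se": emp_se,
                "mcse_emp_se": emp_se / np.sqrt(2.0 * (n - 1)),
                "mod_se": grp["se"].mean(),
                "coverage": 100.0 * p_cov,
                "mcse_coverage": 100.0 * np.sqrt(p_cov * (1 - p_cov) / n),
            }
        )
    return pd.DataFrame(rows)
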