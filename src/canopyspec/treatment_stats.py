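"""Quadratic treatment-response regression.

For each cultivar and canopy metric, ordinary least squares of the metric
on (1, treatment, treatment^2):

    y = b0 + b1 * x + b2 * x^2 + error

summarized by R^2 = 1 - SSE/SST and the overall F-test p-value

    F = ((SST - SSE)/2) / (SSE/(n - 3))  ~  F(2, n - 3)  under the null,

the probability of no effect of the treatment on the metric.  Per-
coefficient t-test p-values are carried as supplementary fields only.
Group summaries report mean +/- standard error (sample SD / sqrt(n)) per
treatment level, the error bar used for replicate means.

The quadratic degree is fixed: it captures a monotone response with
saturation as well as an interior optimum, and keeps one p-value per
(cultivar, metric).  Fits never pool across cultivars.  No multiple-
testing correction is applied by default; Benjamini-Hochberg across
metrics is available for users who want it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InsufficientDataError, RankDeficiencyError

RESPONSE_COLUMNS = ("cultivar", "treatment", "replicate", "metric_name", "value")


def make_response_table(rows) -> pd.DataFrame:
    """Build and validate a long-format response table.

    ``rows`` is an iterable of (cultivar, treatment, replicate,
    metric_name, value) tuples or an equivalently keyed DataFrame.
    Treatments and values must be finite.
    """
    if isinstance(rows, pd.DataFrame):
        table = rows.copy()
    else:
        table = pd.DataFrame(list(rows), columns=RESPONSE_COLUMNS)
    missing = [c for c in RESPONSE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"response table is missing columns {missing}")
    for col in ("treatment", "value"):
        vals = pd.to_numeric(table[col], errors="coerce")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite entries in column {col!r}")
        table[col] = vals.astype(float)
    return table


@dataclass
class QuadraticFit:
    """OLS quadratic fit of one metric against treatment level."""

    b0: float
    b1: float
    b2: float
    r_squared: float
    p_value: float
    n: int
    metric_name: str = ""
    cultivar: str = ""
    coef_p_values: tuple[float, float, float] | None = field(default=None)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.b0 + self.b1 * x + self.b2 * x**2


def _subset(table: pd.DataFrame, cultivar: str | None, metric_name: str | None) -> pd.DataFrame:
    sub = table
    if cultivar is not None:
        sub = sub[sub["cultivar"] == cultivar]
    if metric_name is not None:
        sub = sub[sub["metric_name"] == metric_name]
    return sub


def fit_quadratic(
    table: pd.DataFrame,
    cultivar: str | None = None,
    metric_name: str | None = None,
) -> QuadraticFit:
    """Fit value ~ 1 + treatment + treatment^2 for one cultivar and metric.

    Requires at least 4 observations (3 parameters + 1 residual df) and at
    least 3 distinct treatment levels, else the quadratic is not
    identifiable.

    Raises
    ------
    InsufficientDataError
        Fewer than 4 observations.
    RankDeficiencyError
        Fewer than 3 distinct treatment levels.
    """
    sub = _subset(table, cultivar, metric_name)
    x = sub["treatment"].to_numpy(dtype=float)
    y = sub["value"].to_numpy(dtype=float)
    n = len(y)
    if n < 4:
        raise InsufficientDataError(
            f"quadratic fit needs >= 4 observations, got {n}"
        )
    if len(np.unique(x)) < 3:
        raise RankDeficiencyError(
            "quadratic fit needs >= 3 distinct treatment levels, got "
            f"{len(np.unique(x))}"
        )
    design = sm.add_constant(np.column_stack([x, x**2]))
    result = sm.OLS(y, design).fit()
    b0, b1, b2 = (float(c) for c in result.params)
    # A perfect fit has SSE ~ 0; statsmodels reports f_pvalue = nan there.
    p = float(result.f_pvalue)
    if np.isnan(p):
        p = 0.0 if result.rsquared > 1.0 - 1e-12 else 1.0
    return QuadraticFit(
        b0=b0,
        b1=b1,
        b2=b2,
        r_squared=float(result.rsquared),
        p_value=min(max(p, np.nextafter(0.0, 1.0)), 1.0),
        n=n,
        metric_name=metric_name or "",
        cultivar=cultivar or "",
        coef_p_values=tuple(float(pv) for pv in result.pvalues),
    )


def group_means(
    table: pd.DataFrame,
    cultivar: str | None = None,
    metric_name: str | None = None,
) -> pd.DataFrame:
    """Per-treatment mean, standard error of the mean, and replicate count.

    SEM = sample SD (ddof=1) / sqrt(n); undefined (NaN) when n = 1.
    Returns a DataFrame with columns treatment, mean, sem, n, sorted by
    treatment level.
    """
    sub = _subset(table, cultivar, metric_name)
    rows = []
    for level, grp in sub.groupby("treatment"):
        vals = grp["value"].to_numpy(dtype=float)
        n = len(vals)
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append({"treatment": float(level), "mean": float(vals.mean()), "sem": sem, "n": n})
    return pd.DataFrame(rows, columns=["treatment", "mean", "sem", "n"]).sort_values(
        "treatment", ignore_index=True
    )


def fit_all(table: pd.DataFrame, adjust: bool = False) -> pd.DataFrame:
    """Quadratic fit for every (cultivar, metric) pair in the table.

    With ``adjust=True``, Benjamini-Hochberg adjusted p-values across
    metrics are appended as ``p_adj`` (off by default).
    """
    records = []
    for (cultivar, metric), _grp in table.groupby(["cultivar", "metric_name"]):
        fit = fit_quadratic(table, cultivar=cultivar, metric_name=metric)
        records.append(
            {
                "cultivar": cultivar,
                "metric_name": metric,
                "b0": fit.b0,
                "b1": fit.b1,
                "b2": fit.b2,
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
                "n": fit.n,
                "p_b0": fit.coef_p_values[0],
                "p_b1": fit.coef_p_values[1],
                "p_b2": fit.coef_p_values[2],
            }
        )
    out = pd.DataFrame(records)
    if adjust and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
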