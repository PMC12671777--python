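"""Time-window summary statistics and grouped simple linear regression.

Two lightweight analyses over the combined tables:

* :func:`time_window_summary` partitions a time axis into consecutive
  windows of a user-chosen width (anchored at the minimum observed time
  value; the last window may be partial) and reports, per group and
  window, the count of non-missing values, their mean, sample standard
  deviation (n-1 denominator) and coefficient of variation SD/mean.
* :func:`linear_regression` fits ordinary least squares ``y = a + b x``
  per group and reports the slope, intercept, R², and the two-sided
  p-value of the t-test on the slope (df = n - 2) — raw p-values, no
  multiplicity correction.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)


def _check_columns(table: pd.DataFrame, cols) -> None:
    for col in cols:
        if col not in table.columns:
            raise ValidationError(f"unknown column {col!r}")


def _grouped(table: pd.DataFrame, group_vars):
    if group_vars:
        return table.groupby(list(group_vars), sort=True, dropna=False, observed=True)
    return [((), table)]


def time_window_summary(table: pd.DataFrame, value_var: str, time_var: str,
                        width: float, group_vars=()) -> pd.DataFrame:
    """Per-group, per-window n / mean / SD / CV of ``value_var``.

    Windows are ``[t0, t0+width-1], [t0+width, ...]`` where ``t0`` is
    the minimum observed time value over the whole table, so windows
    align across groups; ``window_end`` is clipped to the maximum
    observed time, flagging a partial final window. Missing values are
    excluded from n, mean and SD; CV is missing when the mean is 0 or
    n < 2.

    Returns a DataFrame with the group columns followed by
    ``window_start, window_end, n, mean, sd, cv``.
    """
    if width <= 0:
        raise ValidationError(f"width must be >= 1, got {width}")
    group_vars = list(group_vars)
    _check_columns(table, [value_var, time_var] + group_vars)
    times = pd.to_numeric(table[time_var], errors="raise")
    valid_time = times.notna()
    if not valid_time.any():
        raise ValidationError(f"no observed values in time column {time_var!r}")
    t0 = float(times[valid_time].min())
    t_max = float(times[valid_time].max())
    n_windows = int(math.floor((t_max - t0) / width)) + 1

    rows = []
    for labels, sub in _grouped(table.loc[valid_time], group_vars):
        sub_times = pd.to_numeric(sub[time_var])
        values = pd.to_numeric(sub[value_var], errors="coerce")
        idx = np.floor((sub_times - t0) / width).astype(int)
        for w in range(n_windows):
            start = t0 + w * width
            end = min(start + width - 1, t_max)
            v = values[idx == w].dropna()
            n = int(v.size)
            mean = float(v.mean()) if n else float("nan")
            sd = float(v.std(ddof=1)) if n >= 2 else float("nan")
            cv = sd / mean if n >= 2 and mean != 0 and not math.isnan(sd) else float("nan")
            row = dict(zip(group_vars, labels if isinstance(labels, tuple) else (labels,)))
            row.update({"window_start": start, "window_end": end,
                        "n": n, "mean": mean, "sd": sd, "cv": cv})
            rows.append(row)
    return pd.DataFrame(rows, columns=group_vars + ["window_start", "window_end",
                                                    "n", "mean", "sd", "cv"])


def ols_fit(x: np.ndarray, y: np.ndarray) -> dict:
    """Closed-form simple OLS on paired finite observations.

    Returns slope, intercept, r_squared and the two-sided slope t-test
    p-value (df = n-2). Degenerate cases yield NaN fields: zero x
    variance (no slope), constant y (R² is 0/0), n < 2 (nothing to
    fit), n < 3 (no residual degrees of freedom for the test).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    out = {"n": n, "slope": np.nan, "intercept": np.nan,
           "r_squared": np.nan, "p_value": np.nan}
    if n < 2:
        return out
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    syy = float(((y - ybar) ** 2).sum())
    sxy = float(((x - xbar) * (y - ybar)).sum())
    if sxx == 0.0:
        logger.warning("degenerate regressor: zero variance in x (n=%d)", n)
        return out
    slope = sxy / sxx
    out["slope"] = slope
    out["intercept"] = ybar - slope * xbar
    if syy > 0.0:
        out["r_squared"] = sxy * sxy / (sxx * syy)
    if n >= 3:
        rss = syy - slope * sxy
        rss = max(rss, 0.0)  # guard tiny negative rounding
        se = math.sqrt(rss / (n - 2) / sxx)
        if se > 0.0:
            t = slope / se
            out["p_value"] = 2.0 * stats.t.sf(abs(t), df=n - 2)
        elif slope != 0.0:
            out["p_value"] = 0.0  # exact fit with nonzero slope
    return out


def linear_regression(table: pd.DataFrame, y_var: str, x_var: str,
                      group_vars=()) -> pd.DataFrame:
    """Per-group simple OLS of ``y_var`` on ``x_var``.

    Returns a DataFrame with the group columns followed by
    ``n, slope, intercept, r_squared, p_value``. Groups with a
    degenerate regressor produce a row with missing slope (and a logged
    warning); groups with fewer than 2 points produce missing fields.
    """
    group_vars = list(group_vars)
    _check_columns(table, [y_var, x_var] + group_vars)
    rows = []
    for labels, sub in _grouped(table, group_vars):
        fit = ols_fit(pd.to_numeric(sub[x_var], errors="coerce").to_numpy(),
                      pd.to_numeric(sub[y_var], errors="coerce").to_numpy())
        row = dict(zip(group_vars, labels if isinstance(labels, tuple) else (labels,)))
        row.update(fit)
        rows.append(row)
    return pd.DataFrame(rows, columns=group_vars + ["n", "slope", "intercept",
                                                    "r_squared", "p_value"])
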