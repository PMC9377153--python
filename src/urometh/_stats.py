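"""Shared statistical helpers used across pipeline stages."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats


def round_half_up(x, decimals: int = 1):
    """Round half away from zero (0.75 -> 0.8), independent of platform
    banker's rounding.  Values here are non-negative methylation frequencies.
    """
    factor = 10.0**decimals
    return np.floor(np.asarray(x, dtype=float) * factor + 0.5) / factor


def two_sample_ttest(a, b, equal_var: bool = False) -> float:
    """Two-sided two-sample t-test p-value, robust to zero-variance groups.

    If both groups are constant, the p-value is 1.0 when the means agree and
    0.0 when they differ (the limiting case of vanishing noise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return np.nan
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def rowwise_ttest(x_case: np.ndarray, x_ctrl: np.ndarray, equal_var: bool = False):
    """Vectorized two-sided t-test along rows of two 2-D arrays (NaN-aware).

    Returns (pvalues, delta) where delta = nanmean(case) - nanmean(ctrl).
    Rows with <2 non-missing values in either group get NaN.
    """
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n1 = np.sum(~np.isnan(x_case), axis=1)
        n0 = np.sum(~np.isnan(x_ctrl), axis=1)
        m1 = np.nanmean(np.where(np.isnan(x_case), np.nan, x_case), axis=1)
        m0 = np.nanmean(np.where(np.isnan(x_ctrl), np.nan, x_ctrl), axis=1)
        v1 = np.nanvar(x_case, axis=1, ddof=1)
        v0 = np.nanvar(x_ctrl, axis=1, ddof=1)
        if equal_var:
            df = n1 + n0 - 2.0
            sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / df
            se2 = sp2 * (1.0 / n1 + 1.0 / n0)
        else:
            se2 = v1 / n1 + v0 / n0
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1)
            )
        t = (m1 - m0) / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        # zero-variance rows: p=1 if equal means else p=0
        zero_se = se2 == 0
        p = np.where(zero_se & (m1 == m0), 1.0, p)
        p = np.where(zero_se & (m1 != m0), 0.0, p)
        p = np.where((n1 < 2) | (n0 < 2), np.nan, p)
    return p, m1 - m0
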