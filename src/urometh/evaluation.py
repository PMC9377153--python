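"""Statistical evaluation: exact Fisher test with conditional-MLE odds ratio,
ROC/AUC, Benjamini-Hochberg adjustment, and dilution-series limit of detection.

The Fisher test follows the R ``fisher.test`` convention: the two-sided
p-value sums noncentral-hypergeometric probabilities (at OR = 1) not larger
than the observed table's, the odds ratio is the conditional maximum-likelihood
estimate, and the confidence interval inverts the exact conditional test.
Zero-cell tables yield OR = 0 or +inf with a one-sided interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multitest import multipletests

from ._stats import two_sample_ttest

__all__ = [
    "FisherResult",
    "LoDResult",
    "fisher_exact",
    "roc_auc",
    "benjamini_hochberg",
    "estimate_lod",
]


@dataclass(frozen=True)
class FisherResult:
    """Exact 2x2 test summary: two-sided p, conditional-MLE OR, exact CI."""

    pvalue: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95


def fisher_exact(table, conf_level: float = 0.95) -> FisherResult:
    """Fisher's exact test on a 2x2 count table.

    Parameters
    ----------
    table : array-like, shape (2, 2)
        Non-negative integer counts.
    conf_level : float
        Confidence level for the exact conditional interval.

    Returns
    -------
    FisherResult
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table entries must be non-negative integers")
    t = t.astype(np.int64)
    if t.sum() == 0:
        raise ValueError("table has no observations")
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    res = _scipy_odds_ratio(t, kind="conditional")
    ci = res.confidence_interval(confidence_level=conf_level)
    return FisherResult(
        pvalue=p,
        odds_ratio=float(res.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        conf_level=conf_level,
    )


def roc_auc(scores, labels):
    """ROC curve and AUC for binary labels.

    AUC equals the Mann-Whitney U statistic divided by n1*n0, with ties
    contributing 1/2.

    Returns
    -------
    (roc_points, auc) where roc_points is a DataFrame with columns
    ``fpr``, ``tpr``, ``threshold``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    y = (labels == classes.max()).astype(int)
    fpr, tpr, thr = roc_curve(y, scores)
    auc = float(roc_auc_score(y, scores))
    pts = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return pts, auc


def benjamini_hochberg(pvalues):
    """Benjamini-Hochberg step-up FDR adjustment.

    NaN entries are passed through untouched and excluded from the family.
    """
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class LoDResult:
    """Limit-of-detection summary for a serial dilution series.

    ``lod`` is twice the smallest dilution fraction whose scores differ from
    the next lower dilution (Student's t-test); ``reached`` is False when no
    tested fraction separates from the dilution below it.
    """

    lod: float | None
    lowest_detected: float | None
    reached: bool
    comparisons: pd.DataFrame = field(repr=False, default=None)
    per_fraction: pd.DataFrame = field(repr=False, default=None)


def estimate_lod(scores, fractions, alpha: float = 0.05, equal_var: bool = True) -> LoDResult:
    """Estimate the limit of detection from a scored dilution series.

    Each tested fraction is compared with the next lower dilution (the blank,
    fraction 0, terminates the series) by a two-sided two-sample t-test.  The
    smallest fraction with p < ``alpha`` is doubled to give the LoD.

    Parameters
    ----------
    scores, fractions : array-like, same length
        Per-sample classifier scores and true mix-in fractions.
    alpha : float
        Significance level for each pairwise comparison.
    equal_var : bool
        Pooled-variance (Student's) t-test by default.
    """
    df = pd.DataFrame({"score": np.asarray(scores, dtype=float),
                       "fraction": np.asarray(fractions, dtype=float)})
    if df["fraction"].min() < 0:
        raise ValueError("fractions must be non-negative")
    levels = sorted(df["fraction"].unique(), reverse=True)
    if len(levels) < 2:
        raise ValueError("need at least two dilution levels")
    per_fraction = (
        df.groupby("fraction")["score"].agg(["count", "mean", "std"]).sort_index(ascending=False)
    )
    rows = []
    for hi, lo in zip(levels[:-1], levels[1:]):
        a = df.loc[df["fraction"] == hi, "score"].to_numpy()
        b = df.loc[df["fraction"] == lo, "score"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            warnings.warn(
                f"fewer than 2 replicates at fraction {hi:g} vs {lo:g}; comparison skipped"
            )
            p = np.nan
        else:
            p = two_sample_ttest(a, b, equal_var=equal_var)
        rows.append({"fraction": hi, "next_lower": lo, "pvalue": p,
                     "significant": bool(p < alpha) if not np.isnan(p) else False})
    comparisons = pd.DataFrame(rows)
    detected = comparisons.loc[comparisons["significant"], "fraction"]
    if detected.empty:
        return LoDResult(lod=None, lowest_detected=None, reached=False,
                         comparisons=comparisons, per_fraction=per_fraction)
    lowest = float(detected.min())
    return LoDResult(lod=2.0 * lowest, lowest_detected=lowest, reached=True,
                     comparisons=comparisons, per_fraction=per_fraction)
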