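"""Haplotype entropy and driver/passenger DMR typing.

The haplotype entropy index of one amplicon in one sample is the Shannon
entropy (nats) of its haplotype prevalence distribution,

    Ent_i = - sum_j p_ij * log(p_ij),    0 * log 0 := 0.

Passenger (T1) DMRs inherit a low-diversity haplotype spectrum from the
tumour's ancestral cell type, so their entropy does not differ by tumour
group; driver (T2) DMRs acquire de novo methylation during oncogenesis and
show elevated entropy in the aggressive group.  Each amplicon is typed by a
two-sample t-test on entropies between the two tumour groups, with
Benjamini-Hochberg adjustment across amplicons: adjusted p < .05 -> T2,
otherwise T1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._stats import two_sample_ttest
from .evaluation import benjamini_hochberg

__all__ = ["entropy_index", "entropy_matrix", "classify_dmr_types", "EntropyDMRTyper"]


def entropy_index(prevalences) -> float:
    """Shannon entropy (nats) of a haplotype prevalence vector.

    Accepts a mapping bin -> prevalence or an array of prevalences; the
    values must sum to 1 (tolerance 1e-6).
    """
    if hasattr(prevalences, "values") and not isinstance(prevalences, pd.Series):
        p = np.asarray(list(prevalences.values()), dtype=float)
    else:
        p = np.asarray(prevalences, dtype=float)
    if p.size == 0 or abs(p.sum() - 1.0) > 1e-6 or np.any(p < -1e-12):
        raise ValueError("prevalences must be non-negative and sum to 1")
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def entropy_matrix(table: pd.DataFrame, min_reads: int = 20) -> pd.DataFrame:
    """Per sample x amplicon entropy from a long haplotype table.

    Amplicons with fewer than ``min_reads`` passing reads in a sample are
    reported missing (NaN) — too few fragments for a stable entropy estimate.
    """
    def _ent(group: pd.DataFrame) -> float:
        if group["count"].sum() < min_reads:
            return np.nan
        p = group["count"].to_numpy(dtype=float)
        return entropy_index(p / p.sum())

    ent = (
        table.groupby(["sample", "amplicon"])[["count"]]
        .apply(_ent)
        .unstack("amplicon")
    )
    ent.columns.name = "amplicon"
    return ent


def classify_dmr_types(entropy: pd.DataFrame, labels: pd.Series,
                       alpha: float = 0.05, equal_var: bool = False) -> pd.DataFrame:
    """Type each amplicon T1/T2 from group-wise entropy differences.

    Parameters
    ----------
    entropy : DataFrame, samples x amplicons (NaN = missing)
    labels : Series mapping sample -> one of exactly two group labels
        (e.g. MIBC / NMIBC or HG / LG).
    alpha : float
        BH-adjusted significance cut; adjusted p < alpha -> T2, >= alpha -> T1.

    Returns
    -------
    DataFrame indexed by amplicon with columns pvalue, p_adj, dmr_type
    (NaN / None where fewer than 2 samples per group are available).
    """
    labels = labels.reindex(entropy.index)
    groups = [g for g in labels.dropna().unique()]
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    g1 = entropy.loc[labels == groups[0]]
    g2 = entropy.loc[labels == groups[1]]
    pvals = pd.Series(
        {amp: two_sample_ttest(g1[amp], g2[amp], equal_var=equal_var)
         for amp in entropy.columns},
        name="pvalue",
    )
    p_adj = pd.Series(benjamini_hochberg(pvals.to_numpy()), index=pvals.index,
                      name="p_adj")
    calls = pd.DataFrame({"pvalue": pvals, "p_adj": p_adj})
    calls["dmr_type"] = np.where(calls["p_adj"] < alpha, "T2", "T1")
    calls.loc[calls["p_adj"].isna(), "dmr_type"] = None
    calls.index.name = "amplicon"
    return calls


class EntropyDMRTyper(BaseEstimator):
    """Estimator wrapper: fit on a haplotype table + group labels, exposing
    the entropy matrix and per-amplicon T1/T2 calls as fitted attributes.

    Parameters
    ----------
    min_reads : minimum passing reads per (sample, amplicon) for entropy.
    alpha : BH-adjusted threshold separating T2 (p_adj < alpha) from T1.
    equal_var : pooled-variance (Student) t-test instead of Welch.
    """

    def __init__(self, min_reads: int = 20, alpha: float = 0.05,
                 equal_var: bool = False):
        self.min_reads = min_reads
        self.alpha = alpha
        self.equal_var = equal_var

    def fit(self, table: pd.DataFrame, y: pd.Series):
        self.entropy_ = entropy_matrix(table, min_reads=self.min_reads)
        self.calls_ = classify_dmr_types(self.entropy_, y, alpha=self.alpha,
                                         equal_var=self.equal_var)
        return self

    @property
    def dmr_types_(self) -> pd.Series:
        return self.calls_["dmr_type"]
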