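"""Trait-associated haplotype classes and tissue-of-origin decomposition.

Two feature families are derived from a labelled training set of haplotype
tables (HG tumour tissue, LG tumour tissue, normal urine):

* **Haplotype classes** — each (amplicon, bin) haplotype is tested in the
  three pairwise contrasts (HG vs LG, HG vs urine, LG vs urine; two-sample
  t-test on prevalences, BH adjustment within each contrast).  A haplotype is
  HG_high when HG is significantly higher (adjusted p <= .001 and mean
  frequency >= 10% in the higher group) in *both* of its contrasts; LG_high
  and Urine_high symmetrically.  A sample's class feature is the mean of its
  prevalences over the haplotypes of that class.

* **Tissue similarities** — mean haplotype-frequency vectors of the three
  training groups form reference profiles; each sample is decomposed by
  non-negative least squares into LG/HG/Urine components, reported as raw
  (unnormalized) NNLS weights.

Together these give the six predictors consumed by the UCAS and BLCAS
score models: Urine_high, HG_high, LG_high, LG_similarity, HG_similarity,
Urine_similarity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from ._stats import rowwise_ttest
from .evaluation import benjamini_hochberg
from .haplotypes import prevalence_wide

__all__ = [
    "assign_haplotype_classes",
    "sample_class_means",
    "reference_profiles",
    "nnls_decompose",
    "build_features",
    "HaplotypeSignature",
    "CLASS_NAMES",
    "FEATURE_NAMES",
]

CLASS_NAMES = ("HG_high", "LG_high", "Urine_high")
SIMILARITY_NAMES = ("LG_similarity", "HG_similarity", "Urine_similarity")
FEATURE_NAMES = ("Urine_high", "HG_high", "LG_high") + SIMILARITY_NAMES

_CONTRASTS = {  # class -> (group, others it must beat)
    "HG_high": ("HG", ("LG", "URINE")),
    "LG_high": ("LG", ("HG", "URINE")),
    "Urine_high": ("URINE", ("HG", "LG")),
}


def _group_matrix(wide: pd.DataFrame, labels: pd.Series, group: str) -> np.ndarray:
    idx = labels.reindex(wide.index) == group
    return wide.loc[idx].to_numpy(dtype=float).T  # haplotypes x samples


def assign_haplotype_classes(table: pd.DataFrame, labels: pd.Series,
                             alpha: float = 0.001, min_freq: float = 0.10,
                             equal_var: bool = False) -> pd.DataFrame:
    """Assign each (amplicon, bin) haplotype to HG_high / LG_high / Urine_high / none.

    Parameters
    ----------
    table : long haplotype table (sample, amplicon, bin, count, prevalence).
    labels : Series sample -> {"HG", "LG", "URINE"}.
    alpha : BH-adjusted significance threshold (significant iff p_adj <= alpha).
    min_freq : minimum mean frequency in the higher group.

    Returns
    -------
    DataFrame indexed by (amplicon, bin) with per-contrast adjusted p-values,
    per-group mean frequencies and the final ``hap_class`` column.
    """
    wide = prevalence_wide(table)
    missing = set(labels.reindex(wide.index).dropna().unique()) ^ {"HG", "LG", "URINE"}
    if missing:
        raise ValueError("labels must contain exactly the groups HG, LG, URINE")
    mats = {g: _group_matrix(wide, labels, g) for g in ("HG", "LG", "URINE")}
    out = pd.DataFrame(index=wide.columns)
    for g in ("HG", "LG", "URINE"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[f"mean_{g}"] = np.nanmean(mats[g], axis=1)
    pairs = [("HG", "LG"), ("HG", "URINE"), ("LG", "URINE")]
    for a, b in pairs:
        p, delta = rowwise_ttest(mats[a], mats[b], equal_var=equal_var)
        out[f"p_adj_{a}_vs_{b}"] = benjamini_hochberg(p)
        out[f"delta_{a}_vs_{b}"] = delta

    def _wins(hi: str, lo: str) -> np.ndarray:
        a, b = (hi, lo) if (hi, lo) in pairs else (lo, hi)
        sign = 1.0 if (hi, lo) in pairs else -1.0
        p_adj = out[f"p_adj_{a}_vs_{b}"].to_numpy()
        delta = sign * out[f"delta_{a}_vs_{b}"].to_numpy()
        hi_mean = out[f"mean_{hi}"].to_numpy()
        return (p_adj <= alpha) & (delta > 0) & (hi_mean >= min_freq)

    cls = np.full(len(out), "none", dtype=object)
    for name, (group, others) in _CONTRASTS.items():
        hit = np.logical_and.reduce([_wins(group, other) for other in others])
        cls = np.where(hit, name, cls)
    out["hap_class"] = cls
    return out


def sample_class_means(sample_prevalences: pd.Series,
                       assignment: pd.DataFrame) -> dict[str, float]:
    """Mean prevalence of each class's haplotypes in one sample.

    ``sample_prevalences`` is a row of the wide prevalence matrix (indexed by
    (amplicon, bin); NaN = amplicon missing in this sample).  Haplotypes whose
    amplicon is missing are dropped from the mean; an empty class gives 0.
    """
    feats = {}
    for name in CLASS_NAMES:
        members = assignment.index[assignment["hap_class"] == name]
        if len(members) == 0:
            warnings.warn(f"no haplotypes assigned to class {name}; feature set to 0")
            feats[name] = 0.0
            continue
        vals = sample_prevalences.reindex(members).dropna()
        feats[name] = float(vals.mean()) if len(vals) else 0.0
    return feats


def reference_profiles(table: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Mean haplotype-frequency vector per training group.

    Returns a DataFrame indexed by (amplicon, bin) with columns HG, LG, URINE.
    """
    wide = prevalence_wide(table)
    labels = labels.reindex(wide.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        refs = {g: np.nanmean(wide.loc[labels == g].to_numpy(dtype=float), axis=0)
                for g in ("HG", "LG", "URINE")}
    return pd.DataFrame(refs, index=wide.columns)


def nnls_decompose(sample_vector: pd.Series, refs: pd.DataFrame) -> dict[str, float]:
    """Non-negative least-squares decomposition into LG/HG/Urine components.

    Missing entries are dropped pairwise from the sample and all references.
    Weights are raw NNLS solutions, never renormalized.
    """
    v = sample_vector.reindex(refs.index).to_numpy(dtype=float)
    A = refs[["LG", "HG", "URINE"]].to_numpy(dtype=float)
    ok = ~np.isnan(v) & ~np.isnan(A).any(axis=1)
    if not ok.any():
        raise ValueError("sample vector has no observed entries")
    w, _ = nnls(A[ok], v[ok])
    return {"LG_similarity": float(w[0]), "HG_similarity": float(w[1]),
            "Urine_similarity": float(w[2])}


def build_features(table: pd.DataFrame, assignment: pd.DataFrame,
                   refs: pd.DataFrame) -> pd.DataFrame:
    """Per-sample feature matrix (samples x 6) for the score models."""
    wide = prevalence_wide(table)
    rows = {}
    for sample, prev in wide.iterrows():
        feats = sample_class_means(prev, assignment)
        feats.update(nnls_decompose(prev, refs))
        rows[sample] = feats
    out = pd.DataFrame.from_dict(rows, orient="index")[list(FEATURE_NAMES)]
    out.index.name = "sample"
    return out


class HaplotypeSignature(BaseEstimator, TransformerMixin):
    """Learn haplotype classes + reference profiles, emit classifier features.

    fit(X, y): X is a long haplotype table, y maps sample -> HG/LG/URINE.
    transform(X): features DataFrame with the six predictors
    (Urine_high, HG_high, LG_high, LG/HG/Urine_similarity).
    """

    def __init__(self, alpha: float = 0.001, min_freq: float = 0.10,
                 equal_var: bool = False):
        self.alpha = alpha
        self.min_freq = min_freq
        self.equal_var = equal_var

    def fit(self, X: pd.DataFrame, y: pd.Series):
        self.assignment_ = assign_haplotype_classes(
            X, y, alpha=self.alpha, min_freq=self.min_freq, equal_var=self.equal_var
        )
        self.reference_profiles_ = reference_profiles(X, y)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return build_features(X, self.assignment_, self.reference_profiles_)
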