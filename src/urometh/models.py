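"""UCAS and BLCAS score models.

Both scores are Gaussian-family generalized linear models with identity
link on a 0/1 class indicator — i.e. ordinary least squares on the binary
response, scored by the linear predictor:

* **UCAS** (urine cancer score) separates cancer tissue (1) from normal
  urine (0): ``y ~ Urine_high + HG_high + LG_high + Urine_similarity``,
  decision cutoff 0.42 (score >= cutoff -> positive).
* **BLCAS** (basal/luminal cancer score) separates HG (1) from LG (0)
  tumour tissue: ``y ~ HG_high + LG_high``, cutoff 0.52
  (score >= cutoff -> basal-like).

Risk grouping combines both calls: high risk iff UCAS positive or BLCAS
basal-like.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "GaussianScoreModel",
    "UCAS_PREDICTORS",
    "BLCAS_PREDICTORS",
    "ucas_model",
    "blcas_model",
    "fit_ucas",
    "fit_blcas",
    "predict_scores",
    "score_samples",
]

UCAS_PREDICTORS = ("Urine_high", "HG_high", "LG_high", "Urine_similarity")
BLCAS_PREDICTORS = ("HG_high", "LG_high")
UCAS_CUTOFF = 0.42
BLCAS_CUTOFF = 0.52


class GaussianScoreModel(BaseEstimator):
    """OLS fit of a 0/1 class indicator on a fixed predictor set.

    Parameters
    ----------
    predictors : tuple of str
        Feature columns entering the linear predictor.
    cutoff : float
        Decision threshold; score >= cutoff is called positive.
    name : str
        Model name used in serialized files.

    Attributes
    ----------
    intercept_ : float
    coef_ : Series indexed by predictor name
    n_per_class_ : dict label -> training count
    """

    def __init__(self, predictors=UCAS_PREDICTORS, cutoff: float = UCAS_CUTOFF,
                 name: str = "UCAS"):
        self.predictors = tuple(predictors)
        self.cutoff = cutoff
        self.name = name

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        missing = [p for p in self.predictors if p not in X.columns]
        if missing:
            raise ValueError(f"{self.name}: missing predictors {missing}")
        return X[list(self.predictors)].to_numpy(dtype=float)

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        if np.unique(y).size < 2:
            raise ValueError(f"{self.name}: training labels are all equal")
        M = self._design(X)
        D = np.column_stack([np.ones(len(M)), M])
        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            # locate columns not adding rank, to name the collinear predictors
            bad = []
            base = D[:, :1]
            for j, name in enumerate(self.predictors):
                cand = np.column_stack([base, D[:, j + 1]])
                if np.linalg.matrix_rank(cand) == base.shape[1]:
                    bad.append(name)
                else:
                    base = cand
            raise ValueError(
                f"{self.name}: rank-deficient design; collinear predictors: {bad}"
            )
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = pd.Series(beta[1:], index=list(self.predictors), name="coef")
        labels, counts = np.unique(y, return_counts=True)
        self.n_per_class_ = dict(zip(labels.tolist(), counts.tolist()))
        return self

    def decision_function(self, X: pd.DataFrame) -> pd.Series:
        M = self._design(X)
        scores = self.intercept_ + M @ self.coef_.to_numpy()
        return pd.Series(scores, index=X.index, name=f"{self.name}_score")

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Thresholded call: 1 iff score >= cutoff (boundary is positive)."""
        return (self.decision_function(X) >= self.cutoff).astype(int)

    # -- plain-text serialization for audit --------------------------------
    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"model\t{self.name}\n")
            fh.write(f"cutoff\t{self.cutoff!r}\n")
            fh.write(f"intercept\t{self.intercept_!r}\n")
            for name, c in self.coef_.items():
                fh.write(f"coef:{name}\t{c!r}\n")

    @classmethod
    def from_text(cls, path) -> "GaussianScoreModel":
        fields = {}
        coefs = {}
        with open(path) as fh:
            for line in fh:
                key, val = line.rstrip("\n").split("\t")
                if key.startswith("coef:"):
                    coefs[key[5:]] = float(val)
                else:
                    fields[key] = val
        model = cls(predictors=tuple(coefs), cutoff=float(fields["cutoff"]),
                    name=fields["model"])
        model.intercept_ = float(fields["intercept"])
        model.coef_ = pd.Series(coefs, name="coef")
        model.n_per_class_ = {}
        return model


def ucas_model(cutoff: float = UCAS_CUTOFF) -> GaussianScoreModel:
    return GaussianScoreModel(UCAS_PREDICTORS, cutoff, "UCAS")


def blcas_model(cutoff: float = BLCAS_CUTOFF) -> GaussianScoreModel:
    return GaussianScoreModel(BLCAS_PREDICTORS, cutoff, "BLCAS")


def fit_ucas(features: pd.DataFrame, labels, cutoff: float = UCAS_CUTOFF):
    """Fit the urine cancer score (cancer tissue = 1, normal urine = 0)."""
    return ucas_model(cutoff).fit(features, labels)


def fit_blcas(features: pd.DataFrame, labels, cutoff: float = BLCAS_CUTOFF):
    """Fit the basal/luminal score (HG tissue = 1, LG tissue = 0)."""
    return blcas_model(cutoff).fit(features, labels)


def predict_scores(model: GaussianScoreModel, features: pd.DataFrame) -> pd.DataFrame:
    """Scores and thresholded calls for one fitted model."""
    score = model.decision_function(features)
    call = score >= model.cutoff
    return pd.DataFrame({"score": score, "call": call.astype(int)})


def score_samples(ucas: GaussianScoreModel, blcas: GaussianScoreModel,
                  features: pd.DataFrame) -> pd.DataFrame:
    """Joint UCAS/BLCAS scoring with the combined risk group.

    Risk is ``high`` when UCAS is positive or BLCAS is basal-like, ``low``
    when UCAS is negative and BLCAS luminal-like.
    """
    u = ucas.decision_function(features)
    b = blcas.decision_function(features)
    ucas_pos = u >= ucas.cutoff
    basal = b >= blcas.cutoff
    out = pd.DataFrame({
        "ucas_score": u,
        "ucas_call": np.where(ucas_pos, "positive", "negative"),
        "blcas_score": b,
        "blcas_class": np.where(basal, "basal", "luminal"),
        "risk_group": np.where(ucas_pos | basal, "high", "low"),
    })
    out.index.name = "sample"
    return out
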