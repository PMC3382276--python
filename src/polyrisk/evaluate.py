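"""ROC/AUC evaluation of polygenic risk scores.

The AUC is read as the probability that a randomly chosen case is ranked
above a randomly chosen control by the score — the normalized Mann-Whitney
U statistic, with ties given half credit.  It is therefore invariant to any
strictly monotone transformation of the score and to the case:control ratio
of the evaluation sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["polygenic_score", "auc", "roc_curve", "PredictionResult", "evaluate_scores"]


def polygenic_score(genotypes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted allele-count score, ``score_i = sum_j X_ij w_j``.

    Linear in the weights; loci with weight 0 contribute nothing, so a
    predictor restricted to a subset of loci is expressed by zeroing the
    rest.
    """
    genotypes = np.asarray(genotypes)
    weights = np.asarray(weights, dtype=np.float64)
    if genotypes.ndim != 2 or genotypes.shape[1] != weights.size:
        raise ValueError(
            f"genotype matrix with {genotypes.shape[-1]} loci does not match "
            f"{weights.size} weights"
        )
    return genotypes.astype(np.float64) @ weights


def auc(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    """Mann-Whitney AUC: fraction of case/control pairs ranked concordantly.

    Computed in O(n log n) from midranks; ties count 1/2.  Equals the
    trapezoidal area under the full ROC curve.
    """
    case_scores = np.asarray(case_scores, dtype=np.float64)
    control_scores = np.asarray(control_scores, dtype=np.float64)
    if case_scores.size == 0 or control_scores.size == 0:
        raise ValueError("both score groups must be non-empty")
    n_ca, n_co = case_scores.size, control_scores.size
    ranks = rankdata(np.concatenate([case_scores, control_scores]))
    u = ranks[:n_ca].sum() - n_ca * (n_ca + 1) / 2.0
    return float(u / (n_ca * n_co))


def roc_curve(
    case_scores: np.ndarray, control_scores: np.ndarray
) -> pd.DataFrame:
    """ROC points at every distinct threshold, thresholds descending.

    Returns a frame with columns ``fpr``, ``tpr``, ``threshold`` starting at
    (0, 0) and ending at (1, 1); the trapezoidal area under the points
    equals :func:`auc` exactly.
    """
    case_scores = np.asarray(case_scores, dtype=np.float64)
    control_scores = np.asarray(control_scores, dtype=np.float64)
    if case_scores.size == 0 or control_scores.size == 0:
        raise ValueError("both score groups must be non-empty")
    y = np.concatenate([np.ones(case_scores.size), np.zeros(control_scores.size)])
    s = np.concatenate([case_scores, control_scores])
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass
class PredictionResult:
    """A scored predictor evaluated on the validation partition."""

    scenario: str
    loci: np.ndarray        # indices of loci with non-zero weight
    scores: np.ndarray      # validation-individual scores
    affected: np.ndarray    # validation labels
    auc: float
    roc: pd.DataFrame


def evaluate_scores(
    scores: np.ndarray, affected: np.ndarray, scenario: str = "",
    weights: np.ndarray | None = None,
) -> PredictionResult:
    """Bundle scores and labels into a :class:`PredictionResult`."""
    scores = np.asarray(scores, dtype=np.float64)
    affected = np.asarray(affected, dtype=bool)
    ca, co = scores[affected], scores[~affected]
    loci = (
        np.flatnonzero(weights) if weights is not None else np.array([], dtype=int)
    )
    return PredictionResult(
        scenario=scenario,
        loci=loci,
        scores=scores,
        affected=affected,
        auc=auc(ca, co),
        roc=roc_curve(ca, co),
    )
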