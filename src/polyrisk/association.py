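"""Per-locus association testing and polygenic score estimation.

Effects are estimated one locus at a time on the training half of the
case-control sample, by default with a linear regression of the 0/1
affection label on the 0/1/2 genotype count.  That is the classical
single-marker score test: for ranking loci and weighting a polygenic score
it is equivalent in practice to logistic regression at these sample sizes,
with none of the separation pathologies, and it vectorizes over all loci at
once.  Logistic regression is available as an alternative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .evaluate import auc as _mann_whitney_auc

__all__ = [
    "PolygenicScorePredictor",
    "per_locus_association",
    "select_top_k",
]

STAT_COLUMNS = ["locus", "effect", "se", "statistic", "p", "rank", "monomorphic"]


def _marginal_linear(X: np.ndarray, y: np.ndarray):
    """Vectorized per-locus simple linear regression of y on genotype.

    Returns (slope, se, wald 1-df statistic, p-value, monomorphic flag).
    Monomorphic loci (zero genotype variance in this sample) are flagged and
    reported as effect 0, statistic 0, p = 1.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    xbar = X.mean(axis=0)
    ybar = y.mean()
    sxy = (y @ X) / n - xbar * ybar
    sxx = (X * X).mean(axis=0) - xbar**2
    syy = y.var()
    mono = sxx <= 0.0
    sxx_safe = np.where(mono, 1.0, sxx)
    slope = np.where(mono, 0.0, sxy / sxx_safe)
    # residual variance of y given x, per locus
    rss = np.maximum(syy - slope * sxy, 0.0)
    dof = max(n - 2, 1)
    se = np.sqrt(rss * n / dof / (n * sxx_safe))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(mono | (se == 0.0), 0.0, (slope / se) ** 2)
    pval = np.where(mono, 1.0, stats.chi2.sf(stat, df=1))
    se = np.where(mono, np.nan, se)
    return slope, se, stat, pval, mono


def _marginal_logistic(X: np.ndarray, y: np.ndarray):
    """Per-locus logistic regression (statsmodels), one fit per locus."""
    import statsmodels.api as sm

    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    m = X.shape[1]
    slope = np.zeros(m)
    se = np.full(m, np.nan)
    stat = np.zeros(m)
    pval = np.ones(m)
    mono = X.var(axis=0) <= 0.0
    for j in range(m):
        if mono[j]:
            continue
        design = sm.add_constant(X[:, j])
        fit = sm.Logit(y, design).fit(disp=False, maxiter=100)
        slope[j] = fit.params[1]
        se[j] = fit.bse[1]
        stat[j] = (slope[j] / se[j]) ** 2
        pval[j] = stats.chi2.sf(stat[j], df=1)
    return slope, se, stat, pval, mono


def _rank_by_p(pval: np.ndarray) -> np.ndarray:
    """1-based rank by ascending p-value, ties broken by locus index."""
    order = np.lexsort((np.arange(pval.size), pval))
    rank = np.empty(pval.size, dtype=np.int64)
    rank[order] = np.arange(1, pval.size + 1)
    return rank


class PolygenicScorePredictor(BaseEstimator):
    """Marginal per-locus effect estimator and polygenic scorer.

    Parameters
    ----------
    method : {"linear", "logistic"}, default "linear"
        Per-locus regression model for the 0/1 affection label.
    top_k : int or None, default None
        If set, only the ``top_k`` loci with smallest p-values (ties broken
        by locus index) contribute to the score; otherwise all loci do.

    Attributes
    ----------
    effect_ : ndarray of shape (n_loci,)
        Estimated per-allele effect for every locus.
    se_, statistic_, pvalue_ : ndarray
        Standard errors, Wald 1-df statistics and p-values.
    rank_ : ndarray of int
        1-based rank by ascending p-value (a permutation of 1..n_loci).
    monomorphic_ : ndarray of bool
        Loci with no genotype variation in the training sample.
    support_ : ndarray of bool
        Loci whose effects enter the score (all True when top_k is None).

    Examples
    --------
    >>> model = PolygenicScorePredictor(top_k=15).fit(X_train, y_train)
    >>> scores = model.decision_function(X_valid)
    >>> model.score(X_valid, y_valid)   # Mann-Whitney AUC
    """

    def __init__(self, method: str = "linear", top_k: int | None = None):
        self.method = method
        self.top_k = top_k

    def fit(self, X, y):
        X = check_array(X, dtype=np.float64)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(
                f"need both cases and controls in the training data, "
                f"got classes {classes}"
            )
        y01 = (y == classes.max()).astype(np.float64)
        if self.method == "linear":
            est = _marginal_linear(X, y01)
        elif self.method == "logistic":
            est = _marginal_logistic(X, y01)
        else:
            raise ValueError(
                f"unknown method {self.method!r}; use 'linear' or 'logistic'"
            )
        self.effect_, self.se_, self.statistic_, self.pvalue_, self.monomorphic_ = est
        self.rank_ = _rank_by_p(self.pvalue_)
        self.n_features_in_ = X.shape[1]
        self.classes_ = classes
        if self.top_k is None:
            self.support_ = np.ones(self.n_features_in_, dtype=bool)
        else:
            if not 0 < self.top_k <= self.n_features_in_:
                raise ValueError(
                    f"top_k must lie in [1, {self.n_features_in_}], got {self.top_k}"
                )
            self.support_ = self.rank_ <= self.top_k
        scores = X @ (self.effect_ * self.support_)
        frac_cases = float(y01.mean())
        self.threshold_ = float(np.quantile(scores, 1.0 - frac_cases))
        return self

    @property
    def stats_(self) -> pd.DataFrame:
        """Per-locus statistics table (locus, effect, se, statistic, p, rank)."""
        check_is_fitted(self, "effect_")
        return pd.DataFrame(
            {
                "locus": np.arange(self.n_features_in_),
                "effect": self.effect_,
                "se": self.se_,
                "statistic": self.statistic_,
                "p": self.pvalue_,
                "rank": self.rank_,
                "monomorphic": self.monomorphic_,
            }
        )

    def decision_function(self, X) -> np.ndarray:
        """Polygenic score: genotype counts weighted by selected effects."""
        check_is_fitted(self, "effect_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} loci, the model was fitted with "
                f"{self.n_features_in_}"
            )
        return X @ (self.effect_ * self.support_)

    def predict(self, X) -> np.ndarray:
        """Label by thresholding the score at the training case fraction."""
        check_is_fitted(self, "threshold_")
        scores = self.decision_function(X)
        return self.classes_[(scores > self.threshold_).astype(int)]

    def score(self, X, y) -> float:
        """Mann-Whitney AUC of the score on (X, y)."""
        scores = self.decision_function(X)
        y = np.asarray(y)
        return _mann_whitney_auc(
            scores[y == self.classes_.max()], scores[y == self.classes_.min()]
        )


def per_locus_association(
    data, method: str = "linear"
) -> pd.DataFrame:
    """Per-locus association statistics on the training partition.

    ``data`` is a :class:`~polyrisk.simulate.CaseControlDataset`; only its
    training view enters the regression, keeping the validation half
    untouched for evaluation.
    """
    X_train, y_train = data.training()
    if X_train.shape[0] == 0 or np.unique(y_train).size < 2:
        raise ValueError("training partition must contain both cases and controls")
    model = PolygenicScorePredictor(method=method).fit(X_train, y_train)
    return model.stats_


def select_top_k(stats: pd.DataFrame, k: int) -> pd.DataFrame:
    """The ``k`` loci with smallest p-values, ties broken by locus ID."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > len(stats):
        raise ValueError(f"k={k} exceeds the {len(stats)} available loci")
    ordered = stats.sort_values(["p", "locus"], kind="mergesort")
    return ordered.head(k).reset_index(drop=True)
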