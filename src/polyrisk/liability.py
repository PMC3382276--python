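"""Closed-form liability-threshold theory for disease risk prediction.

The liability-threshold model posits an unobserved continuous liability,
standard normal in the population, composed of an additive genetic part with
variance ``h2`` and a residual with variance ``1 - h2``.  Disease occurs when
liability exceeds the threshold ``T`` set by the population prevalence ``K``.

This module collects the quantities that follow in closed form from that
model: penetrance as a function of genetic load, the moments of liability in
cases and controls (truncated-normal selection intensities), the maximum AUC
attainable by a genomic profile explaining a given share of liability
variance, the inverse map from an observed AUC back to variance explained,
the conversion of a per-allele odds ratio into liability-scale variance, and
the 1-df non-central chi-square power/sample-size arithmetic used for GWAS
design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LiabilityModel",
    "liability_threshold",
    "penetrance",
    "max_auc",
    "variance_from_auc",
    "or_to_liability_variance",
    "gwas_power",
    "required_n",
]


def liability_threshold(K: float) -> float:
    """Liability threshold ``T`` for prevalence ``K``.

    ``T`` is the upper-``K`` quantile of the standard normal: a fraction
    ``K`` of the population lies above it.

    Parameters
    ----------
    K : float
        Disease prevalence, strictly between 0 and 1.
    """
    if not 0.0 < K < 1.0:
        raise ValueError(f"prevalence K must lie in (0, 1), got {K}")
    return float(stats.norm.isf(K))


@dataclass(frozen=True)
class LiabilityModel:
    """Prevalence/heritability bundle with derived truncated-normal moments.

    Attributes
    ----------
    K : float
        Disease prevalence.
    h2 : float
        Narrow-sense heritability of liability.
    T : float
        Liability threshold (upper-``K`` standard-normal quantile).
    z : float
        Standard-normal density at ``T``.
    i : float
        Mean liability of cases, ``z / K`` (the selection intensity).
    i2 : float
        Mean liability of controls, ``-z / (1 - K)``.
    """

    K: float
    h2: float
    T: float = field(init=False)
    z: float = field(init=False)
    i: float = field(init=False)
    i2: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.K < 1.0:
            raise ValueError(f"prevalence K must lie in (0, 1), got {self.K}")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"heritability h2 must lie in [0, 1], got {self.h2}")
        T = liability_threshold(self.K)
        z = float(stats.norm.pdf(T))
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "i", z / self.K)
        object.__setattr__(self, "i2", -z / (1.0 - self.K))


def penetrance(g, model: LiabilityModel):
    """Probability of disease given genetic load ``g`` on the liability scale.

    With residual liability normal with variance ``1 - h2`` around ``g``, the
    penetrance is the upper-tail normal probability of ``(T - g)/sqrt(1-h2)``.
    It is monotone non-decreasing in ``g`` and integrates to ``K`` against the
    N(0, h2) density of genetic load.  At ``h2 = 1`` there is no residual and
    the function degenerates to a step at ``g = T`` (value 1/2 exactly at the
    threshold, by the limiting argument).
    """
    g = np.asarray(g, dtype=float)
    if model.h2 >= 1.0:
        out = np.where(g > model.T, 1.0, 0.0)
        out = np.where(g == model.T, 0.5, out)
        return out if out.ndim else float(out)
    out = stats.norm.sf((model.T - g) / np.sqrt(1.0 - model.h2))
    return out if np.ndim(g) else float(out)


def _case_control_score_moments(model: LiabilityModel, rho2: float):
    """Mean and variance of a profile score in cases and controls.

    The profile score is the part of liability captured by the predictor,
    normal with variance ``rho2`` and correlation ``sqrt(rho2)`` with total
    liability.  Conditioning on case status truncates liability at ``T``,
    shifting the score mean to ``i * rho2`` (cases) / ``i2 * rho2`` (controls)
    and shrinking its variance by the usual truncation factor.
    """
    i, i2, T = model.i, model.i2, model.T
    mean_case = i * rho2
    mean_ctrl = i2 * rho2
    var_case = rho2 * (1.0 - rho2 * i * (i - T))
    var_ctrl = rho2 * (1.0 - rho2 * i2 * (i2 - T))
    return mean_case, var_case, mean_ctrl, var_ctrl


def max_auc(model: LiabilityModel, rho2: float | None = None) -> float:
    """AUC of a genomic profile explaining ``rho2`` of liability variance.

    ``rho2`` defaults to ``h2`` (a predictor capturing all genetic variance),
    which gives the maximum attainable AUC for the trait.  The AUC is the
    probability that a random case's score exceeds a random control's; both
    scores are normal with the threshold-truncated moments, so

        AUC = Phi( (mu_case - mu_ctrl) / sqrt(var_case + var_ctrl) ).

    Increasing in ``rho2``; for fixed ``rho2`` it increases as prevalence
    falls (rarer diseases ascertain cases further into the tail).
    """
    if rho2 is None:
        rho2 = model.h2
    if not 0.0 <= rho2 <= model.h2:
        raise ValueError(
            f"rho2 must lie in [0, h2] = [0, {model.h2}], got {rho2}"
        )
    if rho2 == 0.0:
        return 0.5
    mc, vc, m0, v0 = _case_control_score_moments(model, rho2)
    return float(stats.norm.cdf((mc - m0) / np.sqrt(vc + v0)))


def variance_from_auc(auc: float, model: LiabilityModel) -> float:
    """Share of genetic variance implied by an observed profile AUC.

    Numerically inverts :func:`max_auc` in ``rho2`` and returns
    ``rho2 / h2``: the proportion of the *genetic* variance the profile must
    explain to reach ``auc`` under this prevalence and heritability.  The
    same AUC can correspond to very different shares depending on (K, h2),
    which is why an AUC quoted without its parameters is ambiguous.
    """
    if model.h2 == 0.0:
        raise ValueError("h2 = 0: no genetic variance to attribute an AUC to")
    attainable = max_auc(model, model.h2)
    if not 0.5 <= auc < attainable:
        raise ValueError(
            f"auc must lie in [0.5, {attainable:.6f}) for K={model.K}, "
            f"h2={model.h2}; got {auc}"
        )
    if auc == 0.5:
        return 0.0
    rho2 = optimize.brentq(
        lambda r: max_auc(model, r) - auc, 0.0, model.h2, xtol=1e-12
    )
    return float(rho2 / model.h2)


def or_to_liability_variance(
    maf: float, oddsratio: float, K: float, method: str = "probit"
) -> float:
    """Liability-scale variance explained by one biallelic risk locus.

    Parameters
    ----------
    maf : float
        Risk-allele frequency.
    oddsratio : float
        Per-allele (multiplicative) odds ratio.
    K : float
        Disease prevalence.
    method : {"probit", "logit"}
        "probit" (default) solves for genotype-specific risks under
        Hardy-Weinberg that reproduce the odds ratio and the prevalence,
        converts each risk to a genotype mean on the liability scale through
        the fixed threshold, and takes the additive (regression) allele
        effect beta; returns ``2 p (1-p) beta^2``.  "logit" is the cruder
        scaling ``beta = ln(OR) * K(1-K) / z`` from the observed logistic
        scale to liability.
    """
    if not 0.0 < K < 1.0:
        raise ValueError(f"prevalence K must lie in (0, 1), got {K}")
    if oddsratio <= 0.0:
        raise ValueError(f"odds ratio must be positive, got {oddsratio}")
    if maf <= 0.0 or maf >= 1.0:
        warnings.warn(
            f"degenerate risk-allele frequency {maf}: locus explains no variance",
            stacklevel=2,
        )
        return 0.0
    if oddsratio == 1.0:
        return 0.0
    p = maf
    if method == "logit":
        T = liability_threshold(K)
        z = stats.norm.pdf(T)
        beta = np.log(oddsratio) * K * (1.0 - K) / z
        return float(2.0 * p * (1.0 - p) * beta**2)
    if method != "probit":
        raise ValueError(f"unknown method {method!r}; use 'probit' or 'logit'")

    geno_freq = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    or_geno = np.array([1.0, oddsratio, oddsratio**2])

    def prevalence_gap(baseline_odds: float) -> float:
        odds = baseline_odds * or_geno
        return float(geno_freq @ (odds / (1.0 + odds))) - K

    base = optimize.brentq(prevalence_gap, 1e-300, 1e12, xtol=1e-15)
    risks = base * or_geno / (1.0 + base * or_geno)
    T = liability_threshold(K)
    # genotype mean on the liability scale with unit residual variance,
    # anchored to the common threshold T
    mu = T - stats.norm.isf(risks)
    counts = np.array([0.0, 1.0, 2.0])
    cov = float(geno_freq @ (mu * counts)) - float(geno_freq @ mu) * 2 * p
    beta = cov / (2.0 * p * (1.0 - p))
    return float(2.0 * p * (1.0 - p) * beta**2)


def _chi2_threshold(alpha: float) -> float:
    return float(stats.chi2.isf(alpha, df=1))


def gwas_power(n: float, q2: float, alpha: float) -> float:
    """Power of a 1-df association test for a variant explaining ``q2``.

    The test statistic is non-central chi-square with 1 df and
    non-centrality ``n * q2``; significance is declared above the central
    chi-square quantile for the two-sided level ``alpha``.
    """
    if n <= 0:
        raise ValueError(f"sample size must be positive, got {n}")
    if not 0.0 <= q2 < 1.0:
        raise ValueError(f"variance explained q2 must lie in [0, 1), got {q2}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"significance alpha must lie in (0, 1), got {alpha}")
    thr = _chi2_threshold(alpha)
    if q2 == 0.0:
        return alpha
    return float(stats.ncx2.sf(thr, df=1, nc=n * q2))


def required_n(q2: float, alpha: float, power: float) -> int:
    """Smallest sample size reaching ``power`` at significance ``alpha``.

    Solves for the non-centrality ``ncp*`` at which the 1-df non-central
    chi-square test attains the target power, then returns
    ``ceil(ncp* / q2)`` adjusted so that :func:`gwas_power` at the returned
    ``n`` meets the target while ``n - 1`` does not.
    """
    if not 0.0 < q2 < 1.0:
        raise ValueError(f"variance explained q2 must lie in (0, 1), got {q2}")
    if not 0.0 < power < 1.0:
        raise ValueError(f"target power must lie in (0, 1), got {power}")
    thr = _chi2_threshold(alpha)

    def power_gap(ncp: float) -> float:
        return float(stats.ncx2.sf(thr, df=1, nc=ncp)) - power

    hi = 4.0
    while power_gap(hi) < 0:
        hi *= 2.0
    ncp_star = optimize.brentq(power_gap, 1e-12, hi, xtol=1e-9)
    n = int(np.ceil(ncp_star / q2))
    while n > 1 and gwas_power(n - 1, q2, alpha) >= power:
        n -= 1
    while gwas_power(n, q2, alpha) < power:
        n += 1
    return n
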