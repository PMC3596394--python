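"""Inference for the generalized Mantel-Haenszel odds ratio.

Contains the delta-method standard error of the log of the generalized
Mantel-Haenszel estimator (the gradient of the log-ratio statistic is
propagated analytically through the softmax probabilities and sandwiched
with the ML covariance), Wald and likelihood-ratio tests of the
homogeneity hypothesis delta = beta_11 - beta_01 - beta_10 = 0, and a
nonparametric bootstrap cross-check of any log-OR estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import Dataset
from .estimators import constrained_ml_or, crude_or, generalized_mh
from .multinomial import (FitError, MultinomialParams, fit_constrained,
                          fit_unconstrained, predict_probs)

logger = logging.getLogger(__name__)

__all__ = [
    "HomogeneityTest",
    "delta_method_se",
    "wald_homogeneity",
    "lr_homogeneity",
    "bootstrap_se",
]


@dataclass
class HomogeneityTest:
    """Chi-square test of homogeneity of the odds ratio over covariates.

    Under homogeneity the m-vector delta is zero; both the Wald and the
    likelihood-ratio statistic are referred to chi-square(m).
    """

    method: str
    statistic: float
    df: int
    p_value: float

    def as_row(self) -> dict:
        return {"method": self.method, "statistic": self.statistic,
                "df": self.df, "p_value": self.p_value}


def _log_gmh_gradient(params: MultinomialParams, data: Dataset) -> np.ndarray:
    """Analytic gradient of log(sum p11 p00 / sum p10 p01) in the expanded
    parameter vector (alpha_01, alpha_10, alpha_11, beta_01, beta_10, beta_11).

    Chain rule through the softmax: with category probabilities p_c and
    non-reference linear predictors eta_d,
    d p_c / d eta_d = p_c (1[c=d] - p_d) and d p_00 / d eta_d = -p_00 p_d.
    Both products p11*p00 and p10*p01 involve the reference category, so
    each derivative picks up a common -2 p_d term plus the indicator of
    the product's own non-reference member.
    """
    p = predict_probs(params, data).p
    s1 = float(np.sum(p[:, 3] * p[:, 0]))
    s2 = float(np.sum(p[:, 2] * p[:, 1]))
    a = p[:, 3] * p[:, 0] / s1  # subject weights, numerator sum
    b = p[:, 2] * p[:, 1] / s2  # denominator sum
    # dR/d eta_{i,d}, d = 1..3 indexing categories (01, 10, 11)
    ind = np.zeros((data.n, 3))
    ind[:, 2] = a          # 1[d=11] weight from the numerator
    ind[:, 0] += -b        # 1[d=01] from the denominator
    ind[:, 1] += -b        # 1[d=10] from the denominator
    deta = ind - 2.0 * (a - b)[:, None] * p[:, 1:]
    m = data.m
    g = np.zeros(3 + 3 * m)
    g[:3] = deta.sum(axis=0)
    if m:
        for d in range(3):
            g[3 + d * m: 3 + (d + 1) * m] = deta[:, d] @ data.z
    return g


def _log_gmh_gradient_fd(params: MultinomialParams, data: Dataset,
                         h: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of the same statistic; guards the
    analytic algebra in tests."""
    from copy import deepcopy

    def value(theta):
        q = deepcopy(params)
        q.alpha = theta[:3]
        q.beta = theta[3:].reshape(3, data.m) if data.m else np.empty((3, 0))
        return generalized_mh(predict_probs(q, data)).log_or

    theta0 = params.theta
    g = np.zeros_like(theta0)
    for j in range(len(theta0)):
        tp, tm = theta0.copy(), theta0.copy()
        tp[j] += h
        tm[j] -= h
        g[j] = (value(tp) - value(tm)) / (2 * h)
    return g


def delta_method_se(params: MultinomialParams, data: Dataset) -> float:
    """Delta-method SE of the log generalized Mantel-Haenszel OR.

    SE = sqrt(g' Sigma g) with g the analytic gradient of the log-ratio
    statistic and Sigma the ML covariance of the fit (expanded covariance
    for a constrained fit).
    """
    g = _log_gmh_gradient(params, data)
    var = float(g @ params.covariance @ g)
    if var < 0:
        raise np.linalg.LinAlgError(
            "negative delta-method variance: covariance is not PSD along "
            f"gradient direction {g}")
    return float(np.sqrt(var))


def wald_homogeneity(params_unconstrained: MultinomialParams) -> HomogeneityTest:
    """Wald chi-square test of delta = 0 from the unconstrained fit.

    statistic = delta' V^{-1} delta with V the covariance of the contrast
    beta_11 - beta_01 - beta_10; df = m.  With m = 0 the hypothesis is
    vacuous and p = 1 is returned.
    """
    if params_unconstrained.constrained:
        raise ValueError("Wald homogeneity test needs the unconstrained fit")
    m = params_unconstrained.m
    if m == 0:
        return HomogeneityTest("wald", 0.0, 0, 1.0)
    C = np.zeros((m, 3 + 3 * m))
    C[:, 3: 3 + m] = -np.eye(m)
    C[:, 3 + m: 3 + 2 * m] = -np.eye(m)
    C[:, 3 + 2 * m:] = np.eye(m)
    V = C @ params_unconstrained.covariance @ C.T
    delta = params_unconstrained.delta
    try:
        stat = float(delta @ np.linalg.solve(V, delta))
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"singular contrast covariance in Wald test: {e}") from e
    return HomogeneityTest("wald", stat, m, float(stats.chi2.sf(stat, m)))


def lr_homogeneity(fit_u: MultinomialParams,
                   fit_c: MultinomialParams) -> HomogeneityTest:
    """Likelihood-ratio test of homogeneity from the nested pair of fits.

    statistic = 2 (loglik_unconstrained - loglik_constrained), df = m.
    Tiny negative statistics (optimizer noise) are clamped to zero; a
    negative value beyond -1e-6 signals an optimizer failure and raises.
    """
    if fit_c.constrained is False or fit_u.constrained is True:
        raise ValueError("lr_homogeneity(fit_u, fit_c) expects (unconstrained, constrained)")
    stat = 2.0 * (fit_u.loglik - fit_c.loglik)
    if stat < -1e-6:
        raise FitError(f"negative LR statistic {stat:.3e}: optimizer failure")
    stat = max(stat, 0.0)
    m = fit_u.m
    if m == 0:
        return HomogeneityTest("lr", 0.0, 0, 1.0)
    return HomogeneityTest("lr", float(stat), m, float(stats.chi2.sf(stat, m)))


_ESTIMATOR_FUNCS = ("generalized_mh", "constrained_ml", "crude")


def _log_or_of(data: Dataset, estimator: str) -> float:
    if estimator == "crude":
        return crude_or(data).log_or
    if estimator == "generalized_mh":
        fit = fit_unconstrained(data)
        return generalized_mh(predict_probs(fit, data)).log_or
    if estimator == "constrained_ml":
        return constrained_ml_or(fit_constrained(data)).log_or
    raise ValueError(f"unknown estimator {estimator!r}; choose from {_ESTIMATOR_FUNCS}")


def bootstrap_se(data: Dataset, estimator: str = "generalized_mh",
                 B: int = 500, seed: int = 0) -> float:
    """Nonparametric bootstrap SE of an estimator's log OR.

    Subjects are resampled with replacement B times; replicates in which an
    (X,Y) cell is empty (or the fit fails) are redrawn, with the redraw
    count logged.  A single seed expands to independent per-replicate
    streams, so results are reproducible and order-independent.
    """
    if B < 100:
        raise ValueError("B must be at least 100 for a stable bootstrap SE")
    streams = np.random.SeedSequence(seed).spawn(B)
    vals = np.empty(B)
    redraws = 0
    for b, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        while True:
            idx = rng.integers(0, data.n, size=data.n)
            boot = Dataset(data.x[idx], data.y[idx], data.z[idx],
                           list(data.covariate_names))
            if (boot.cell_counts() == 0).any():
                redraws += 1
                continue
            try:
                vals[b] = _log_or_of(boot, estimator)
            except FitError:
                redraws += 1
                continue
            break
    if redraws:
        logger.info("bootstrap redrew %d degenerate replicates", redraws)
    return float(np.std(vals, ddof=1))
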