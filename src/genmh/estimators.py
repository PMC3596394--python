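"""Odds-ratio point estimators.

Four routes to a covariate-adjusted odds ratio between binary X and Y:

* the classical Mantel-Haenszel estimator pooled over discrete strata,
  sum(n11_i n00_i / n_i) / sum(n10_i n01_i / n_i);
* its generalization in which observed stratum cell fractions are replaced
  by subject-specific classification probabilities from the multinomial
  logistic fit, sum(p11_i p00_i) / sum(p10_i p01_i) over subjects;
* the average of subject-specific log odds ratios read off the fitted
  parameters; and
* the constrained-ML estimator log(psi) = alpha_11 - alpha_10 - alpha_01
  from the homogeneity fit, which coincides with the generalized
  Mantel-Haenszel estimator evaluated on homogeneity-model probabilities.

All estimators are symmetric in X and Y.  Confidence intervals are Wald
intervals on the log scale, exponentiated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.contingency_tables import StratifiedTable as _SMStratifiedTable

from .data import Dataset, StratifiedTable
from .multinomial import ClassificationProbs, MultinomialParams

__all__ = [
    "ORSummary",
    "SubjectLogORs",
    "classical_mh",
    "generalized_mh",
    "subject_log_ors",
    "constrained_ml_or",
    "crude_or",
]

Z_95 = 1.959964  # standard normal 97.5% quantile


@dataclass
class ORSummary:
    """An odds-ratio estimate with log-scale SE and 95% Wald CI."""

    estimator_label: str
    log_or: float
    se_log_or: float
    n_used: int

    @property
    def or_value(self) -> float:
        return float(np.exp(self.log_or))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.log_or - Z_95 * self.se_log_or))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.log_or + Z_95 * self.se_log_or))

    def as_row(self) -> dict:
        return {
            "estimator": self.estimator_label,
            "or": self.or_value,
            "log_or": self.log_or,
            "se_log_or": self.se_log_or,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n_used,
        }


@dataclass
class SubjectLogORs:
    """Per-subject log odds ratios eta_i = log(psi) + delta' z_i.

    Constant across subjects exactly when the fit is homogeneity-
    constrained (delta = 0 by construction).
    """

    eta: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.eta.mean())

    def summary(self) -> dict:
        return {
            "min": float(self.eta.min()),
            "median": float(np.median(self.eta)),
            "mean": self.mean,
            "max": float(self.eta.max()),
        }


def _mh_sums(tables: np.ndarray) -> tuple[float, float]:
    n_i = tables.sum(axis=1).astype(float)
    ok = n_i > 0
    num = float(np.sum(tables[ok, 3] * tables[ok, 0] / n_i[ok]))
    den = float(np.sum(tables[ok, 2] * tables[ok, 1] / n_i[ok]))
    return num, den


def classical_mh(table: StratifiedTable) -> ORSummary:
    """Classical Mantel-Haenszel pooled odds ratio over discrete strata.

    Strata with a zero margin contribute zero to both sums and are thereby
    ignored, as in the textbook procedure.  The standard error is the
    Robins-Breslow-Greenland estimator.  When the denominator (or
    numerator) sum is zero the log OR is reported as +inf (or -inf) with an
    undefined SE instead of raising.
    """
    num, den = _mh_sums(table.tables)
    n_used = int(table.tables.sum())
    if den == 0.0 and num == 0.0:
        raise ValueError("Mantel-Haenszel OR undefined: both pooled sums are zero")
    if den == 0.0:
        return ORSummary("classical_mh", np.inf, np.nan, n_used)
    if num == 0.0:
        return ORSummary("classical_mh", -np.inf, np.nan, n_used)
    # statsmodels expects 2x2xk tables [[a, b], [c, d]] pooling sum(ad/n)/sum(bc/n)
    t = np.stack([table.tables[:, [3, 2]], table.tables[:, [1, 0]]], axis=1)
    sm = _SMStratifiedTable(np.moveaxis(t, 0, 2).astype(float))
    return ORSummary("classical_mh", float(sm.logodds_pooled),
                     float(sm.logodds_pooled_se), n_used)


def crude_or(data: Dataset) -> ORSummary:
    """Unadjusted OR from the marginal 2x2 table, with the closed-form
    log-scale SE sqrt(1/n00 + 1/n01 + 1/n10 + 1/n11)."""
    n00, n01, n10, n11 = data.cell_counts().astype(float)
    if min(n00, n01, n10, n11) == 0:
        num, den = n11 * n00, n10 * n01
        log_or = np.inf if den == 0 else (-np.inf if num == 0 else np.log(num / den))
        return ORSummary("crude", log_or, np.nan, data.n)
    log_or = float(np.log(n11 * n00 / (n10 * n01)))
    se = float(np.sqrt(1 / n00 + 1 / n01 + 1 / n10 + 1 / n11))
    return ORSummary("crude", log_or, se, data.n)


def generalized_mh(probs: ClassificationProbs,
                   se_log_or: float = np.nan) -> ORSummary:
    """Generalized Mantel-Haenszel OR from classification probabilities.

    OR = sum_i p11_i p00_i / sum_i p10_i p01_i, summing over subjects.  The
    estimate is a weighted mean of the subject-specific odds ratios
    (p11_i p00_i)/(p10_i p01_i) and therefore lies between their extremes.
    The point estimate carries no SE of its own; the delta-method SE from
    the inference module (or a bootstrap SE) can be attached via
    ``se_log_or``.
    """
    p = probs.p
    num = float(np.sum(p[:, 3] * p[:, 0]))
    den = float(np.sum(p[:, 2] * p[:, 1]))
    return ORSummary("generalized_mh", float(np.log(num / den)),
                     float(se_log_or), probs.n)


def subject_log_ors(params: MultinomialParams, data: Dataset) -> SubjectLogORs:
    """Subject-specific log odds ratios under the fitted model.

    eta_i = (alpha_11 - alpha_10 - alpha_01) + delta' z_i with
    delta = beta_11 - beta_01 - beta_10.  Their average is an alternative
    summary estimator of log(OR); under a constrained fit all eta_i equal
    the constrained-ML estimate.
    """
    if params.m != data.m:
        raise ValueError("covariate dimension mismatch between fit and data")
    eta = params.log_psi + data.z @ params.delta
    return SubjectLogORs(np.asarray(eta, dtype=float))


def avg_subject_specific(params: MultinomialParams, data: Dataset) -> ORSummary:
    """Average-of-subject-specific-log-OR estimator with a delta-method SE.

    The statistic mean(eta_i) is linear in the parameters, with gradient
    the average of the per-subject contrast gradients, so its variance is
    an exact quadratic form in the fit covariance.
    """
    eta = subject_log_ors(params, data)
    m = params.m
    zbar = data.z.mean(axis=0) if m else np.empty(0)
    g = np.zeros(3 + 3 * m)
    g[:3] = (-1.0, -1.0, 1.0)
    if m:
        g[3:3 + m] = -zbar
        g[3 + m:3 + 2 * m] = -zbar
        g[3 + 2 * m:] = zbar
    se = float(np.sqrt(g @ params.covariance @ g))
    return ORSummary("avg_subject_specific", eta.mean, se, data.n)


def constrained_ml_or(params_constrained: MultinomialParams) -> ORSummary:
    """Parametric OR estimate from the homogeneity-constrained fit.

    log(psi) = alpha_11 - alpha_10 - alpha_01; its SE is the square root
    of c' Sigma c with c the (+1, -1, -1) contrast over the intercepts.
    Identical to the generalized Mantel-Haenszel estimate computed from the
    constrained fit's classification probabilities.
    """
    if not params_constrained.constrained:
        raise ValueError("constrained_ml_or requires a homogeneity-constrained fit")
    c = np.zeros(3 + 3 * params_constrained.m)
    c[:3] = (-1.0, -1.0, 1.0)
    se = float(np.sqrt(c @ params_constrained.covariance @ c))
    return ORSummary("constrained_ml", params_constrained.log_psi, se,
                     params_constrained.n)
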