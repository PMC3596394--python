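"""Binary logistic regressions implied by the joint multinomial model.

Factorizing P(X, Y | Z) as P(Y | X, Z) P(X | Z) (or the mirror image)
shows that the joint multinomial logistic model induces a conditional
binary logistic model

    logit P(Y=1 | X, Z) = gamma_0 + gamma_1 X + gamma_2' Z + gamma_3' (X Z)

with gamma_1 = alpha_11 - alpha_10 - alpha_01 and
gamma_3 = beta_11 - beta_10 - beta_01 = delta.  Homogeneity of the odds
ratio (delta = 0) is therefore equivalent to absence of X-by-Z interaction
in the conditional model, and without interaction both conditional
regressions (Y on X,Z and X on Y,Z) estimate the same log(psi) that the
joint model estimates — though not identically in finite samples, because
the conditional fits ignore the marginal distribution of the conditioning
variable.  This module fits both conditional models directly (reusing the
softmax Newton solver in its two-category special case) and exposes the
algebraic map from a joint fit to the induced gamma parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import Dataset
from .estimators import ORSummary
from .inference import HomogeneityTest
from .multinomial import MultinomialParams, fit_categorical_logit

__all__ = ["GammaParams", "fit_binary_logistic", "gamma_from_multinomial"]

_DIRECTIONS = ("y_given_x", "x_given_y")


@dataclass
class GammaParams:
    """Coefficients of a conditional binary logistic model.

    ``gamma1`` is the main-effect log odds ratio; ``gamma3`` the
    interaction slopes whose vanishing expresses homogeneity.
    """

    gamma0: float
    gamma1: float
    gamma2: np.ndarray
    gamma3: np.ndarray | None
    direction: str

    @property
    def m(self) -> int:
        return len(self.gamma2)


def _check_direction(direction: str) -> None:
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")


def fit_binary_logistic(
    data: Dataset,
    direction: str = "y_given_x",
    with_interaction: bool = False,
) -> tuple[GammaParams, ORSummary, HomogeneityTest | None]:
    """Fit Y on X, Z (and optionally X*Z), or the mirrored X on Y, Z.

    Returns the fitted coefficients, an :class:`ORSummary` for the
    main-effect odds ratio exp(gamma_1), and — when the interaction is
    included — a Wald chi-square test of gamma_3 = 0 (df = m), the
    conditional-model counterpart of the homogeneity test.
    """
    _check_direction(direction)
    if direction == "y_given_x":
        resp, pred = data.y, data.x
        label = "logistic_y_on_x"
    else:
        resp, pred = data.x, data.y
        label = "logistic_x_on_y"
    m = data.m
    cols = [np.ones(data.n), pred.astype(float), data.z]
    if with_interaction and m:
        cols.append(pred[:, None] * data.z)
    W = np.column_stack(cols)
    p = W.shape[1]
    theta, cov, _ll, _it, _gn = fit_categorical_logit(W, resp, [np.eye(p)])
    gamma2 = theta[2:2 + m]
    gamma3 = theta[2 + m:] if (with_interaction and m) else None
    gp = GammaParams(float(theta[0]), float(theta[1]), gamma2, gamma3, direction)
    summ = ORSummary(label, float(theta[1]), float(np.sqrt(cov[1, 1])), data.n)
    test = None
    if with_interaction and m:
        V = cov[2 + m:, 2 + m:]
        stat = float(gamma3 @ np.linalg.solve(V, gamma3))
        test = HomogeneityTest("wald_interaction", stat, m,
                               float(stats.chi2.sf(stat, m)))
    return gp, summ, test


def gamma_from_multinomial(params: MultinomialParams,
                           direction: str = "y_given_x") -> GammaParams:
    """Induced conditional-model coefficients of a joint multinomial fit.

    Direction ``y_given_x``: gamma_0 = alpha_01, gamma_2 = beta_01;
    direction ``x_given_y`` mirrors with the (1,0) category.  In both
    directions gamma_1 = alpha_11 - alpha_10 - alpha_01 and
    gamma_3 = delta, so a constrained fit maps to gamma_3 = 0 exactly.
    """
    _check_direction(direction)
    i = 0 if direction == "y_given_x" else 1
    return GammaParams(
        gamma0=float(params.alpha[i]),
        gamma1=params.log_psi,
        gamma2=params.beta[i].copy(),
        gamma3=params.delta.copy(),
        direction=direction,
    )
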