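"""Maximum-likelihood fitting of the four-category multinomial logistic model.

The joint distribution of the binary pair (X, Y) given covariates z is
modelled with softmax probabilities over the categories
(0,0), (0,1), (1,0), (1,1), with (0,0) as reference::

    P(X=x, Y=y | z)  proportional to  exp(alpha_xy + beta_xy' z),
    alpha_00 = 0, beta_00 = 0.

Two fits are provided: the unconstrained model with 3 + 3m free parameters,
and the homogeneity-constrained model in which the (1,1) slope is tied to
the sum of the other two, beta_11 = beta_01 + beta_10 (equivalently
delta = beta_11 - beta_01 - beta_10 = 0, the hypothesis that the
subject-specific odds ratio does not depend on z).  The constrained fit is
implemented by reparameterization, so the same concave likelihood and the
same Newton-Raphson machinery serve both.

Parameter order in the expanded (3 + 3m)-vector and its covariance is
(alpha_01, alpha_10, alpha_11, beta_01, beta_10, beta_11).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

from .data import Dataset

__all__ = [
    "MultinomialParams",
    "ClassificationProbs",
    "FitError",
    "SeparationError",
    "fit_unconstrained",
    "fit_constrained",
    "predict_probs",
    "fit_categorical_logit",
]

# Category codes: 0=(0,0) reference, 1=(0,1), 2=(1,0), 3=(1,1)
CATEGORIES = ("00", "01", "10", "11")

_DIVERGENCE_BOUND = 30.0  # |linear-predictor coefficient| beyond this flags separation


class FitError(RuntimeError):
    """Optimizer failed to converge; carries the last iterate."""

    def __init__(self, message: str, theta=None, grad_norm=None):
        super().__init__(message)
        self.theta = theta
        self.grad_norm = grad_norm


class SeparationError(FitError):
    """Likelihood increases while a coefficient diverges: (quasi-)complete
    separation.  Reduce or recode covariates."""


@dataclass
class MultinomialParams:
    """ML estimates of the multinomial logistic model.

    ``alpha`` holds the three intercepts (alpha_01, alpha_10, alpha_11);
    ``beta`` is a (3, m) array with rows (beta_01, beta_10, beta_11).
    ``covariance`` is (3+3m) x (3+3m) in the order alpha then the three
    beta blocks; for a constrained fit it is the image of the reduced
    (3+2m)-parameter covariance under the constraint map, hence singular.
    """

    alpha: np.ndarray
    beta: np.ndarray
    covariance: np.ndarray
    loglik: float
    converged: bool
    constrained: bool
    n: int
    n_iter: int = 0
    grad_norm: float = np.nan

    @property
    def m(self) -> int:
        return self.beta.shape[1]

    @property
    def delta(self) -> np.ndarray:
        """Heterogeneity contrast delta = beta_11 - beta_01 - beta_10."""
        return self.beta[2] - self.beta[0] - self.beta[1]

    @property
    def theta(self) -> np.ndarray:
        """Expanded parameter vector matching ``covariance``'s ordering."""
        return np.concatenate([self.alpha, self.beta.ravel()])

    @property
    def log_psi(self) -> float:
        """Common log odds ratio at z = 0: alpha_11 - alpha_10 - alpha_01."""
        return float(self.alpha[2] - self.alpha[1] - self.alpha[0])

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "loglik": self.loglik,
            "constrained": self.constrained,
            "converged": self.converged,
            "n": self.n,
        }


@dataclass
class ClassificationProbs:
    """Subject-specific classification probabilities.

    ``p`` is (n, 4) with columns ordered (p00, p01, p10, p11); each row
    sums to one and all entries are strictly interior.
    """

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float).reshape(-1, 4)
        if not np.allclose(self.p.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("probability rows must sum to 1")
        if (self.p <= 0).any() or (self.p >= 1).any():
            raise ValueError("probabilities must be strictly in (0, 1)")

    @property
    def n(self) -> int:
        return self.p.shape[0]


def fit_categorical_logit(
    W: np.ndarray,
    cat: np.ndarray,
    maps: list[np.ndarray],
    max_iter: int = 200,
    tol_loglik: float = 1e-10,
    tol_grad: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, float, int, float]:
    """Newton-Raphson ML fit of a softmax model with linear parameter maps.

    Category ``c`` (1..K-1; 0 is reference) has linear predictor
    ``W @ (maps[c-1] @ theta)``.  The maps express constrained models
    (shared or summed coefficient blocks) in one solver; binary logistic
    regression is the K=2 special case.

    Returns ``(theta, cov_theta, loglik, n_iter, grad_norm)`` where
    ``cov_theta`` is the inverse observed information at the optimum.
    """
    W = np.asarray(W, dtype=float)
    cat = np.asarray(cat, dtype=int)
    n, p = W.shape
    K = len(maps) + 1
    q = maps[0].shape[1]
    maps = [np.asarray(M, dtype=float) for M in maps]
    Y = np.zeros((n, K - 1))
    for c in range(1, K):
        Y[cat == c, c - 1] = 1.0

    def loglik_probs(theta):
        eta = np.column_stack([W @ (M @ theta) for M in maps])
        full = np.column_stack([np.zeros(n), eta])
        P = softmax(full, axis=1)
        # log-sum-exp for numerical stability
        mx = full.max(axis=1)
        lse = mx + np.log(np.exp(full - mx[:, None]).sum(axis=1))
        ll = float((full[np.arange(n), cat] - lse).sum())
        return ll, P[:, 1:]

    def grad_hess(theta, P):
        R = Y - P  # n x (K-1)
        g = np.zeros(q)
        for c, M in enumerate(maps):
            g += M.T @ (W.T @ R[:, c])
        H = np.zeros((q, q))
        for c in range(K - 1):
            for d in range(K - 1):
                w = P[:, c] * ((1.0 if c == d else 0.0) - P[:, d])
                H -= maps[c].T @ (W.T @ (W * w[:, None])) @ maps[d]
        return g, H

    theta = np.zeros(q)
    ll, P = loglik_probs(theta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        g, H = grad_hess(theta, P)
        gnorm = float(np.max(np.abs(g)))
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, -g, rcond=None)[0]
        if float(np.max(np.abs(step))) < 1e-4:
            # quadratic-convergence regime: loglik differences are at noise
            # level, so take the full Newton step unconditionally
            cand = theta + step
            ll_new, P_new = loglik_probs(cand)
        else:
            # step-halving line search on the concave likelihood
            t = 1.0
            for _ in range(40):
                cand = theta + t * step
                ll_new, P_new = loglik_probs(cand)
                if ll_new >= ll - 1e-14:
                    break
                t *= 0.5
            else:
                raise FitError("step-halving failed to find an ascent step",
                               theta=theta, grad_norm=gnorm)
        improved = ll_new - ll
        theta, ll, P = cand, ll_new, P_new
        coef_max = max(float(np.max(np.abs(M @ theta))) for M in maps)
        if coef_max > _DIVERGENCE_BOUND:
            raise SeparationError(
                f"coefficient magnitude {coef_max:.1f} exceeds {_DIVERGENCE_BOUND}: "
                "likely (quasi-)complete separation; reduce covariates",
                theta=theta, grad_norm=gnorm)
        g, _H = grad_hess(theta, P)
        gnorm = float(np.max(np.abs(g)))
        if gnorm < tol_grad:
            break
        # loglik gains below the double-precision floor with an already
        # tiny gradient: the optimum is resolved to machine accuracy
        if abs(improved) < 8 * np.finfo(float).eps * (1 + abs(ll)) and gnorm < 1e-5:
            break
    else:
        raise FitError(
            f"no convergence in {max_iter} iterations (gradient max-norm {gnorm:.2e})",
            theta=theta, grad_norm=gnorm)
    _g, H = grad_hess(theta, P)
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        # collinear design (e.g. a constant covariate): flat likelihood
        # directions get zero variance; identified contrasts are unaffected
        cov = np.linalg.pinv(-H, hermitian=True)
    cov = (cov + cov.T) / 2
    return theta, cov, ll, n_iter, gnorm


def _design(data: Dataset) -> np.ndarray:
    return np.column_stack([np.ones(data.n), data.z])


def _maps_unconstrained(m: int) -> list[np.ndarray]:
    """Selector maps from theta = (a01,a10,a11, b01, b10, b11) to (a_c, b_c)."""
    q = 3 + 3 * m
    maps = []
    for c in range(3):
        M = np.zeros((1 + m, q))
        M[0, c] = 1.0
        M[1:, 3 + c * m: 3 + (c + 1) * m] = np.eye(m)
        maps.append(M)
    return maps


def _maps_constrained(m: int) -> list[np.ndarray]:
    """Maps from theta = (a01,a10,a11, b01, b10) with b11 := b01 + b10."""
    q = 3 + 2 * m
    maps = []
    for c in range(3):
        M = np.zeros((1 + m, q))
        M[0, c] = 1.0
        if c < 2:
            M[1:, 3 + c * m: 3 + (c + 1) * m] = np.eye(m)
        else:
            M[1:, 3: 3 + m] = np.eye(m)
            M[1:, 3 + m: 3 + 2 * m] = np.eye(m)
        maps.append(M)
    return maps


def _expansion_matrix(m: int) -> np.ndarray:
    """Jacobian T of the constraint map: expanded (3+3m) = T @ reduced (3+2m)."""
    T = np.zeros((3 + 3 * m, 3 + 2 * m))
    T[:3, :3] = np.eye(3)
    T[3: 3 + 2 * m, 3: 3 + 2 * m] = np.eye(2 * m)
    T[3 + 2 * m:, 3: 3 + m] = np.eye(m)
    T[3 + 2 * m:, 3 + m: 3 + 2 * m] = np.eye(m)
    return T


def _check_cells(data: Dataset) -> None:
    counts = data.cell_counts()
    if (counts == 0).any():
        empty = [CATEGORIES[i] for i in np.flatnonzero(counts == 0)]
        raise FitError(f"empty (X,Y) cells {empty}: intercepts are not identifiable")


def fit_unconstrained(data: Dataset, **solver_kw) -> MultinomialParams:
    """Unconstrained ML fit of the four-category model (3 + 3m parameters).

    The covariance is the inverse observed information at the optimum.
    Raises :class:`SeparationError` on detected separation and
    :class:`FitError` on non-convergence.
    """
    _check_cells(data)
    m = data.m
    theta, cov, ll, it, gn = fit_categorical_logit(
        _design(data), data.category, _maps_unconstrained(m), **solver_kw)
    alpha = theta[:3]
    beta = theta[3:].reshape(3, m) if m else np.empty((3, 0))
    return MultinomialParams(alpha, beta, cov, ll, True, False, data.n, it, gn)


def fit_constrained(data: Dataset, **solver_kw) -> MultinomialParams:
    """ML fit under the homogeneity constraint beta_11 = beta_01 + beta_10.

    Free parameters are (alpha_01, alpha_10, alpha_11, beta_01, beta_10);
    the returned object is expanded back to the full parameterization, with
    the covariance mapped through the Jacobian of the constraint so that
    downstream delta-method code need not distinguish the two fits.
    """
    _check_cells(data)
    m = data.m
    theta_r, cov_r, ll, it, gn = fit_categorical_logit(
        _design(data), data.category, _maps_constrained(m), **solver_kw)
    T = _expansion_matrix(m)
    theta = T @ theta_r
    cov = T @ cov_r @ T.T
    alpha = theta[:3]
    beta = theta[3:].reshape(3, m) if m else np.empty((3, 0))
    return MultinomialParams(alpha, beta, cov, ll, True, True, data.n, it, gn)


def predict_probs(params: MultinomialParams, data: Dataset) -> ClassificationProbs:
    """Classification probabilities p_xy(z_i) for every subject.

    Rows are the softmax of the three fitted linear predictors and the
    implicit zero of the reference category (0,0).
    """
    if params.m != data.m:
        raise ValueError(f"covariate dimension mismatch: fit has m={params.m}, "
                         f"data has m={data.m}")
    eta = params.alpha[None, :] + data.z @ params.beta.T  # n x 3
    full = np.column_stack([np.zeros(data.n), eta])
    return ClassificationProbs(softmax(full, axis=1))
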