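"""Lightweight Newton–Raphson fitters for logistic and multinomial-logistic
regression.

These back every model fit in the package.  The simulation engine performs on
the order of 10^5 small fits (n of a few hundred, fewer than ~25 parameters)
per design cell, so the fitters are written directly on numpy arrays with
warm-start support and step-halving; they return the coefficient vector, the
observed-information covariance and the maximised log-likelihood, which is all
the pooling statistics need.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit

from .errors import FitFailure, SingularMatrixError

# |beta| beyond this on standardized-ish designs signals quasi-separation
_SEPARATION_BOUND = 25.0


@dataclass
class LogitFit:
    """Result of a binary logistic fit.

    Attributes
    ----------
    beta : (p,) MLE coefficient vector (design order).
    cov : (p, p) inverse observed information at the MLE.
    loglik : maximised log-likelihood.
    n_iter : Newton iterations used.
    """

    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int


def logistic_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Bernoulli log-likelihood at ``beta`` for design ``X`` and 0/1 ``y``."""
    eta = X @ beta
    return float(np.sum(y * log_expit(eta) + (1.0 - y) * log_expit(-eta)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    *,
    ridge: float = 0.0,
    max_iter: int = 60,
    tol: float = 1e-10,
    beta0: np.ndarray | None = None,
) -> LogitFit:
    """Fit a binary logistic regression by Newton–Raphson with step-halving.

    Parameters
    ----------
    X : (n, p) design matrix, intercept column included by the caller.
    y : (n,) outcomes in {0, 1}.
    ridge : optional L2 penalty on the coefficients (used only to stabilise
        conditional imputation models; 0 gives the MLE).
    beta0 : warm start.

    Raises
    ------
    FitFailure
        on non-convergence or detected (quasi-)separation.
    SingularMatrixError
        if the information matrix cannot be solved.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=np.float64)
    eye = np.eye(p)

    def penalised(b: np.ndarray) -> float:
        pen = 0.5 * ridge * float(b @ b)
        return logistic_loglik(b, X, y) - pen

    ll = penalised(beta)
    H = eye
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X.T * w) @ X + ridge * eye
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            # exactly singular (e.g. a constant-zero design column): take the
            # minimum-norm step, which leaves unidentified coefficients at 0
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving keeps the penalised log-likelihood monotone
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new = penalised(cand)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        else:  # pragma: no cover - pathological
            raise FitFailure("logistic step-halving failed to find ascent")
        beta, gain = cand, ll_new - ll
        ll = ll_new
        if abs(gain) < tol and float(np.max(np.abs(grad))) < 1e-6 * (1.0 + abs(ll)):
            break
    else:
        raise FitFailure(f"logistic fit did not converge in {max_iter} iterations")

    if ridge == 0.0 and float(np.max(np.abs(beta))) > _SEPARATION_BOUND:
        raise FitFailure("possible separation: coefficient magnitude exceeded bound")

    mu = expit(X @ beta)
    w = mu * (1.0 - mu)
    H = (X.T * w) @ X + ridge * eye
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        # pseudo-inverse covariance for exactly singular designs; the
        # unidentified directions get zero rows/columns
        cov = np.linalg.pinv(H)
    return LogitFit(beta=beta, cov=cov, loglik=logistic_loglik(beta, X, y), n_iter=it)


@dataclass
class MultinomialFit:
    """Result of a baseline-category multinomial-logistic fit.

    ``beta`` has shape (K-1, p): one row per non-reference category.  ``cov``
    is the (K-1)p x (K-1)p inverse information with rows vec'd category-major.
    """

    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int


def _softmax_probs(B: np.ndarray, X: np.ndarray) -> np.ndarray:
    """(n, K) category probabilities; category 0 is the reference."""
    eta = X @ B.T  # (n, K-1)
    full = np.concatenate([np.zeros((X.shape[0], 1)), eta], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


def multinomial_loglik(B: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    P = _softmax_probs(B, X)
    return float(np.sum(np.log(np.clip(P[np.arange(len(y)), y], 1e-300, None))))


def fit_multinomial(
    X: np.ndarray,
    y: np.ndarray,
    n_categories: int,
    *,
    ridge: float = 0.0,
    max_iter: int = 80,
    tol: float = 1e-9,
    beta0: np.ndarray | None = None,
) -> MultinomialFit:
    """Fit a multinomial (softmax) regression with category 0 as reference.

    ``y`` holds integer codes 0..K-1.  Newton on the full blocked Hessian;
    sizes here are tiny (K <= 5, p <= 15) so dense solves are cheapest.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    n, p = X.shape
    K = int(n_categories)
    if K < 2:
        raise FitFailure("multinomial fit needs at least 2 categories")
    B = np.zeros((K - 1, p)) if beta0 is None else np.array(beta0, dtype=np.float64)
    Y = np.zeros((n, K - 1))
    for c in range(1, K):
        Y[:, c - 1] = y == c

    def penalised(Bm: np.ndarray) -> float:
        return multinomial_loglik(Bm, X, y) - 0.5 * ridge * float(np.sum(Bm * Bm))

    ll = penalised(B)
    H = np.eye((K - 1) * p)
    for it in range(1, max_iter + 1):
        P = _softmax_probs(B, X)[:, 1:]  # (n, K-1)
        grad = (X.T @ (Y - P)).T.reshape(-1) - ridge * B.reshape(-1)
        H = np.empty(((K - 1) * p, (K - 1) * p))
        for c in range(K - 1):
            for d in range(c, K - 1):
                if c == d:
                    w = P[:, c] * (1.0 - P[:, c])
                else:
                    w = -P[:, c] * P[:, d]
                block = (X.T * w) @ X
                H[c * p:(c + 1) * p, d * p:(d + 1) * p] = block
                H[d * p:(d + 1) * p, c * p:(c + 1) * p] = block
        H += ridge * np.eye((K - 1) * p)
        try:
            step = np.linalg.solve(H, grad).reshape(K - 1, p)
        except np.linalg.LinAlgError as exc:
            raise SingularMatrixError("singular information matrix in multinomial fit") from exc
        t = 1.0
        for _ in range(30):
            cand = B + t * step
            ll_new = penalised(cand)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        else:  # pragma: no cover
            raise FitFailure("multinomial step-halving failed to find ascent")
        B, gain = cand, ll_new - ll
        ll = ll_new
        if abs(gain) < tol:
            break
    else:
        raise FitFailure(f"multinomial fit did not converge in {max_iter} iterations")

    if ridge == 0.0 and float(np.max(np.abs(B))) > _SEPARATION_BOUND:
        raise FitFailure("possible separation in multinomial fit")
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise SingularMatrixError("singular information matrix at multinomial optimum") from exc
    return MultinomialFit(beta=B, cov=cov, loglik=multinomial_loglik(B, X, y), n_iter=it)
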