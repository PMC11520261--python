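"""Weighted-L1 penalized logistic regression via FISTA.

Solves ``min_b0,beta  (1/n) * sum log(1 + exp(-y~ * (b0 + X beta)))
+ alpha * sum_j w_j |beta_j|`` with per-column penalty weights ``w_j >= 0``
(``w_j = 0`` means unpenalized, as for forced confounders) and an
unpenalized intercept.  scikit-learn's L1 logistic cannot express
per-column weights or exemptions, hence this small solver; it is the
second stage of the adaptive LASSO, warm-started along a descending alpha
path.
"""

from __future__ import annotations

import numpy as np

from drclaims.exceptions import ConvergenceError

__all__ = ["fit_weighted_l1_logistic", "logistic_path", "logistic_deviance"]


def _log1pexp(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    small = x <= 30
    out[small] = np.log1p(np.exp(x[small]))
    out[~small] = x[~small]
    return out


def _expit(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def logistic_deviance(intercept: float, beta: np.ndarray, X, y) -> float:
    """Mean deviance (-2/n * log-likelihood)."""
    eta = intercept + np.asarray(X, dtype=float) @ beta
    y = np.asarray(y, dtype=float)
    return float(2.0 * np.mean(_log1pexp(eta) - y * eta))


def fit_weighted_l1_logistic(
    X: np.ndarray,
    y: np.ndarray,
    penalty_weights: np.ndarray,
    alpha: float,
    *,
    beta0: np.ndarray | None = None,
    intercept0: float = 0.0,
    max_iter: int = 500,
    tol: float = 1e-7,
    lipschitz: float | None = None,
) -> tuple[float, np.ndarray, bool]:
    """One FISTA solve.  Returns ``(intercept, beta, converged)``.

    ``tol`` is on the relative change of the full coefficient vector
    between iterations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.asarray(penalty_weights, dtype=float)

    if lipschitz is None:
        # ||[1 X]||_2^2 / (4n) upper bound via power iteration
        lipschitz = _lipschitz_bound(X)
    step = 1.0 / lipschitz

    beta = np.zeros(p) if beta0 is None else beta0.copy()
    b0 = intercept0
    zb, zb0 = beta.copy(), b0
    t_mom = 1.0
    thresh = step * alpha * w

    for _ in range(max_iter):
        eta = zb0 + X @ zb
        resid = _expit(eta) - y
        grad_b = X.T @ resid / n
        grad_0 = resid.mean()
        new_beta = zb - step * grad_b
        new_beta = np.sign(new_beta) * np.maximum(np.abs(new_beta) - thresh, 0.0)
        new_b0 = zb0 - step * grad_0

        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        accel = (t_mom - 1.0) / t_next
        zb = new_beta + accel * (new_beta - beta)
        zb0 = new_b0 + accel * (new_b0 - b0)
        t_mom = t_next

        delta = np.sqrt(np.sum((new_beta - beta) ** 2) + (new_b0 - b0) ** 2)
        scale = max(1.0, np.sqrt(np.sum(new_beta**2) + new_b0**2))
        beta, b0 = new_beta, new_b0
        if delta / scale < tol:
            return b0, beta, True
    return b0, beta, False


def _lipschitz_bound(X: np.ndarray) -> float:
    n = X.shape[0]
    Xa = np.column_stack([np.ones(n), X])
    v = np.ones(Xa.shape[1]) / np.sqrt(Xa.shape[1])
    for _ in range(30):
        v = Xa.T @ (Xa @ v)
        nv = np.linalg.norm(v)
        if nv == 0:
            return 1.0
        v = v / nv
    return float(nv / (4.0 * n) * 1.01)


def logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    penalty_weights: np.ndarray,
    alphas: np.ndarray,
    *,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray, list[bool]]:
    """Warm-started fits along a descending alpha path.

    Returns ``(intercepts, betas, converged_flags)`` with ``betas`` of
    shape ``(len(alphas), p)``.  Raises :class:`ConvergenceError` only if a
    fit is wildly diverging (non-finite coefficients).
    """
    X = np.asarray(X, dtype=float)
    lipschitz = _lipschitz_bound(X)
    p = X.shape[1]
    beta = np.zeros(p)
    b0 = float(np.log(np.mean(y) / (1 - np.mean(y)))) if 0 < np.mean(y) < 1 else 0.0
    intercepts = np.empty(len(alphas))
    betas = np.empty((len(alphas), p))
    flags = []
    for k, a in enumerate(alphas):
        b0, beta, ok = fit_weighted_l1_logistic(
            X, y, penalty_weights, a,
            beta0=beta, intercept0=b0,
            max_iter=max_iter, tol=tol, lipschitz=lipschitz,
        )
        if not np.all(np.isfinite(beta)):
            raise ConvergenceError(
                f"penalized logistic fit diverged at alpha={a:.3g}"
            )
        intercepts[k] = b0
        betas[k] = beta
        flags.append(ok)
    return intercepts, betas, flags
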