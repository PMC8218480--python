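"""Weighted multinomial logistic regression, reference-category form.

Small Newton-Raphson solver used by the transition estimators.  The model is

    ln(p_j / p_0) = x' beta_j,   j = 1..D   (class 0 is the reference)

fitted by weighted maximum likelihood.  The problem sizes here are tiny
(<= 4 destinations x 4 terms) but the bootstrap refits it hundreds of
thousands of times, so the solver supports warm starts and uses analytic
gradients and Hessians.  A minute Levenberg ridge (1e-10) keeps the Newton
step defined under near-separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MNLogitResult", "fit_mnlogit", "softmax_reference"]


@dataclass
class MNLogitResult:
    coef: np.ndarray          # (D, T): row j are the coefficients of class j+1
    converged: bool
    n_iter: int
    grad_norm: float
    loglik: float


def softmax_reference(eta: np.ndarray) -> np.ndarray:
    """Probabilities for reference-category logits.

    ``eta`` has shape (..., D) of non-reference linear predictors; returns
    shape (..., D + 1) with the reference class first.  Handles -inf
    entries (structural zeros) exactly.
    """
    eta = np.asarray(eta, dtype=float)
    full = np.concatenate([np.zeros(eta.shape[:-1] + (1,)), eta], axis=-1)
    m = np.max(full, axis=-1, keepdims=True)
    ex = np.exp(full - m)
    return ex / ex.sum(axis=-1, keepdims=True)


def _nll_grad_hess(beta, X, Y, w, need_hess=True):
    n, T = X.shape
    D = Y.shape[1] - 1
    eta = X @ beta.reshape(D, T).T          # (n, D)
    P = softmax_reference(eta)              # (n, D+1)
    ll = np.sum(w * np.log(np.clip((P * Y).sum(axis=1), 1e-300, None)))
    resid = Y[:, 1:] - P[:, 1:]             # (n, D)
    grad = (X.T @ (w[:, None] * resid)).T.ravel()   # (D*T,)
    if not need_hess:
        return -ll, -grad, None
    H = np.empty((D * T, D * T))
    WP = w[:, None] * P[:, 1:]
    for j in range(D):
        for k in range(j, D):
            wjk = WP[:, j] * ((j == k) - P[:, 1 + k])
            block = X.T @ (wjk[:, None] * X)
            H[j * T:(j + 1) * T, k * T:(k + 1) * T] = block
            if k != j:
                H[k * T:(k + 1) * T, j * T:(j + 1) * T] = block
    return -ll, -grad, H


def fit_mnlogit(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    n_classes: int | None = None,
    start: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> MNLogitResult:
    """Fit a weighted multinomial logit with class 0 as reference.

    Parameters
    ----------
    X : (n, T) design matrix (include the intercept column yourself).
    y : (n,) integer class labels in 0..n_classes-1.
    weights : optional positive case weights.
    start : optional (D, T) warm-start coefficients.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, T = X.shape
    K = int(n_classes if n_classes is not None else y.max() + 1)
    D = K - 1
    if D < 1:
        raise ValueError("need at least two classes")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    Y = np.zeros((n, K))
    Y[np.arange(n), y] = 1.0

    beta = np.zeros(D * T) if start is None else np.asarray(start, dtype=float).ravel().copy()
    nll, grad, H = _nll_grad_hess(beta, X, Y, w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gnorm = np.max(np.abs(grad))
        if gnorm < tol * max(1.0, w.sum()):
            converged = True
            break
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(D * T), -grad)
        except np.linalg.LinAlgError:
            step = -grad
        # step halving on the objective
        lam = 1.0
        for _ in range(40):
            cand = beta + lam * step
            nll_c, grad_c, H_c = _nll_grad_hess(cand, X, Y, w)
            if nll_c <= nll + 1e-12 * abs(nll):
                beta, nll, grad, H = cand, nll_c, grad_c, H_c
                break
            lam *= 0.5
        else:  # no improving step: treat as converged-at-boundary
            break
    gnorm = float(np.max(np.abs(grad)))
    converged = converged or gnorm < 1e-6 * max(1.0, w.sum())
    return MNLogitResult(
        coef=beta.reshape(D, T),
        converged=converged,
        n_iter=it,
        grad_norm=gnorm,
        loglik=-nll,
    )
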