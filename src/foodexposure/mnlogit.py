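"""Weighted multinomial logit maximum likelihood.

Baseline-category logit with continuous (calibration) weights: the
log-likelihood is sum_i w_i [eta_{i,y_i} - log sum_k exp(eta_ik)] with the
baseline class's linear predictor fixed at 0.  Newton-Raphson with the
analytic gradient and Hessian; Wald covariance from the inverse observed
information at the optimum.  Estimates are invariant to rescaling all
weights by a constant up to the covariance scale, which is why calibration
weights are normalized to mean 1 upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, SeparationError

#: a |log-odds| this large on a categorical design implies quasi-separation
_SEPARATION_BOUND = 30.0


@dataclass
class MNLogitFit:
    """Flattened parameters are ordered class-major: (K-1, p) row-wise."""

    params: np.ndarray  # (K-1, p)
    cov: np.ndarray  # ((K-1)*p, (K-1)*p)
    llf: float
    converged: bool
    n_iter: int
    n_classes: int

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov)).reshape(self.params.shape)


def _log_likelihood(B, X, y_onehot, w):
    eta = X @ B.T  # (n, K-1)
    # log-sum-exp over {0} ∪ classes, baseline eta = 0
    m = np.maximum(eta.max(axis=1), 0.0)
    lse = m + np.log(np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1))
    return float(np.sum(w * ((y_onehot[:, 1:] * eta).sum(axis=1) - lse)))


def _probs(B, X):
    eta = X @ B.T
    m = np.maximum(eta.max(axis=1), 0.0)
    e = np.exp(eta - m[:, None])
    e0 = np.exp(-m)
    denom = e0 + e.sum(axis=1)
    P = np.empty((X.shape[0], B.shape[0] + 1))
    P[:, 0] = e0 / denom
    P[:, 1:] = e / denom[:, None]
    return P


def fit_mnlogit(
    y: np.ndarray,
    X: np.ndarray,
    weights: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    ridge: float = 0.0,
) -> MNLogitFit:
    """Fit a weighted baseline-category multinomial logit.

    Parameters
    ----------
    y
        Integer class labels 0..K-1; class 0 is the baseline.
    X
        Design matrix including the intercept column.
    weights
        Positive case weights (default all ones).
    ridge
        Optional tiny L2 penalty on the coefficients, used as the
        quasi-separation fallback in screening; 0 for plain ML.
    """
    y = np.asarray(y, dtype=int)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    K = int(y.max()) + 1
    if K < 2:
        raise ValueError("outcome must have at least 2 classes")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    Y = np.zeros((n, K))
    Y[np.arange(n), y] = 1.0

    B = np.zeros((K - 1, p))
    ll = _log_likelihood(B, X, Y, w) - 0.5 * ridge * np.sum(B**2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        P = _probs(B, X)
        # gradient, class-major
        G = np.empty((K - 1, p))
        for k in range(1, K):
            G[k - 1] = X.T @ (w * (Y[:, k] - P[:, k]))
        g = G.ravel() - ridge * B.ravel()
        # Hessian of the negative log-likelihood (block structure)
        H = np.empty(((K - 1) * p, (K - 1) * p))
        for k in range(1, K):
            for l in range(1, K):
                d = w * P[:, k] * ((1.0 if k == l else 0.0) - P[:, l])
                H[(k - 1) * p : k * p, (l - 1) * p : l * p] = X.T @ (
                    d[:, None] * X
                )
        H += ridge * np.eye((K - 1) * p)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # backtracking line search on the (penalized) log-likelihood
        lam = 1.0
        for _ in range(30):
            B_new = B + lam * step.reshape(K - 1, p)
            ll_new = _log_likelihood(B_new, X, Y, w) - 0.5 * ridge * np.sum(
                B_new**2
            )
            if ll_new >= ll - 1e-12:
                break
            lam *= 0.5
        B, ll_prev, ll = B_new, ll, ll_new
        if np.max(np.abs(g)) < 1e-6 and abs(ll - ll_prev) < tol * (
            1 + abs(ll)
        ):
            converged = True
            break
    if ridge == 0.0 and np.max(np.abs(B)) > _SEPARATION_BOUND:
        raise SeparationError(
            "quasi-complete separation: unbounded coefficient "
            f"(max |beta| = {np.max(np.abs(B)):.1f})"
        )
    if not converged:
        raise ConvergenceError(
            f"multinomial fit did not converge in {max_iter} iterations "
            f"(max |score| = {np.max(np.abs(g)):.2e})"
        )
    P = _probs(B, X)
    H = np.empty(((K - 1) * p, (K - 1) * p))
    for k in range(1, K):
        for l in range(1, K):
            d = w * P[:, k] * ((1.0 if k == l else 0.0) - P[:, l])
            H[(k - 1) * p : k * p, (l - 1) * p : l * p] = X.T @ (
                d[:, None] * X
            )
    H += ridge * np.eye((K - 1) * p)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return MNLogitFit(
        params=B,
        cov=cov,
        llf=_log_likelihood(B, X, Y, w),
        converged=converged,
        n_iter=it,
        n_classes=K,
    )


def fit_intercept_only(
    y: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Log-likelihood of the intercept-only model (closed form).

    The weighted MLE class probabilities are the weighted class frequencies.
    """
    y = np.asarray(y, dtype=int)
    K = int(y.max()) + 1
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    totals = np.bincount(y, weights=w, minlength=K)
    probs = totals / totals.sum()
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    return float(np.sum(totals[totals > 0] * logp[totals > 0]))
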