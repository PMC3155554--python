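"""Internal Breslow partial-likelihood engine.

Small, fast numpy routines for the Cox partial likelihood under the Breslow
tie convention, with offset support.  These back the componentwise boosting
and the BIC model averaging, where thousands of small fits / one-dimensional
updates are needed and a full-featured fitter would dominate the runtime.
Public-facing multivariate fits go through :func:`cnisig.cox_models.cox_fit`
(lifelines, Efron ties); the two are cross-checked in the test suite.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "SurvivalData",
    "breslow_loglik",
    "componentwise_score_info",
    "newton_fit",
]

_MAX_ABS_BETA = 50.0


class SurvivalData:
    """Pre-sorted survival data for repeated partial-likelihood evaluation.

    Sorting and the tied-time bookkeeping are done once; every evaluation is
    then a handful of vectorised cumulative sums.
    """

    def __init__(self, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if time.ndim != 1 or time.shape != event.shape:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if np.any(time <= 0):
            raise ValueError("survival times must be positive")
        if event.sum() == 0:
            raise ValueError("at least one event is required")
        self.n = time.size
        self.order = np.argsort(time, kind="stable")
        self.time = time[self.order]
        self.event = event[self.order].astype(bool)
        # risk set of sample i = all j with time_j >= time_i; with ties this
        # starts at the first index sharing time_i
        self.first_of_time = np.searchsorted(self.time, self.time, side="left")
        self.n_events = int(self.event.sum())

    def sort(self, a):
        """Reorder an (n,) or (n, p) array into internal time order."""
        return np.asarray(a, dtype=float)[self.order]

    def _risk_revcumsum(self, values):
        # reverse cumulative sum evaluated at each sample's risk-set start
        rc = np.cumsum(values[::-1], axis=0)[::-1]
        return rc[self.first_of_time]


def breslow_loglik(sd: SurvivalData, eta_sorted: np.ndarray) -> float:
    """Breslow log partial likelihood at linear predictor ``eta`` (sorted)."""
    eta = eta_sorted - eta_sorted.max()  # guard exp overflow; PL is shift-invariant
    w = np.exp(eta)
    denom = sd._risk_revcumsum(w)
    ev = sd.event
    return float(np.sum(eta[ev] - np.log(denom[ev])))


def componentwise_score_info(sd: SurvivalData, X_sorted: np.ndarray,
                             eta_sorted: np.ndarray):
    """Per-column score and diagonal information at the current predictor.

    Returns ``(U, I)`` where ``U[j]`` and ``I[j]`` are the first and second
    derivative (negated) of the Breslow log partial likelihood with respect to
    a one-parameter update of column ``j`` alone, evaluated at 0.
    """
    eta = eta_sorted - eta_sorted.max()
    w = np.exp(eta)
    B = sd._risk_revcumsum(w)
    A = sd._risk_revcumsum(w[:, None] * X_sorted)
    C = sd._risk_revcumsum(w[:, None] * X_sorted ** 2)
    ev = sd.event
    mean = A[ev] / B[ev, None]
    U = np.sum(X_sorted[ev] - mean, axis=0)
    I = np.sum(C[ev] / B[ev, None] - mean ** 2, axis=0)
    return U, I


def _loglik_grad_hess(sd, X, eta):
    eta = eta - eta.max()
    w = np.exp(eta)
    B = sd._risk_revcumsum(w)
    A = sd._risk_revcumsum(w[:, None] * X)
    wXX = w[:, None, None] * X[:, :, None] * X[:, None, :]
    C = sd._risk_revcumsum(wXX.reshape(sd.n, -1)).reshape(sd.n, X.shape[1], X.shape[1])
    ev = sd.event
    mean = A[ev] / B[ev, None]
    ll = float(np.sum(eta[ev] - np.log(B[ev])))
    grad = np.sum(X[ev] - mean, axis=0)
    hess = np.sum(C[ev] / B[ev, None, None]
                  - mean[:, :, None] * mean[:, None, :], axis=0)
    return ll, grad, hess


def newton_fit(sd: SurvivalData, X_sorted: np.ndarray, offset_sorted=None,
               beta0=None, tol: float = 1e-8, max_iter: int = 60):
    """Newton–Raphson maximisation of the Breslow partial likelihood.

    Returns ``(beta, loglik, inv_info)``.  ``X_sorted``/``offset_sorted`` must
    already be in the data's internal time order.  Monotone-likelihood
    trajectories are capped at |beta| = 50 with a warning.
    """
    n, p = X_sorted.shape
    offset = np.zeros(n) if offset_sorted is None else offset_sorted
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)
    ll, grad, hess = _loglik_grad_hess(sd, X_sorted, offset + X_sorted @ beta)
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular information matrix (collinear covariates?)") from exc
        # step-halving keeps the likelihood monotone
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new = breslow_loglik(sd, offset + X_sorted @ cand)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2
        beta = cand
        if np.any(np.abs(beta) > _MAX_ABS_BETA):
            warnings.warn("monotone partial likelihood: coefficients capped",
                          RuntimeWarning, stacklevel=2)
            beta = np.clip(beta, -_MAX_ABS_BETA, _MAX_ABS_BETA)
            ll, grad, hess = _loglik_grad_hess(sd, X_sorted, offset + X_sorted @ beta)
            break
        ll, grad, hess = _loglik_grad_hess(sd, X_sorted, offset + X_sorted @ beta)
    try:
        inv_info = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        inv_info = np.full((p, p), np.nan)
    return beta, ll, inv_info
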