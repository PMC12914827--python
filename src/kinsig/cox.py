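"""Cox proportional-hazards engine.

Newton–Raphson maximization of the partial likelihood with Efron (or
Breslow) tie handling, written directly in NumPy so that the thousands
of small fits in the calibration simulations stay cheap. Also provides
Schoenfeld residuals for the proportional-hazards check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class CoxConvergenceError(RuntimeError):
    pass


@dataclass
class CoxEngineResult:
    beta: np.ndarray
    cov: np.ndarray  # inverse observed information
    loglik: float
    loglik_null: float
    n_iter: int
    converged: bool
    flags: list[str]


def _prepare(times, events, X):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    order = np.argsort(times, kind="stable")
    return times[order], events[order], X[order]


def _group_starts(times, events):
    """Start index, count and event-member slices per distinct event time."""
    groups = []
    n = len(times)
    i = 0
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        ev = [k for k in range(i, j) if events[k] == 1]
        if ev:
            groups.append((i, ev))
        i = j
    return groups


def _loglik_grad_hess(beta, times, events, X, groups, ties="efron", want_hess=True):
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -200, 200)
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]

    # Suffix sums: risk set at the i-th sorted time is samples i..n-1.
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1] if want_hess else None

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for start, ev_idx in groups:
        d = len(ev_idx)
        ll += float(eta[ev_idx].sum())
        grad += X[ev_idx].sum(axis=0)
        s0r, s1r = s0[start], s1[start]
        s2r = s2[start] if want_hess else None
        if ties == "efron" and d > 1:
            s0d = w[ev_idx].sum()
            s1d = wx[ev_idx].sum(axis=0)
            s2d = wxx[ev_idx].sum(axis=0) if want_hess else None
        else:
            s0d = 0.0
            s1d = np.zeros(p)
            s2d = np.zeros((p, p)) if want_hess else None
        for j in range(d):
            f = j / d if (ties == "efron" and d > 1) else 0.0
            a0 = s0r - f * s0d
            a1 = s1r - f * s1d
            ll -= np.log(a0)
            grad -= a1 / a0
            if want_hess:
                a2 = s2r - f * s2d
                hess -= a2 / a0 - np.outer(a1, a1) / a0**2
    return ll, grad, hess


def fit_cox(
    times,
    events,
    X,
    ties: str = "efron",
    max_iter: int = 60,
    tol: float = 1e-8,
) -> CoxEngineResult:
    """Maximize the Cox partial likelihood by damped Newton iterations.

    Convergence requires the max-norm of the score to drop below ``tol``.
    Monotone likelihood (perfect separation) is flagged rather than
    raised, with the coefficient left at its last (large) value.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    times, events, X = _prepare(times, events, X)
    n, p = X.shape
    if events.sum() < 1:
        raise ValueError("no events in the data")
    sds = X.std(axis=0)
    if np.any(sds <= 0):
        raise ValueError("constant covariate in design matrix")
    groups = _group_starts(times, events)

    beta = np.zeros(p)
    ll_null, _, _ = _loglik_grad_hess(beta, times, events, X, groups, ties, want_hess=False)
    ll, grad, hess = _loglik_grad_hess(beta, times, events, X, groups, ties)
    flags: list[str] = []
    converged = False
    it = 0
    # Absolute gradient tolerance is unreachable at large n (float summation
    # noise grows with n), so a stalled likelihood with a small gradient also
    # counts as converged.
    grad_floor = max(tol, 1e-9 * n)
    for it in range(1, max_iter + 1):
        info = -hess
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            flags.append("singular_information")
            break
        # Step-halving line search on the partial likelihood.
        scale = 1.0
        for _ in range(20):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = _loglik_grad_hess(
                cand, times, events, X, groups, ties
            )
            if ll_new >= ll - 1e-10:
                break
            scale /= 2.0
        ll_prev = ll
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        gmax = np.max(np.abs(grad))
        if gmax < tol:
            converged = True
            break
        if abs(ll - ll_prev) < 1e-10 * max(1.0, abs(ll)) and gmax < grad_floor:
            converged = True
            break
    if not converged:
        flags.append("no_convergence")
    if np.any(np.abs(beta) > 15):
        flags.append("monotone_likelihood")
    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        flags.append("singular_information")
    return CoxEngineResult(
        beta=beta,
        cov=cov,
        loglik=float(ll),
        loglik_null=float(ll_null),
        n_iter=it,
        converged=converged,
        flags=flags,
    )


def schoenfeld_residuals(times, events, X, beta):
    """Unscaled Schoenfeld residuals at each event, in event-time order.

    Residual for an event at time t is x_i minus the risk-set weighted
    covariate mean at t. Returns ``(event_times, residuals)`` with one
    row per event.
    """
    times, events, X = _prepare(times, events, X)
    eta = np.clip(X @ beta, -200, 200)
    w = np.exp(eta)
    wx = w[:, None] * X
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    groups = _group_starts(times, events)
    rows, ts = [], []
    for start, ev_idx in groups:
        xbar = s1[start] / s0[start]
        for i in ev_idx:
            rows.append(X[i] - xbar)
            ts.append(times[i])
    return np.asarray(ts), np.asarray(rows)
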