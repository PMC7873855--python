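"""Cox proportional-hazards partial likelihood with Breslow baseline.

Small, allocation-light Newton solver used both for the censoring model
behind the IPCW weights (fitted once per tree on the structure sample)
and for the Cox plug-in comparison estimator.  Ties are handled by
Breslow's method, matching the Breslow baseline cumulative hazard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoxFit", "fit_cox", "baseline_cumhaz_at", "survival_at"]

_ETA_CLIP = 500.0  # guards exp() overflow on adversarial inputs


@dataclass(frozen=True)
class CoxFit:
    """Fitted Cox model: coefficients plus Breslow baseline step function."""

    beta: np.ndarray
    baseline_times: np.ndarray       # sorted unique event times
    baseline_cumhaz: np.ndarray      # Breslow cumulative hazard at those times
    iterations: int
    converged: bool
    log_likelihood: float
    degenerate: bool = False         # no events at all: hazard identically 0

    @property
    def p(self) -> int:
        return self.beta.shape[0]


def _loglik_score_info(X, eta, order, first_tie, event_sorted, want_hessian=True):
    """Breslow log partial likelihood, score and information.

    ``order`` sorts times ascending; ``first_tie[i]`` is the first index of
    the tie block of sorted position ``i`` so suffix sums taken there cover
    the full risk set {j : Z_j >= Z_i}.
    """
    theta = np.exp(np.clip(eta[order], -_ETA_CLIP, _ETA_CLIP))
    Xs = X[order]
    # suffix cumulative sums over the risk set
    s0 = np.cumsum(theta[::-1])[::-1]
    s1 = np.cumsum((theta[:, None] * Xs)[::-1], axis=0)[::-1]
    ev = event_sorted
    s0e = s0[first_tie[ev]]
    s1e = s1[first_tie[ev]]
    xbar = s1e / s0e[:, None]
    ll = float(np.sum(eta[order][ev] - np.log(s0e)))
    score = Xs[ev].sum(axis=0) - xbar.sum(axis=0)
    if not want_hessian:
        return ll, score, None
    p = X.shape[1]
    outer = (theta[:, None, None] * Xs[:, :, None] * Xs[:, None, :])
    s2 = np.cumsum(outer[::-1], axis=0)[::-1]
    s2e = s2[first_tie[ev]]
    info = (s2e / s0e[:, None, None]).sum(axis=0) - np.einsum(
        "ij,ik->jk", xbar, xbar
    )
    return ll, score, info


def fit_cox(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """Maximize the Breslow partial likelihood by Newton–Raphson.

    Step-halving keeps the log-likelihood monotone; convergence when the
    relative change in log partial likelihood drops below ``tol``.  With no
    events the degenerate fit (hazard identically zero) is returned.
    """
    X = np.asarray(X, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    n, p = X.shape
    if not event.any():
        return CoxFit(
            beta=np.zeros(p),
            baseline_times=np.empty(0),
            baseline_cumhaz=np.empty(0),
            iterations=0,
            converged=True,
            log_likelihood=0.0,
            degenerate=True,
        )
    order = np.argsort(time, kind="stable")
    ts = time[order]
    first_tie = np.searchsorted(ts, ts, side="left")
    event_sorted = event[order]

    beta = np.zeros(p)
    ll, score, info = _loglik_score_info(X, X @ beta, order, first_tie, event_sorted)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(info, score, rcond=None)
        # step-halving: insist on non-decreasing log partial likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, score_new, info_new = _loglik_score_info(
                X, X @ cand, order, first_tie, event_sorted
            )
            if ll_new >= ll or not np.isfinite(ll):
                break
            scale *= 0.5
        else:
            # step-halving exhausted: already at a stationary point
            converged = bool(np.abs(score).max() < 1e-6 * (1 + np.abs(ll)))
            break
        rel = abs(ll_new - ll) / (abs(ll) + 1e-300)
        beta, ll, score, info = cand, ll_new, score_new, info_new
        if rel < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"Cox partial likelihood did not converge in {max_iter} iterations "
            f"(log-lik {ll:.6g}, |score| {np.abs(score).max():.3g})"
        )

    # Breslow baseline on the event times
    theta = np.exp(np.clip((X @ beta)[order], -_ETA_CLIP, _ETA_CLIP))
    s0 = np.cumsum(theta[::-1])[::-1]
    ev_times = ts[event_sorted]
    uniq, first = np.unique(ev_times, return_index=True)
    counts = np.diff(np.append(first, ev_times.size))
    # s0 at the first index of each unique event time's tie block
    pos = np.searchsorted(ts, uniq, side="left")
    cumhaz = np.cumsum(counts / s0[pos])
    return CoxFit(
        beta=beta,
        baseline_times=uniq,
        baseline_cumhaz=cumhaz,
        iterations=it,
        converged=True,
        log_likelihood=ll,
    )


def baseline_cumhaz_at(fit: CoxFit, t: np.ndarray, left_continuous: bool = True):
    """Breslow cumulative baseline hazard Λ̂₀(t) (or Λ̂₀(t⁻))."""
    t = np.asarray(t, float)
    side = "left" if left_continuous else "right"
    idx = np.searchsorted(fit.baseline_times, t, side=side) - 1
    out = np.where(idx >= 0, fit.baseline_cumhaz[np.maximum(idx, 0)], 0.0)
    return out


def survival_at(fit: CoxFit, t, x, left_continuous: bool = True) -> np.ndarray:
    """exp(−Λ̂₀(t⁻)·exp(x·β̂)) — conditional survival under the fit.

    ``t`` and ``x`` broadcast row-wise; the degenerate (no-event) fit
    returns 1 everywhere.
    """
    t = np.atleast_1d(np.asarray(t, float))
    x = np.atleast_2d(np.asarray(x, float))
    if fit.degenerate:
        return np.ones(max(t.shape[0], x.shape[0]))
    lam = baseline_cumhaz_at(fit, t, left_continuous)
    eta = np.clip(x @ fit.beta, -_ETA_CLIP, _ETA_CLIP)
    return np.exp(-lam * np.exp(eta))
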