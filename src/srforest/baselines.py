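"""Comparison estimators of heterogeneous RMST.

Four families are provided:

* ``km_survival`` + ``rmst_from_survival`` — covariate-free Kaplan–Meier
  plug-in (``Naive.km``): the area under the product-limit survival
  curve up to L.
* ``cox_rmst`` — proportional-hazards plug-in (``Naive.Cox``): Cox fit
  for the event time, Breslow baseline, area under
  ``S(u|x) = exp(−Λ̂₀(u) e^{x β̂})``.
* ``fit_ee_rmst`` with ``censoring_mode="km"`` — the weighted
  estimating-equation regression ``g[μᴸ(x)] = β'(1, x)`` assuming
  covariate-independent censoring (KM weights).
* ``fit_ee_rmst`` with ``censoring_mode="cox"`` — the same regression
  with Cox-modeled (covariate-dependent) censoring weights.

Identity and exponential links are supported for the estimating-equation
models; predictions are clipped to [0, L].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .cox import fit_cox, survival_at
from .data import RestrictedDataset, SurvivalDataset
from .ipcw import DEFAULT_WEIGHT_FLOOR, compute_ipcw, fit_cox_censoring

__all__ = [
    "StepSurvival",
    "km_survival",
    "km_censoring_survival",
    "rmst_from_survival",
    "cox_rmst",
    "EeRmstModel",
    "fit_ee_rmst",
    "predict_ee_rmst",
]


@dataclass(frozen=True)
class StepSurvival:
    """Right-continuous step survival function starting at 1."""

    times: np.ndarray
    surv: np.ndarray

    def at(self, t, left_continuous: bool = False) -> np.ndarray:
        t = np.asarray(t, float)
        side = "left" if left_continuous else "right"
        idx = np.searchsorted(self.times, t, side=side) - 1
        return np.where(idx >= 0, self.surv[np.maximum(idx, 0)], 1.0)


def km_survival(data: SurvivalDataset, event_is_censoring: bool = False) -> StepSurvival:
    """Product-limit estimator of the survival function of T (or of C)."""
    events = (data.delta == 0) if event_is_censoring else (data.delta == 1)
    kmf = KaplanMeierFitter().fit(data.Z, event_observed=events.astype(int))
    sf = kmf.survival_function_
    times = sf.index.to_numpy(float)
    surv = sf.iloc[:, 0].to_numpy(float)
    keep = times > 0
    return StepSurvival(times=times[keep], surv=surv[keep])


def km_censoring_survival(data: SurvivalDataset) -> StepSurvival:
    """KM estimate of ``1 − G(t)``: censoring treated as the event."""
    return km_survival(data, event_is_censoring=True)


def rmst_from_survival(surv: StepSurvival, L: float) -> float:
    """Exact area under a right-continuous step survival curve on [0, L]."""
    if not L > 0:
        raise ValueError(f"L must be positive, got {L}")
    ts = surv.times[surv.times < L]
    vals = surv.surv[: ts.shape[0]]
    edges = np.concatenate([[0.0], ts, [L]])
    heights = np.concatenate([[1.0], vals])
    return float(np.sum(heights * np.diff(edges)))


def cox_rmst(data: SurvivalDataset, L: float, x: np.ndarray) -> np.ndarray:
    """Cox plug-in hRMST: ∫₀ᴸ exp(−Λ̂₀(u)·e^{xβ̂}) du for each query row."""
    if not (data.delta == 1).any():
        raise ValueError("Cox plug-in needs at least one event")
    fit = fit_cox(data.X, data.Z, data.delta == 1)
    x = np.atleast_2d(np.asarray(x, float))
    eta = np.clip(x @ fit.beta, -500, 500)
    ts = fit.baseline_times[fit.baseline_times < L]
    ch = fit.baseline_cumhaz[: ts.shape[0]]
    edges = np.concatenate([[0.0], ts, [L]])
    widths = np.diff(edges)
    # survival after each jump, per query; the first segment has S = 1
    cumh = np.concatenate([[0.0], ch])
    S = np.exp(-np.outer(np.exp(eta), cumh))
    return S @ widths


@dataclass(frozen=True)
class EeRmstModel:
    """Weighted estimating-equation RMST regression g[μᴸ(x)] = β'(1, x)."""

    link: str  # "identity" | "exp"
    beta: np.ndarray  # intercept first
    censoring_mode: str  # "km" | "cox"
    L: float
    iterations: int
    converged: bool


def _ee_weights(rdata: RestrictedDataset, censoring_mode: str, floor: float):
    if censoring_mode == "cox":
        model = fit_cox_censoring(rdata.base)
        return compute_ipcw(rdata, model, floor=floor).w
    if censoring_mode == "km":
        sc = km_censoring_survival(rdata.base)
        surv = sc.at(rdata.ZL, left_continuous=True)
        return rdata.deltaL / np.maximum(surv, floor)
    raise ValueError(f"unknown censoring_mode {censoring_mode!r}")


def fit_ee_rmst(
    rdata: RestrictedDataset,
    link: str = "identity",
    censoring_mode: str = "cox",
    floor: float = DEFAULT_WEIGHT_FLOOR,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> EeRmstModel:
    """Solve ``Σ ŵ_i X̃_i (ZL_i − g⁻¹(β'X̃_i)) = 0`` with ``X̃ = (1, X)``.

    The identity link solves in one weighted-least-squares step; the exp
    link runs damped Newton on the estimating-function norm.
    """
    if not (rdata.deltaL == 1).any():
        raise ValueError("no uncensored restricted observations")
    w = _ee_weights(rdata, censoring_mode, floor)
    Xt = np.column_stack([np.ones(rdata.n), rdata.X])
    z = rdata.ZL
    if link == "identity":
        A = Xt.T @ (w[:, None] * Xt)
        b = Xt.T @ (w * z)
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as err:
            raise RuntimeError("singular weighted design matrix") from err
        return EeRmstModel(link, beta, censoring_mode, rdata.L, 1, True)
    if link != "exp":
        raise ValueError(f"unsupported link {link!r}")
    # exp link: F(beta) = X' W (z - exp(X beta)); damped Newton
    wbar = w * z
    mean_z = wbar.sum() / max(w.sum(), 1e-300)
    beta = np.zeros(Xt.shape[1])
    beta[0] = np.log(max(mean_z, 1e-12))
    fnorm = np.inf
    for it in range(1, max_iter + 1):
        m = np.exp(np.clip(Xt @ beta, -500, 500))
        F = Xt.T @ (w * (z - m))
        fnorm = float(np.linalg.norm(F))
        if fnorm < tol * (1 + abs(mean_z) * rdata.n):
            return EeRmstModel(link, beta, censoring_mode, rdata.L, it, True)
        Jac = Xt.T @ ((w * m)[:, None] * Xt)
        try:
            step = np.linalg.solve(Jac, F)
        except np.linalg.LinAlgError as err:
            raise RuntimeError("singular Jacobian in exp-link fit") from err
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            mc = np.exp(np.clip(Xt @ cand, -500, 500))
            if np.linalg.norm(Xt.T @ (w * (z - mc))) < fnorm:
                break
            scale *= 0.5
        else:
            break
        beta = beta + scale * step
    raise RuntimeError(
        f"exp-link estimating equation did not converge (|F| = {fnorm:.3g})"
    )


def predict_ee_rmst(model: EeRmstModel, x: np.ndarray) -> np.ndarray:
    """``g⁻¹(β̂'(1, x))`` clipped to [0, L]."""
    if not model.converged:
        raise ValueError("model did not converge; refusing to predict")
    x = np.atleast_2d(np.asarray(x, float))
    eta = model.beta[0] + x @ model.beta[1:]
    pred = eta if model.link == "identity" else np.exp(np.clip(eta, -500, 500))
    return np.clip(pred, 0.0, model.L)
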