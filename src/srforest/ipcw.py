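"""Inverse-probability-of-censoring weights from a Cox censoring model.

The censoring time ``C`` is assumed to follow a proportional-hazards
model ``λ_C(t|x) = λ₀(t)·exp(x'β_C)``.  Fitting treats censoring
(``delta == 0``) as the event of interest and events as censored; the
Breslow baseline gives the censoring survival ``1 − Ĝ(t|x)``, evaluated
left-continuously so that a subject censored exactly at a baseline jump
is not weighted by its own jump.  The IPCW weight of subject ``i`` is

    ŵ_i = δᴸ_i / max(1 − Ĝ(Zᴸ_i⁻ | X_i), floor)

which has unit mean under a correctly specified censoring model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cox import CoxFit, fit_cox, survival_at
from .data import RestrictedDataset, SurvivalDataset

__all__ = [
    "CensoringModel",
    "IpcwWeights",
    "fit_cox_censoring",
    "censoring_survival",
    "compute_ipcw",
    "psi_value",
    "DEFAULT_WEIGHT_FLOOR",
]

#: lower bound on 1−Ĝ in the weight denominator (Assumption-style ε_L bound)
DEFAULT_WEIGHT_FLOOR = 0.05


@dataclass(frozen=True)
class CensoringModel:
    """Cox model for the censoring distribution."""

    fit: CoxFit

    @property
    def beta_C(self) -> np.ndarray:
        return self.fit.beta

    @property
    def baseline_times(self) -> np.ndarray:
        return self.fit.baseline_times

    @property
    def baseline_cumhaz(self) -> np.ndarray:
        return self.fit.baseline_cumhaz

    @property
    def degenerate(self) -> bool:
        return self.fit.degenerate


@dataclass(frozen=True)
class IpcwWeights:
    w: np.ndarray
    floor_used: np.ndarray  # boolean per observation


def fit_cox_censoring(
    data: SurvivalDataset, indices: np.ndarray | None = None
) -> CensoringModel:
    """Fit the censoring Cox model on a subject subset (default: all).

    With no censoring events in the subset the degenerate model
    (``Ĝ ≡ 0``, all weights equal ``deltaL``) is returned with a warning.
    """
    if indices is None:
        X, Z, delta = data.X, data.Z, data.delta
    else:
        idx = np.asarray(indices)
        X, Z, delta = data.X[idx], data.Z[idx], data.delta[idx]
    cens_event = delta == 0
    if not cens_event.any():
        warnings.warn(
            "no censoring events in subset; using degenerate censoring model "
            "(all subjects treated as fully observed)",
            stacklevel=2,
        )
    fit = fit_cox(X, Z, cens_event)
    return CensoringModel(fit=fit)


def censoring_survival(model: CensoringModel, t, x) -> np.ndarray:
    """``1 − Ĝ(t⁻|x)``: probability of remaining uncensored just before t."""
    return survival_at(model.fit, t, x, left_continuous=True)


def compute_ipcw(
    rdata: RestrictedDataset,
    model: CensoringModel,
    floor: float = DEFAULT_WEIGHT_FLOOR,
) -> IpcwWeights:
    """IPCW weights ``ŵ_i = δᴸ_i / max(1 − Ĝ(Zᴸ_i⁻|X_i), floor)``."""
    if not model.degenerate and model.fit.p != rdata.base.p:
        raise ValueError(
            f"censoring model has {model.fit.p} covariates, data has {rdata.base.p}"
        )
    surv = censoring_survival(model, rdata.ZL, rdata.base.X)
    floored = surv < floor
    denom = np.maximum(surv, floor)
    w = rdata.deltaL / denom
    return IpcwWeights(w=w, floor_used=floored & (rdata.deltaL == 1))


def psi_value(zL, w, mu):
    """Estimating-function value ``ψ_μ = w·(zL − μ)``."""
    return np.asarray(w, float) * (np.asarray(zL, float) - mu)
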