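"""Right-censored survival data containers and CSV I/O.

A sample is a table with one row per subject: numeric covariates ``X``,
an observed time ``Z = min(T, C)`` and an event indicator
``delta = 1{T <= C}``.  Restriction at a horizon ``L`` maps this to
``ZL = min(Z, L)`` with indicator ``deltaL`` which is 1 whenever the
*restricted* survival time ``T ∧ L`` is known to be observed — i.e. when
the subject's follow-up reaches ``L`` (``Z >= L``) or the event occurred
before ``L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "RestrictedDataset",
    "restrict",
    "read_survival_csv",
    "write_survival_csv",
]


@dataclass(frozen=True)
class SurvivalDataset:
    """Raw right-censored sample: covariates, observed times, event flags."""

    X: np.ndarray
    Z: np.ndarray
    delta: np.ndarray
    covariate_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Z = np.asarray(self.Z, dtype=float).ravel()
        delta = np.asarray(self.delta).ravel()
        if X.shape[0] != Z.shape[0] or Z.shape[0] != delta.shape[0]:
            raise ValueError(
                f"inconsistent lengths: X has {X.shape[0]} rows, "
                f"Z has {Z.shape[0]}, delta has {delta.shape[0]}"
            )
        if X.shape[0] < 1:
            raise ValueError("dataset must contain at least one subject")
        if np.isnan(X).any() or np.isnan(Z).any():
            raise ValueError("missing values are not supported")
        if (Z < 0).any():
            bad = int(np.flatnonzero(Z < 0)[0])
            raise ValueError(f"negative observed time at row {bad}")
        uniq = np.unique(delta)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError(f"event indicator must be 0/1, found {uniq.tolist()}")
        names = tuple(self.covariate_names) or tuple(
            f"x{j + 1}" for j in range(X.shape[1])
        )
        if len(names) != X.shape[1]:
            raise ValueError("covariate_names length does not match X columns")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Z", Z)
        object.__setattr__(self, "delta", delta.astype(np.int8))
        object.__setattr__(self, "covariate_names", names)

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, indices: np.ndarray) -> "SurvivalDataset":
        idx = np.asarray(indices)
        return SurvivalDataset(
            self.X[idx], self.Z[idx], self.delta[idx], self.covariate_names
        )


@dataclass(frozen=True)
class RestrictedDataset:
    """A :class:`SurvivalDataset` truncated at the restriction time ``L``."""

    base: SurvivalDataset
    L: float
    ZL: np.ndarray
    deltaL: np.ndarray

    @property
    def n(self) -> int:
        return self.base.n

    @property
    def X(self) -> np.ndarray:
        return self.base.X


def restrict(data: SurvivalDataset, L: float) -> RestrictedDataset:
    """Truncate observed times at ``L``.

    ``ZL = min(Z, L)``; the restricted event indicator is 1 when the
    follow-up reaches ``L`` (the restricted time ``T ∧ L`` is then fully
    observed regardless of later censoring) and equals ``delta`` otherwise.
    """
    if not L > 0:
        raise ValueError(f"restriction time L must be positive, got {L}")
    reached = data.Z >= L
    ZL = np.minimum(data.Z, L)
    deltaL = np.where(reached, 1, data.delta).astype(np.int8)
    return RestrictedDataset(base=data, L=float(L), ZL=ZL, deltaL=deltaL)


def read_survival_csv(path) -> SurvivalDataset:
    """Read a survival table: columns ``time``, ``event`` plus covariates.

    Every non time/event column is taken as a numeric covariate, in file
    order.  Malformed rows raise with the offending row number (0-based
    data row, excluding the header).
    """
    df = pd.read_csv(path)
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: required column '{col}' missing")
    cov_cols = [c for c in df.columns if c not in ("time", "event")]
    ev = pd.to_numeric(df["event"], errors="coerce")
    bad = ~ev.isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: non-binary event value at data row {row}")
    t = pd.to_numeric(df["time"], errors="coerce")
    if t.isna().any() or (t < 0).any():
        row = int(np.flatnonzero((t.isna() | (t < 0)).to_numpy())[0])
        raise ValueError(f"{path}: missing or negative time at data row {row}")
    X = np.empty((len(df), len(cov_cols)))
    for j, c in enumerate(cov_cols):
        col = pd.to_numeric(df[c], errors="coerce")
        if col.isna().any():
            row = int(np.flatnonzero(col.isna().to_numpy())[0])
            raise ValueError(f"{path}: non-numeric covariate '{c}' at data row {row}")
        X[:, j] = col.to_numpy()
    return SurvivalDataset(
        X, t.to_numpy(float), ev.to_numpy(int), tuple(cov_cols)
    )


def write_survival_csv(path, data: SurvivalDataset, extra: dict | None = None) -> None:
    """Write a dataset in the same layout :func:`read_survival_csv` expects."""
    df = pd.DataFrame({"time": data.Z, "event": data.delta.astype(int)})
    for j, name in enumerate(data.covariate_names):
        df[name] = data.X[:, j]
    for name, col in (extra or {}).items():
        df[name] = col
    df.to_csv(path, index=False)
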