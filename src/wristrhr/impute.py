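"""Multiple imputation by chained equations with predictive mean matching,
and Box-Cox normalizing transforms for continuous measures.

The PMM variant is type-0 matching: for each missing cell a linear model of
the target on all other (current) columns is fitted to the observed rows, the
observed cases are ranked by distance between predicted values, and the
imputed value is drawn uniformly from the ``donors`` nearest observed values
— so every imputed value is an element of the variable's observed support.
Singular predictive models fall back to a ridge-regularized fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError

__all__ = ["ImputationSet", "mice_pmm", "box_cox_fit", "box_cox_apply"]


@dataclass
class ImputationSet:
    """m completed copies of one table plus the missingness provenance."""

    tables: list[pd.DataFrame]
    mask: pd.DataFrame  # True where the cell was missing (hence imputed)
    m: int
    seed: int | None

    def __post_init__(self):
        if len(self.tables) != self.m:
            raise DataError("ImputationSet: number of tables must equal m")


def _fit_predict(X_obs, y_obs, X_all, ridge=1e-6):
    """Least-squares prediction with ridge fallback for singular designs."""
    A = np.column_stack([np.ones(len(X_obs)), X_obs])
    B = np.column_stack([np.ones(len(X_all)), X_all])
    try:
        coef, _, rank, _ = np.linalg.lstsq(A, y_obs, rcond=None)
        if rank < A.shape[1]:
            raise np.linalg.LinAlgError("rank deficient")
    except np.linalg.LinAlgError:
        warnings.warn("singular predictive model in PMM; using ridge fallback")
        AtA = A.T @ A + ridge * np.eye(A.shape[1])
        coef = np.linalg.solve(AtA, A.T @ y_obs)
    return B @ coef


def mice_pmm(
    table: pd.DataFrame,
    m: int = 5,
    donors: int = 5,
    iterations: int = 10,
    seed: int | None = None,
) -> ImputationSet:
    """Chained-equations imputation with predictive mean matching.

    ``table`` must be numeric (code categoricals as integers first; PMM then
    guarantees imputed codes are observed codes).  Produces ``m`` completed
    tables from independent chains; observed cells are identical across them.
    """
    num = table.astype(float)
    mask = num.isna()
    if len(num) < 20 and mask.to_numpy().any():
        raise DataError(f"mice_pmm needs n >= 20 rows, got {len(num)}")
    fully_missing = [c for c in num.columns if mask[c].all()]
    if fully_missing:
        raise DataError(f"variables with no observed values: {fully_missing}")

    na_cols = [c for c in num.columns if mask[c].any()]
    if not na_cols:
        return ImputationSet([table.copy() for _ in range(m)], mask, m, seed)

    root = np.random.default_rng(seed)
    completed = []
    for _ in range(m):
        rng = np.random.default_rng(root.integers(2**31))
        X = num.to_numpy(float).copy()
        col_idx = {c: j for j, c in enumerate(num.columns)}
        miss = mask.to_numpy()
        # initialize missing cells with random observed draws
        for c in na_cols:
            j = col_idx[c]
            obs = X[~miss[:, j], j]
            X[miss[:, j], j] = rng.choice(obs, size=int(miss[:, j].sum()), replace=True)
        for _ in range(iterations):
            for c in na_cols:
                j = col_idx[c]
                others = [k for k in range(X.shape[1]) if k != j]
                obs_rows = ~miss[:, j]
                mis_rows = miss[:, j]
                pred = _fit_predict(X[obs_rows][:, others], X[obs_rows, j], X[:, others])
                pred_obs = pred[obs_rows]
                pred_mis = pred[mis_rows]
                y_obs = X[obs_rows, j]
                k = min(donors, y_obs.size)
                for where, pm in zip(np.flatnonzero(mis_rows), pred_mis):
                    d = np.abs(pred_obs - pm)
                    nearest = np.argpartition(d, k - 1)[:k]
                    X[where, j] = y_obs[rng.choice(nearest)]
        completed.append(pd.DataFrame(X, index=num.index, columns=num.columns))
    return ImputationSet(completed, mask, m, seed)


def box_cox_fit(
    values, grid: np.ndarray | None = None
) -> tuple[float, float]:
    """Profile-likelihood Box-Cox fit over a lambda grid.

    Returns (lambda, shift); ``shift = 1 - min`` is applied first when the
    minimum is nonpositive.  Constant input skips the transform (identity,
    lambda=1, with a warning).
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size < 10:
        raise DataError(f"box_cox_fit needs >= 10 non-missing values, got {v.size}")
    shift = 0.0
    if v.min() <= 0:
        shift = 1.0 - v.min()
    if np.all(v == v[0]):
        warnings.warn("constant input to box_cox_fit; identity transform used")
        return 1.0, shift
    shifted = v + shift
    if grid is None:
        grid = np.arange(-2.0, 2.0 + 1e-9, 0.01)
    llf = np.array([stats.boxcox_llf(lam, shifted) for lam in grid])
    return float(grid[np.argmax(llf)]), shift


def box_cox_apply(values, lam: float, shift: float = 0.0) -> np.ndarray:
    """Apply y -> ((y+shift)^lam - 1)/lam (log(y+shift) at lam=0);
    NaN passes through."""
    v = np.asarray(values, float)
    out = np.full(v.shape, np.nan)
    ok = np.isfinite(v)
    y = v[ok] + shift
    if np.any(y <= 0):
        raise DataError("box_cox_apply: nonpositive values after shift")
    if lam == 0.0:
        out[ok] = np.log(y)
    else:
        out[ok] = (y**lam - 1.0) / lam
    return out
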