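"""Penalized association models of device RHR on baseline-covariate domains.

Pipeline per (domain, sex): multiply impute the sex stratum's covariates
(MICE-PMM, m completed tables), Box-Cox transform continuous vitals/physical
and laboratory measures, append raw age and age-squared (the inverted-U age
term), dummy-code categoricals dropping the most frequent reference level,
standardize all predictors, stack the m completed tables vertically with
observation weight 1/m, and fit an elastic net on the stacked objective

    (1/2W) sum_i w_i (y_i - x_i b)^2 + lambda [alpha |b|_1 + (1-alpha)|b|_2^2 / 2]

over a 100-point, 4-decade lambda path with alpha in {0.5, 1}, choosing the
(alpha, lambda) pair that minimizes 5-fold cross-validated MSE with folds
assigned at the participant level (all m copies of a participant share a
fold).  The outcome is device RHR in bpm, centered within the stratum.

Exposed in Model/Results style::

    res = RHRAssociationModel(covariates, rhr).fit(m=5, seed=1)
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet

from .covariates import DOMAINS, CovariateTable
from .exceptions import ConfigError, DataError
from .impute import ImputationSet, box_cox_apply, box_cox_fit, mice_pmm

__all__ = [
    "StackedDesign",
    "ENETFit",
    "encode_for_imputation",
    "build_design",
    "elastic_net_solve",
    "fit_senet",
    "association_report",
    "RHRAssociationModel",
    "RHRAssociationResults",
]

BOXCOX_DOMAINS = ("vitals_physical", "labs")


def encode_for_imputation(
    covariates: CovariateTable, extra: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, list]]:
    """Numeric-code a covariate table (plus extra numeric columns) for MICE.

    Categorical labels become integer codes; the returned mapping
    ``codes[name]`` lists the levels in code order so imputed codes can be
    decoded back to labels.  ``extra`` (e.g. age, device_rhr) is joined on
    participant_id index.
    """
    df = covariates.data.copy()
    codes: dict[str, list] = {}
    for name in covariates.names(kind="categorical"):
        levels = sorted(df[name].dropna().unique().tolist())
        codes[name] = levels
        mapping = {lv: float(i) for i, lv in enumerate(levels)}
        df[name] = df[name].map(mapping)
    df = df.astype(float)
    joined = df.join(extra, how="inner")
    if len(joined) != len(df):
        raise DataError("extra columns missing for some participants")
    return joined, codes


@dataclass
class StackedDesign:
    domain: str
    sex: str
    X: np.ndarray  # standardized predictors, stacked over the m tables
    y: np.ndarray  # centered outcome
    weights: np.ndarray  # 1/m per stacked row
    columns: list[str]
    participant_ids: np.ndarray
    m: int
    n: int  # participants
    transform: dict = field(default_factory=dict)  # per-column (lam, shift, mean, sd)
    y_mean: float = 0.0


def build_design(
    imputation_set: ImputationSet,
    codes: dict[str, list],
    meta: pd.DataFrame,
    outcome_col: str,
    domain: str,
    sex: str,
    age_col: str = "age",
) -> StackedDesign:
    """Assemble the stacked, transformed, standardized design for one model."""
    if domain not in DOMAINS:
        raise ConfigError(f"unknown domain {domain!r}")
    domain_vars = [c for c in meta.index if meta.loc[c, "domain"] == domain]
    if not domain_vars:
        raise ConfigError(f"no covariates tagged with domain {domain!r}")

    m = imputation_set.m
    frames = []
    for completed in imputation_set.tables:
        cols: dict[str, np.ndarray] = {}
        for name in domain_vars:
            kind = meta.loc[name, "kind"]
            if kind == "categorical":
                levels = codes[name]
                lab = np.asarray(levels, object)[completed[name].to_numpy(int)]
                # reference = most frequent level in this stratum (pooled)
                pooled = pd.concat([t[name] for t in imputation_set.tables])
                ref_code = int(pooled.value_counts().idxmax())
                for j, level in enumerate(levels):
                    if j == ref_code:
                        continue
                    cols[f"{name}={level}"] = (lab == level).astype(float)
            else:
                cols[name] = completed[name].to_numpy(float)
        cols[age_col] = completed[age_col].to_numpy(float)
        cols[f"{age_col}_sq"] = completed[age_col].to_numpy(float) ** 2
        frame = pd.DataFrame(cols, index=completed.index)
        frame["__y__"] = completed[outcome_col].to_numpy(float)
        frames.append(frame)

    stacked = pd.concat(frames)
    y = stacked.pop("__y__").to_numpy(float)
    n = len(imputation_set.tables[0])

    transform: dict[str, dict] = {}
    X_cols: list[np.ndarray] = []
    names: list[str] = []
    for name in stacked.columns:
        v = stacked[name].to_numpy(float)
        is_boxcox = (
            name in meta.index
            and meta.loc[name, "kind"] == "continuous"
            and meta.loc[name, "domain"] in BOXCOX_DOMAINS
        )
        spec: dict = {}
        if is_boxcox:
            lam, shift = box_cox_fit(v)
            v = box_cox_apply(v, lam, shift)
            spec.update(lam=lam, shift=shift)
        mean, sd = float(v.mean()), float(v.std())
        if sd == 0:
            warnings.warn(f"constant design column {name!r} dropped")
            continue
        v = (v - mean) / sd
        spec.update(mean=mean, sd=sd)
        # drop exact duplicates of an earlier column (collinear twins)
        if any(np.allclose(v, prev, atol=1e-10) for prev in X_cols):
            warnings.warn(f"design column {name!r} duplicates an earlier column; dropped")
            continue
        transform[name] = spec
        X_cols.append(v)
        names.append(name)

    X = np.column_stack(X_cols)
    y_mean = float(y.mean())
    return StackedDesign(
        domain=domain,
        sex=sex,
        X=X,
        y=y - y_mean,
        weights=np.full(len(y), 1.0 / m),
        columns=names,
        participant_ids=np.asarray(stacked.index, object),
        m=m,
        n=n,
        transform=transform,
        y_mean=y_mean,
    )


@dataclass
class ENETFit:
    domain: str
    sex: str
    alpha: float
    lam: float
    coefficients: dict[str, float]
    intercept: float
    cv_error: float
    n: int
    m: int
    lambda_path: np.ndarray = field(repr=False, default=None)
    cv_path: dict = field(repr=False, default=None)  # alpha -> MSE per lambda

    @property
    def selected(self) -> dict[str, bool]:
        return {k: v != 0.0 for k, v in self.coefficients.items()}


def elastic_net_solve(X, y, weights, lam, alpha, tol=1e-8, max_iter=50_000):
    """Solve the weighted elastic-net objective at one (lambda, alpha).

    Coordinate descent on (1/2W) sum w_i (y_i - b0 - x_i b)^2 +
    lambda [alpha |b|_1 + (1-alpha)|b|_2^2 / 2]; returns (coefficients,
    intercept).  At lambda -> 0 this converges to ordinary least squares.
    """
    est = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True,
                     max_iter=max_iter, tol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # vanishing-penalty fits converge slowly
        est.fit(X, y, sample_weight=weights)
    return est.coef_.copy(), float(est.intercept_)


def _lambda_max(X, y, w, alpha):
    W = w.sum()
    y_c = y - np.average(y, weights=w)
    grad = np.abs(X.T @ (w * y_c)) / W
    return float(grad.max() / alpha)


def _participant_folds(pids, folds, rng):
    unique = pd.unique(pids)
    perm = rng.permutation(len(unique))
    fold_of = {unique[i]: perm[i] % folds for i in range(len(unique))}
    return np.asarray([fold_of[p] for p in pids])


def fit_senet(
    design: StackedDesign,
    alphas: tuple[float, ...] = (0.5, 1.0),
    n_lambdas: int = 100,
    lambda_decades: float = 4.0,
    folds: int = 5,
    seed: int | None = None,
    max_refolds: int = 10,
) -> ENETFit:
    """Cross-validated stacked elastic net over the (alpha, lambda) grid."""
    X, y, w, pids = design.X, design.y, design.weights, design.participant_ids
    rng = np.random.default_rng(seed)

    lam_max = max(_lambda_max(X, y, w, a) for a in alphas)
    path = np.geomspace(lam_max, lam_max * 10.0 ** (-lambda_decades), n_lambdas)

    fold_id = None
    for _ in range(max_refolds):
        candidate = _participant_folds(pids, folds, rng)
        if all(np.ptp(y[candidate != f]) > 0 for f in range(folds)):
            fold_id = candidate
            break
    if fold_id is None:
        raise DataError("could not build CV folds with outcome variation")

    cv_path = {}
    best = None
    for a in alphas:
        sse = np.zeros(n_lambdas)
        wsum = 0.0
        for f in range(folds):
            tr, te = fold_id != f, fold_id == f
            est = ElasticNet(l1_ratio=a, fit_intercept=True, warm_start=True,
                             max_iter=5000, tol=1e-6)
            preds = np.empty((n_lambdas, int(te.sum())))
            for j, lam in enumerate(path):
                est.set_params(alpha=lam)
                est.fit(X[tr], y[tr], sample_weight=w[tr])
                preds[j] = est.predict(X[te])
            sse += ((y[te][None, :] - preds) ** 2 * w[te][None, :]).sum(axis=1)
            wsum += w[te].sum()
        mse = sse / wsum
        cv_path[a] = mse
        j = int(np.argmin(mse))
        if best is None or mse[j] < best[0]:
            best = (float(mse[j]), a, float(path[j]))

    cv_err, alpha, lam = best
    coef, intercept = elastic_net_solve(X, y, w, lam, alpha)
    coefs = {name: float(c) for name, c in zip(design.columns, coef)}
    return ENETFit(
        domain=design.domain,
        sex=design.sex,
        alpha=alpha,
        lam=lam,
        coefficients=coefs,
        intercept=intercept + design.y_mean,
        cv_error=cv_err,
        n=design.n,
        m=design.m,
        lambda_path=path,
        cv_path=cv_path,
    )


def association_report(fits: list[ENETFit]) -> pd.DataFrame:
    """Rank variables by |standardized coefficient| within each fit.

    Rank 1 is the strongest association; the top variable of each
    (domain, sex) model carries ``top=True``.  Ordering is invariant to the
    input variable order (ties broken by name).
    """
    rows = []
    for fit in fits:
        ranked = sorted(
            fit.coefficients.items(), key=lambda kv: (-abs(kv[1]), kv[0])
        )
        for rank, (name, coef) in enumerate(ranked, start=1):
            rows.append(
                {
                    "domain": fit.domain,
                    "sex": fit.sex,
                    "variable": name,
                    "coefficient": coef,
                    "alpha": fit.alpha,
                    "lambda": fit.lam,
                    "rank": rank,
                    "top": rank == 1 and coef != 0.0,
                }
            )
    return pd.DataFrame(rows)


class RHRAssociationModel:
    """Domain-wise penalized regression of device RHR on baseline covariates.

    Parameters
    ----------
    covariates : CovariateTable (wide, with missingness).
    rhr : DataFrame with participant_id, device_rhr, sex, age.
    """

    def __init__(self, covariates: CovariateTable, rhr: pd.DataFrame):
        missing = {"participant_id", "device_rhr", "sex", "age"} - set(rhr.columns)
        if missing:
            raise DataError(f"rhr table missing columns: {sorted(missing)}")
        self.covariates = covariates
        self.rhr = rhr.set_index("participant_id")

    def fit(
        self,
        domains: tuple[str, ...] = DOMAINS,
        sexes: tuple[str, ...] = ("female", "male"),
        m: int = 5,
        donors: int = 5,
        iterations: int = 10,
        folds: int = 5,
        alphas: tuple[float, ...] = (0.5, 1.0),
        seed: int | None = None,
    ) -> "RHRAssociationResults":
        fits = []
        root = np.random.default_rng(seed)
        for sex in sexes:
            ids = self.rhr.index[self.rhr["sex"] == sex]
            ids = ids.intersection(self.covariates.data.index)
            if len(ids) == 0:
                warnings.warn(f"no participants in stratum {sex!r}; skipped")
                continue
            sub = CovariateTable(self.covariates.data.loc[ids], self.covariates.meta)
            extra = self.rhr.loc[ids, ["age", "device_rhr"]].astype(float)
            coded, codes = encode_for_imputation(sub, extra)
            imp = mice_pmm(
                coded, m=m, donors=donors, iterations=iterations,
                seed=int(root.integers(2**31)),
            )
            for domain in domains:
                design = build_design(
                    imp, codes, sub.meta, outcome_col="device_rhr",
                    domain=domain, sex=sex,
                )
                fits.append(
                    fit_senet(
                        design, alphas=alphas, folds=folds,
                        seed=int(root.integers(2**31)),
                    )
                )
        return RHRAssociationResults(self, fits)


class RHRAssociationResults:
    """Collection of fitted domain x sex elastic-net models."""

    def __init__(self, model: RHRAssociationModel, fits: list[ENETFit]):
        self.model = model
        self.fits = {(f.domain, f.sex): f for f in fits}

    def report(self) -> pd.DataFrame:
        return association_report(list(self.fits.values()))

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "domain": f.domain,
                    "sex": f.sex,
                    "alpha": f.alpha,
                    "lambda": f.lam,
                    "cv_error": f.cv_error,
                    "n": f.n,
                    "m": f.m,
                }
                for f in self.fits.values()
            ]
        )

    def summary(self) -> str:
        lines = ["Device RHR associations (stacked elastic net)", ""]
        rep = self.report()
        for (domain, sex), fit in self.fits.items():
            top = rep[(rep["domain"] == domain) & (rep["sex"] == sex) & (rep["rank"] == 1)]
            name = top.iloc[0]["variable"] if len(top) else "-"
            coef = top.iloc[0]["coefficient"] if len(top) else float("nan")
            n_sel = sum(fit.selected.values())
            lines.append(
                f"{domain:<18}{sex:<8}alpha={fit.alpha:<5}lambda={fit.lam:<10.4g}"
                f"selected={n_sel:<4}top: {name} ({coef:+.2f} bpm/SD)"
            )
        return "\n".join(lines)
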