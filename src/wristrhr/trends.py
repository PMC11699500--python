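"""Sex-stratified RHR percentile categories and tests for trend.

Participants are split, within sex, into three device-RHR categories at the
25th and 75th percentiles (type-7 linear-interpolation quantiles; low:
rhr <= c25, mid: c25 < rhr <= c75, high: rhr > c75).  Binary characteristics
— including the full set of level-vs-rest dummies for categorical ones — are
tested with the Cochran-Armitage trend test over equally spaced scores
(0, 1, 2); continuous characteristics with Spearman rank correlation against
the ordinal category.  Tests run on complete cases; two-sided p-values, no
multiplicity adjustment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import CovariateTable
from .exceptions import DataError, InsufficientDataError

__all__ = [
    "categorize_rhr",
    "dummy_code",
    "cochran_armitage",
    "spearman_trend",
    "trend_report",
]

CATEGORY_LABELS = ("low", "mid", "high")  # 0-25th, 25-75th, 75-100th


def categorize_rhr(pairs: pd.DataFrame, rhr_col: str = "device_rhr") -> tuple[pd.DataFrame, dict]:
    """Assign each participant a within-sex RHR percentile category.

    Returns (categories, cutpoints): ``categories`` has participant_id, sex,
    category (0/1/2) and category_label; ``cutpoints`` maps sex ->
    (c25, c75) in bpm.
    """
    out = []
    cutpoints: dict[str, tuple[float, float]] = {}
    for s, sub in pairs.groupby("sex", sort=True):
        values = sub[rhr_col].to_numpy(float)
        if values.size < 4:
            raise InsufficientDataError(
                f"sex stratum {s!r} has {values.size} participants; need >= 4"
            )
        c25, c75 = np.quantile(values, [0.25, 0.75])  # type-7 interpolation
        if c25 == c75:
            warnings.warn(f"degenerate RHR distribution in stratum {s!r}")
        cat = np.where(values <= c25, 0, np.where(values <= c75, 1, 2))
        cutpoints[s] = (float(c25), float(c75))
        out.append(
            pd.DataFrame(
                {
                    "participant_id": sub["participant_id"].values,
                    "sex": s,
                    "category": cat,
                    "category_label": np.asarray(CATEGORY_LABELS, object)[cat],
                }
            )
        )
    return pd.concat(out, ignore_index=True), cutpoints


def dummy_code(table: CovariateTable, drop_reference: bool = False) -> CovariateTable:
    """Expand categorical covariates into 0/1 level indicators.

    With ``drop_reference=False`` (trend testing) every observed level gets a
    level-vs-all-others column; with ``drop_reference=True`` (regression
    design) the most frequent level is dropped to keep the design full rank.
    Missing categorical entries propagate to all of their dummies.
    """
    data = table.data.copy()
    meta = table.meta.copy()
    for name in table.names(kind="categorical"):
        col = data[name]
        levels = col.dropna().unique().tolist()
        if len(levels) < 2:
            warnings.warn(f"categorical covariate {name!r} has <2 observed levels; dropped")
            data = data.drop(columns=[name])
            meta = meta.drop(index=[name])
            continue
        order = col.value_counts().index.tolist()  # most frequent first
        kept = order[1:] if drop_reference else order
        for level in kept:
            dummy = (col == level).astype(float)
            dummy[col.isna()] = np.nan
            data[f"{name}={level}"] = dummy
            meta.loc[f"{name}={level}"] = {
                "domain": table.meta.loc[name, "domain"],
                "kind": "binary",
            }
        data = data.drop(columns=[name])
        meta = meta.drop(index=[name])
    return CovariateTable(data, meta)


def cochran_armitage(
    successes, totals, scores=(0.0, 1.0, 2.0)
) -> tuple[float, float]:
    """Cochran-Armitage test for trend in proportions across ordered groups.

    ``successes``/``totals`` are per-category counts.  Returns (Z, two-sided
    normal p).  With no outcome variation (pooled proportion 0 or 1) the test
    is degenerate and (0, 1) is returned.
    """
    x = np.asarray(successes, float)
    n_k = np.asarray(totals, float)
    s = np.asarray(scores, float)
    if np.any(n_k <= 0):
        raise DataError("cochran_armitage: all category totals must be > 0")
    if np.any(x < 0) or np.any(x > n_k):
        raise DataError("cochran_armitage: successes must lie in [0, total]")
    n = n_k.sum()
    pbar = x.sum() / n
    if pbar in (0.0, 1.0):
        return 0.0, 1.0
    num = float(np.sum(s * x) - pbar * np.sum(s * n_k))
    var = pbar * (1 - pbar) * (np.sum(n_k * s**2) - np.sum(n_k * s) ** 2 / n)
    if var <= 0:
        return 0.0, 1.0
    z = num / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def spearman_trend(values, categories) -> tuple[float, float]:
    """Spearman rank correlation of a continuous measure with the ordinal
    RHR category (average ranks for ties, large-sample t approximation)."""
    v = np.asarray(values, float)
    c = np.asarray(categories, float)
    ok = np.isfinite(v) & np.isfinite(c)
    v, c = v[ok], c[ok]
    if v.size < 3:
        raise InsufficientDataError(f"spearman_trend needs >= 3 pairs, got {v.size}")
    if np.unique(c).size < 2:
        raise DataError("spearman_trend: categories are all equal")
    if np.all(v == v[0]):
        raise DataError("spearman_trend: zero variance in values")
    rho, p = stats.spearmanr(v, c)
    return float(rho), float(p)


def trend_report(
    covariates: CovariateTable,
    categories: pd.DataFrame,
    sex: str,
) -> pd.DataFrame:
    """Per-covariate trend tests for one sex stratum.

    Binary covariates (including categorical dummies) get Cochran-Armitage
    with per-category n (%); continuous covariates get Spearman with
    per-category mean (SD).  Summaries use non-missing values only.
    """
    cat_sub = categories[categories["sex"] == sex].set_index("participant_id")["category"]
    expanded = dummy_code(covariates, drop_reference=False)
    data = expanded.data.reindex(cat_sub.index)

    rows = []
    for name in data.columns:
        kind = expanded.meta.loc[name, "kind"]
        domain = expanded.meta.loc[name, "domain"]
        values = data[name].to_numpy(float)
        ok = np.isfinite(values)
        cats = cat_sub.to_numpy()[ok]
        vals = values[ok]
        row = {"covariate": name, "domain": domain, "type": kind, "sex": sex}
        try:
            if kind == "binary":
                succ = [float(vals[cats == k].sum()) for k in range(3)]
                tot = [int((cats == k).sum()) for k in range(3)]
                if min(tot) == 0:
                    raise DataError(f"empty category for {name}")
                z, p = cochran_armitage(succ, tot)
                row.update(test="cochran_armitage", statistic=z, p_value=p)
                for k, label in enumerate(CATEGORY_LABELS):
                    pct = 100.0 * succ[k] / tot[k]
                    row[f"summary_{label}"] = f"{int(succ[k])} ({pct:.1f})"
            else:
                rho, p = spearman_trend(vals, cats)
                row.update(test="spearman", statistic=rho, p_value=p)
                for k, label in enumerate(CATEGORY_LABELS):
                    sel = vals[cats == k]
                    row[f"summary_{label}"] = f"{sel.mean():.1f} ({sel.std(ddof=1):.1f})"
        except (DataError, InsufficientDataError) as exc:
            warnings.warn(f"covariate {name!r} skipped: {exc}")
            continue
        rows.append(row)
    return pd.DataFrame(rows)
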