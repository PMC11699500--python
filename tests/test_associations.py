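"""Stacked elastic net: design assembly, OLS limit, KKT threshold, recovery."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import ElasticNet

from wristrhr import (
    RHRAssociationModel,
    SimulationConfig,
    association_report,
    build_design,
    fit_senet,
    generate_covariates,
    mice_pmm,
)
from wristrhr.associations import ENETFit, StackedDesign, _lambda_max, encode_for_imputation
from wristrhr.covariates import CovariateTable


def _design_from_arrays(X, y, pids=None, m=1):
    n = len(y)
    return StackedDesign(
        domain="labs",
        sex="female",
        X=X,
        y=y - y.mean(),
        weights=np.full(n, 1.0 / m),
        columns=[f"v{i}" for i in range(X.shape[1])],
        participant_ids=np.arange(n) if pids is None else pids,
        m=m,
        n=n // m,
        y_mean=float(y.mean()),
    )


def _synthetic_cohort(n=120, seed=0, missing_rate=0.05, effects=None):
    cfg = SimulationConfig(n_participants=n, missing_rate=missing_rate,
                           covariate_effects=effects, seed=seed)
    rng = np.random.default_rng(seed)
    sex = np.array(["female"] * n)
    true_rhr = 66.6 + rng.normal(0, 11, n)
    participants = pd.DataFrame(
        {"participant_id": [f"P{i}" for i in range(n)], "sex": sex, "true_rhr": true_rhr}
    )
    cov = generate_covariates(participants, cfg, rng=np.random.default_rng(seed + 1))
    rhr = pd.DataFrame(
        {
            "participant_id": participants["participant_id"],
            "device_rhr": true_rhr + rng.normal(0, 2, n),
            "sex": sex,
            "age": np.round(rng.uniform(20, 80, n), 1),
        }
    )
    return cov, rhr


def _one_design(cov, rhr, domain="conditions", m=3, seed=0):
    sub_rhr = rhr.set_index("participant_id")
    coded, codes = encode_for_imputation(cov, sub_rhr[["age", "device_rhr"]])
    imp = mice_pmm(coded, m=m, iterations=3, seed=seed)
    return build_design(imp, codes, cov.meta, "device_rhr", domain, "female")


def test_design_stacking_conservation_and_age_terms():
    cov, rhr = _synthetic_cohort(n=80, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        design = _one_design(cov, rhr, m=5)
    assert design.X.shape[0] == 5 * 80
    assert design.weights.sum() == pytest.approx(80)
    assert "age" in design.columns and "age_sq" in design.columns
    # standardized columns
    assert np.allclose(design.X.mean(axis=0), 0, atol=1e-8)
    assert np.allclose(design.X.std(axis=0), 1, atol=1e-8)


def test_design_drops_reference_dummy():
    cov, rhr = _synthetic_cohort(n=80, seed=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        design = _one_design(cov, rhr, domain="demographics_ses", m=2)
    race_cols = [c for c in design.columns if c.startswith("race=")]
    assert len(race_cols) == 3  # 4 levels, most frequent dropped
    assert "race=White" not in design.columns


def test_zero_missingness_imputation_is_identity_through_design():
    cov, rhr = _synthetic_cohort(n=60, seed=3, missing_rate=0.0)
    coded, codes = encode_for_imputation(cov, rhr.set_index("participant_id")[["age", "device_rhr"]])
    imp = mice_pmm(coded, m=4, seed=0)
    for t in imp.tables:
        pd.testing.assert_frame_equal(t, coded.astype(float))


def test_enet_ols_limit():
    """At vanishing penalty with alpha=1 and a single (m=1) table the fit
    matches ordinary least squares."""
    rng = np.random.default_rng(4)
    n, p = 150, 8
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0)
    y = X @ rng.normal(size=p) + rng.normal(0, 0.5, n)
    y = y - y.mean()
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    est = ElasticNet(alpha=1e-10, l1_ratio=1.0, fit_intercept=True,
                     max_iter=200_000, tol=1e-14).fit(X, y)
    assert np.abs(est.coef_ - ols).max() < 1e-6


def test_lambda_max_kills_all_coefficients():
    rng = np.random.default_rng(5)
    n, p = 100, 6
    X = (lambda a: (a - a.mean(0)) / a.std(0))(rng.normal(size=(n, p)))
    y = X @ rng.normal(size=p) + rng.normal(0, 1, n)
    y = y - y.mean()
    w = np.ones(n)
    for alpha in (0.5, 1.0):
        lam = _lambda_max(X, y, w, alpha)
        est = ElasticNet(alpha=lam * (1 + 1e-10), l1_ratio=alpha,
                         fit_intercept=True).fit(X, y)
        assert np.all(est.coef_ == 0.0)
        est2 = ElasticNet(alpha=lam * 0.8, l1_ratio=alpha, fit_intercept=True).fit(X, y)
        assert np.any(est2.coef_ != 0.0)


def test_lasso_path_monotone_on_orthogonal_design():
    """On an orthonormal design the lasso is coordinatewise soft-thresholding,
    so the active-set size is non-increasing in lambda."""
    rng = np.random.default_rng(6)
    n, p = 64, 8
    Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
    X = Q * np.sqrt(n)  # unit-variance orthogonal columns
    y = X @ np.linspace(0.1, 1.0, p) + rng.normal(0, 0.3, n)
    y = y - y.mean()
    lam_max = _lambda_max(X, y, np.ones(n), 1.0)
    path = np.geomspace(lam_max, lam_max * 1e-3, 40)
    est = ElasticNet(l1_ratio=1.0, fit_intercept=True, warm_start=True)
    sizes = []
    for lam in path:
        est.set_params(alpha=lam)
        est.fit(X, y)
        sizes.append(int(np.sum(est.coef_ != 0)))
    assert all(b >= a for a, b in zip(sizes, sizes[1:]))


def test_fit_senet_recovers_planted_signals():
    rng = np.random.default_rng(7)
    n, p = 400, 15
    X = (lambda a: (a - a.mean(0)) / a.std(0))(rng.normal(size=(n, p)))
    beta = np.zeros(p)
    beta[[1, 5, 9]] = 0.6
    y = X @ beta + rng.normal(0, 1, n)
    design = _design_from_arrays(X, y)
    fit = fit_senet(design, seed=0)
    selected = {k for k, v in fit.coefficients.items() if v != 0}
    assert {"v1", "v5", "v9"} <= selected
    assert fit.cv_error < np.var(y)


def test_participant_level_folds_cover_all_copies():
    from wristrhr.associations import _participant_folds

    pids = np.tile(np.arange(30), 3)  # m=3 copies
    folds = _participant_folds(pids, 5, np.random.default_rng(0))
    for pid in range(30):
        assert len(set(folds[pids == pid])) == 1
    assert set(folds) == set(range(5))


def test_association_report_ranking():
    fit = ENETFit(
        domain="labs", sex="female", alpha=1.0, lam=0.1,
        coefficients={"b": -2.0, "a": 0.5, "c": 0.0}, intercept=65.0,
        cv_error=1.0, n=100, m=5,
    )
    rep = association_report([fit])
    assert list(rep.sort_values("rank")["variable"]) == ["b", "a", "c"]
    assert rep.loc[rep["variable"] == "b", "top"].item()
    # permuting the coefficient dict does not change ranks
    fit2 = ENETFit(
        domain="labs", sex="female", alpha=1.0, lam=0.1,
        coefficients={"c": 0.0, "a": 0.5, "b": -2.0}, intercept=65.0,
        cv_error=1.0, n=100, m=5,
    )
    rep2 = association_report([fit2])
    assert rep.sort_values("variable")["rank"].tolist() == rep2.sort_values("variable")["rank"].tolist()


def test_model_results_end_to_end_planted_top_variable():
    """A strongly planted disability-score effect ranks first in the female
    PRO-domain model."""
    cov, rhr = _synthetic_cohort(
        n=250, seed=8, missing_rate=0.03,
        effects={"whodas_score": 0.45, "phq9_score": 0.0, "gad7_score": 0.0,
                 "brfss_ace_score": 0.0, "sleep_hours": 0.0},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = RHRAssociationModel(cov, rhr).fit(
            domains=("pros",), sexes=("female",), m=3, iterations=3, seed=1
        )
    rep = res.report()
    top = rep[rep["rank"] == 1].iloc[0]
    assert top["variable"] == "whodas_score"
    assert top["coefficient"] > 0
    assert "whodas" in res.summary()
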