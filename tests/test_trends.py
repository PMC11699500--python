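"""Percentile categorization, dummy coding, and trend tests."""

import numpy as np
import pandas as pd
import pytest

from wristrhr import (
    DataError,
    SimulationConfig,
    categorize_rhr,
    cochran_armitage,
    dummy_code,
    generate_covariates,
    spearman_trend,
    trend_report,
)
from wristrhr.covariates import CovariateTable


def _pairs_one_sex(values, sex="female"):
    return pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(len(values))],
            "device_rhr": values,
            "sex": sex,
        }
    )


def test_categorize_type7_quantiles_and_sizes():
    cats, cuts = categorize_rhr(_pairs_one_sex(np.arange(1.0, 101.0)))
    assert cuts["female"] == (pytest.approx(25.75), pytest.approx(75.25))
    counts = cats["category"].value_counts()
    assert counts[0] == 25 and counts[1] == 50 and counts[2] == 25


def test_categorize_degenerate_and_equivariance():
    with pytest.warns(UserWarning, match="degenerate"):
        cats, _ = categorize_rhr(_pairs_one_sex([70.0] * 10))
    assert (cats["category"] == 0).all()  # boundary convention: all low

    rng = np.random.default_rng(0)
    v = rng.uniform(50, 90, 57)
    base, cuts1 = categorize_rhr(_pairs_one_sex(v))
    doubled, cuts2 = categorize_rhr(_pairs_one_sex(2 * v))
    assert np.array_equal(base["category"], doubled["category"])
    assert cuts2["female"][0] == pytest.approx(2 * cuts1["female"][0])


def test_category_low_size_property():
    rng = np.random.default_rng(1)
    for n in (40, 101, 250):
        cats, _ = categorize_rhr(_pairs_one_sex(rng.normal(65, 10, n)))
        low = int((cats["category"] == 0).sum())
        assert abs(low - n / 4) <= 1


def _cov_table(values: dict, kinds: dict, domain="demographics_ses"):
    data = pd.DataFrame(values, index=pd.Index([f"P{i}" for i in range(len(next(iter(values.values()))))], name="participant_id"))
    meta = pd.DataFrame(
        {"domain": domain, "kind": [kinds[c] for c in data.columns]}, index=data.columns
    )
    return CovariateTable(data, meta)


def test_dummy_code_full_set_and_reference_drop():
    race = ["White"] * 5 + ["Black"] * 3 + ["Asian"] * 2 + ["Other"] * 2
    table = _cov_table({"race": race, "smoker": [0.0, 1.0] * 6}, {"race": "categorical", "smoker": "binary"})
    full = dummy_code(table, drop_reference=False)
    assert sum(c.startswith("race=") for c in full.data.columns) == 4
    assert "smoker" in full.data.columns  # binary passes through
    reduced = dummy_code(table, drop_reference=True)
    assert sum(c.startswith("race=") for c in reduced.data.columns) == 3
    assert "race=White" not in reduced.data.columns  # most frequent is reference


def test_dummy_code_missing_propagates_and_single_level_dropped():
    race = pd.array(["White", "Black", pd.NA, "White"], dtype=object)
    table = _cov_table({"race": race, "only": ["x"] * 4}, {"race": "categorical", "only": "categorical"})
    with pytest.warns(UserWarning, match="only"):
        out = dummy_code(table)
    assert np.isnan(out.data.loc["P2", "race=White"])
    assert not any(c.startswith("only") for c in out.data.columns)


def test_cochran_armitage_flat_and_degenerate():
    z, p = cochran_armitage([10, 10, 10], [100, 100, 100])
    assert (z, p) == (0.0, 1.0)
    z, p = cochran_armitage([0, 0, 0], [50, 50, 50])
    assert p == 1.0
    with pytest.raises(DataError):
        cochran_armitage([1, 1, 1], [10, 0, 10])


def test_cochran_armitage_reduces_to_two_sample_z():
    """With the middle category absent the trend statistic is exactly the
    pooled two-sample proportion z-test."""
    x1, n1, x2, n2 = 12, 80, 30, 90
    z, _ = cochran_armitage([x1, x2], [n1, n2], scores=(0.0, 1.0))
    p1, p2 = x1 / n1, x2 / n2
    pbar = (x1 + x2) / (n1 + n2)
    zref = (p2 - p1) / np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    assert z == pytest.approx(zref, abs=1e-12)


def test_cochran_armitage_matches_exact_permutation_midp():
    """On a tiny 2x3 table the normal-approximation p agrees with the exact
    permutation null compared on the mid-p scale (the raw discrete tail is
    lattice-coarse at n=12, so the boundary mass is split)."""
    from itertools import combinations

    succ, tot = (1, 2, 3), (4, 4, 4)
    _, p_normal = cochran_armitage(succ, tot)
    scores = np.repeat([0.0, 1.0, 2.0], tot)
    n, k = sum(tot), sum(succ)
    stats_all = []
    for pos in combinations(range(n), k):
        y = np.zeros(n)
        y[list(pos)] = 1.0
        stats_all.append(float(scores @ y))
    stats_all = np.asarray(stats_all)
    expectation = stats_all.mean()
    observed = abs(float(np.dot([0.0, 1.0, 2.0], succ)) - expectation)
    dev = np.abs(stats_all - expectation)
    mid_p = (dev > observed + 1e-9).mean() + 0.5 * (np.abs(dev - observed) <= 1e-9).mean()
    assert p_normal == pytest.approx(mid_p, abs=0.05)


def test_spearman_trend_oracle_and_extremes():
    rho, _ = spearman_trend([1.0, 5.0, 9.0], [0, 1, 2])
    assert rho == pytest.approx(1.0)
    # with tied categories a perfectly monotone measure still correlates
    rho, _ = spearman_trend([1.0, 2, 3, 4, 5, 6], [0, 0, 1, 1, 2, 2])
    assert rho > 0.9

    rng = np.random.default_rng(2)
    v = rng.normal(size=60)
    c = rng.integers(0, 3, 60).astype(float)
    rho, _ = spearman_trend(v, c)
    # independent oracle: average-rank then Pearson
    rv = pd.Series(v).rank().to_numpy()
    rc = pd.Series(c).rank().to_numpy()
    ref = np.corrcoef(rv, rc)[0, 1]
    assert rho == pytest.approx(ref, abs=1e-12)

    with pytest.raises(DataError, match="zero variance"):
        spearman_trend([1.0, 1.0, 1.0, 1.0], [0, 1, 2, 0])


def _planted_cohort(n=500, seed=0, effects=None):
    cfg = SimulationConfig(
        n_participants=n, missing_rate=0.0, covariate_effects=effects, seed=seed
    )
    rng = np.random.default_rng(seed)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    true_rhr = np.where(sex == "female", 66.6, 64.4) + rng.normal(0, 11, n)
    participants = pd.DataFrame(
        {"participant_id": [f"P{i}" for i in range(n)], "sex": sex, "true_rhr": true_rhr}
    )
    cov = generate_covariates(participants, cfg, rng=np.random.default_rng(seed + 1))
    pairs = participants.rename(columns={"true_rhr": "device_rhr"})
    return cov, pairs


def test_trend_report_detects_planted_smoking_link():
    cov, pairs = _planted_cohort(n=600, seed=3, effects={"current_smoker": 0.12})
    cats, _ = categorize_rhr(pairs)
    rep = trend_report(cov, cats, "female").set_index("covariate")
    row = rep.loc["current_smoker"]
    assert row["test"] == "cochran_armitage"
    assert row["statistic"] > 0 and row["p_value"] < 0.05


def test_trend_report_summaries_and_ordering_invariance():
    cov, pairs = _planted_cohort(n=200, seed=4)
    cats, _ = categorize_rhr(pairs)
    rep = trend_report(cov, cats, "male")
    # categorical level percentages within a category sum to <= 100
    race_rows = rep[rep["covariate"].str.startswith("race=")]
    for col in ("summary_low", "summary_mid", "summary_high"):
        pct = race_rows[col].str.extract(r"\(([\d.]+)\)")[0].astype(float)
        # printed percentages are rounded to 0.1, so allow 0.05 per level
        assert pct.sum() <= 100.0 + 0.05 * len(race_rows)
    # participant order must not matter
    shuffled = pairs.sample(frac=1.0, random_state=1)
    cats2, _ = categorize_rhr(shuffled)
    rep2 = trend_report(cov, cats2, "male")
    merged = rep.merge(rep2, on="covariate", suffixes=("_a", "_b"))
    assert np.allclose(merged["p_value_a"], merged["p_value_b"])
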