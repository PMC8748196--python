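"""Score aggregation, ranking, scalability and usability formulas."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from scmetrics.aggregation import (
    ScalabilityRecord,
    UsabilityRecord,
    activity_score,
    combine_partial_scores,
    compare_scaling_schemes,
    feature_scaling_fit,
    loglinear_fit,
    minmax_scale,
    overall_scores,
    partial_scores,
    rank_methods,
    response_score,
    scalability_score,
    scale_results,
    usability_table,
)
from scmetrics.core import ALL_METRICS, BATCH_METRICS, BIO_METRICS, ParameterError


def _random_table(rng, n_runs=6):
    df = pd.DataFrame(
        rng.uniform(size=(n_runs, len(ALL_METRICS))),
        columns=list(ALL_METRICS),
        index=[f"run{i}" for i in range(n_runs)],
    )
    return df


# ------------------------------------------------------------------- scaling


def test_minmax_endpoints():
    col = pd.Series([0.2, 0.6, 1.0], name="m")
    assert list(minmax_scale(col)) == pytest.approx([0.0, 0.5, 1.0])


def test_minmax_preserves_order_and_missing(rng):
    col = pd.Series(rng.uniform(size=10), name="m")
    col.iloc[3] = np.nan
    scaled = minmax_scale(col)
    assert np.isnan(scaled.iloc[3])
    mask = col.notna()
    assert np.array_equal(
        rankdata(col[mask]), rankdata(scaled[mask])
    )


def test_minmax_constant_column_zeroed():
    col = pd.Series([0.5, 0.5, 0.5], name="m")
    with pytest.warns(UserWarning, match="constant"):
        assert list(minmax_scale(col)) == [0.0, 0.0, 0.0]


def test_scaling_is_per_column(rng):
    df = _random_table(rng)
    scaled = scale_results(df)
    assert np.allclose(scaled.min(axis=0), 0.0)
    assert np.allclose(scaled.max(axis=0), 1.0)


# ----------------------------------------------------------- partial/overall


def test_overall_weighted_combination():
    assert combine_partial_scores(1.0, 0.0) == pytest.approx(0.6)
    assert combine_partial_scores(0.0, 1.0) == pytest.approx(0.4)
    x = 0.3141
    assert combine_partial_scores(x, x) == pytest.approx(x)


def test_partial_scores_mean_only_computed_metrics():
    row = pd.Series(np.nan, index=list(ALL_METRICS))
    chosen_bio = list(BIO_METRICS)[:6]
    vals = np.linspace(0.1, 0.9, 6)
    row[chosen_bio] = vals
    row[list(BATCH_METRICS)[0]] = 0.5
    s_bio, s_batch = partial_scores(row)
    assert s_bio == pytest.approx(np.mean(vals))
    assert s_batch == pytest.approx(0.5)
    empty_batch = row.copy()
    empty_batch[list(BATCH_METRICS)] = np.nan
    assert partial_scores(empty_batch)[1] is None


def test_overall_scores_bounded(rng):
    df = _random_table(rng)
    out = overall_scores(df)
    assert ((out["overall_score"] >= 0) & (out["overall_score"] <= 1)).all()


def test_raising_a_metric_never_lowers_overall_at_fixed_bounds(rng):
    df = _random_table(rng)
    scaled = scale_results(df)
    base = overall_scores(scaled, scale=False)
    bumped = scaled.copy()
    # raise one mid-range entry without touching the column's 0/1 bounds
    col = scaled.columns[0]
    mid = scaled[col].sub(0.5).abs().idxmin()
    bumped.loc[mid, col] = min(1.0, scaled.loc[mid, col] + 0.1)
    out = overall_scores(bumped, scale=False)
    assert out.loc[mid, "overall_score"] >= base.loc[mid, "overall_score"]


# ------------------------------------------------------------------- ranking


def _task(scores: dict) -> pd.DataFrame:
    rows = []
    for method, vals in scores.items():
        for i, v in enumerate(np.atleast_1d(vals)):
            rows.append({"method": method, "overall_score": v})
    return pd.DataFrame(rows)


def test_failed_method_inherits_unintegrated_rank():
    t1 = _task({"A": 0.9, "B": 0.5, "Unintegrated": 0.2})
    t2 = _task({"A": 0.9, "Unintegrated": 0.2})  # B failed this task
    ranking = rank_methods({"t1": t1, "t2": t2})
    # in t2 the unintegrated reference ranks 2nd of 2; B inherits that rank
    assert ranking.loc["B", "t2"] == 2.0
    assert ranking.loc["B", "mean_rank"] == pytest.approx(2.0)
    assert ranking.loc["A", "mean_rank"] == pytest.approx(1.0)


def test_single_task_ranking_equals_within_task_order():
    t1 = _task({"A": [0.9, 0.7], "B": 0.5, "C": 0.8, "Unintegrated": 0.2})
    ranking = rank_methods({"t1": t1})
    assert list(ranking.index) == ["A", "C", "B"]
    assert ranking.loc["A", "mean_rank"] == 1.0  # best combination (0.9) used


def test_mean_rank_matches_bruteforce(rng):
    tasks = {}
    methods = ["A", "B", "C", "Unintegrated"]
    for t in range(3):
        tasks[f"t{t}"] = _task(
            {m: rng.uniform(size=2).tolist() for m in methods}
        )
    ranking = rank_methods(tasks)
    # brute-force recomputation
    expect = {}
    for m in ["A", "B", "C"]:
        ranks = []
        for t, table in tasks.items():
            best = table.groupby("method")["overall_score"].max()
            r = pd.Series(rankdata(-best.to_numpy()), index=best.index)
            ranks.append(r[m])
        expect[m] = np.mean(ranks)
    for m, v in expect.items():
        assert ranking.loc[m, "mean_rank"] == pytest.approx(v)


def test_ranking_invariant_to_row_order(rng):
    t = _task({"A": [0.9, 0.3], "B": 0.5, "Unintegrated": 0.2})
    shuffled = t.sample(frac=1.0, random_state=1)
    r1 = rank_methods({"t": t})
    r2 = rank_methods({"t": shuffled})
    pd.testing.assert_frame_equal(r1, r2)


def test_missing_unintegrated_row_rejected():
    with pytest.raises(ParameterError):
        rank_methods({"t": _task({"A": 0.9})})


# --------------------------------------------------------------- scalability


def test_scalability_endpoints():
    # constant curve at the ceiling -> score 0
    c_time = 1e8
    assert scalability_score([1e4, 1e6], [c_time, c_time], "time") == pytest.approx(0.0)
    # f(A) = f(B) = 0 (1 second everywhere) -> score 1
    assert scalability_score([1e4, 1e6], [1.0, 1.0], "time") == pytest.approx(1.0)


def test_scalability_two_point_fit_matches_trapezoid():
    n = [1e4, 1e6]
    secs = [10.0, 1000.0]
    a, b = loglinear_fit(n, secs)
    f = lambda x: a * np.log(x) + b
    trapezoid = 0.5 * (np.log(1e6) - np.log(1e4)) * (f(1e4) + f(1e6))
    expected = 1.0 - trapezoid / ((np.log(1e6) - np.log(1e4)) * np.log(1e8))
    assert scalability_score(n, secs, "time") == pytest.approx(expected)


def test_scalability_needs_two_distinct_sizes():
    with pytest.raises(ParameterError):
        scalability_score([1e4, 1e4], [1.0, 2.0], "time")


def test_feature_fit_recovers_noiseless_coefficients(rng):
    n = rng.integers(1_000, 1_000_000, size=30).astype(float)
    f = rng.integers(500, 20_000, size=30).astype(float)
    y = np.exp(0.5 + 1.2 * np.log(n) + 0.3 * np.log(f))
    b0, b1, b2 = feature_scaling_fit(n, f, y)
    assert (b0, b1, b2) == pytest.approx((0.5, 1.2, 0.3), abs=1e-9)


def test_feature_fit_recovers_noisy_coefficients(rng):
    n = rng.integers(1_000, 1_000_000, size=50).astype(float)
    f = rng.integers(500, 20_000, size=50).astype(float)
    y = np.exp(0.5 + 1.2 * np.log(n) + 0.3 * np.log(f) + rng.normal(0, 0.1, 50))
    _, b1, b2 = feature_scaling_fit(n, f, y)
    assert b1 == pytest.approx(1.2, abs=0.1)
    assert b2 == pytest.approx(0.3, abs=0.15)


def test_feature_fit_rejects_collinear_design():
    n = np.array([1e3, 1e4, 1e5])
    with pytest.raises(ParameterError):
        feature_scaling_fit(n, n, np.array([1.0, 2.0, 3.0]))


def test_scalability_record_validation():
    with pytest.raises(ParameterError):
        ScalabilityRecord(n_cells=0, n_features=10, cpu_time=1.0, peak_mem=1.0)


# ----------------------------------------------------------------- usability


def test_usability_formulas():
    assert response_score(0.0) == 30.0
    assert activity_score(0, 2.0) == 0.0  # log10(1) = 0
    assert activity_score(9, 1.0) == pytest.approx(1.0)  # log10(10)
    with pytest.raises(ParameterError):
        activity_score(5, 0.0)


def test_usability_table_rescaled_and_summed():
    records = {
        "fast": UsabilityRecord(
            package_categories=[1, 1, 1, 1, 1, 1],
            paper_categories=[1, 1, 1, 1],
            closed_issues=90,
            repo_age_years=1.0,
            median_response_days=0.0,
        ),
        "slow": UsabilityRecord(
            package_categories=[0.5] * 6,
            paper_categories=[0.5] * 4,
            closed_issues=0,
            repo_age_years=2.0,
            median_response_days=20.0,
        ),
    }
    df = usability_table(records)
    assert df.loc["fast", "response_raw"] == 30.0
    assert df.loc["fast", "response"] == 1.0 and df.loc["slow", "response"] == 0.0
    assert df.loc["fast", "usability"] == pytest.approx(2.0)
    assert df.loc["slow", "usability"] == pytest.approx(1.0)


# ---------------------------------------------------------- scheme robustness


def test_minmax_vs_zscore_rank_correlation_computable(rng):
    df = _random_table(rng, n_runs=10)
    r = compare_scaling_schemes(df)
    assert -1.0 <= r <= 1.0
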