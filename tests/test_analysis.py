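import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from aquabatch import analysis
from aquabatch.errors import ValidationError


# ------------------------------------------------------ window summaries

def brute_force_windows(times, values, width):
    """Independent partition + textbook sample statistics."""
    pairs = [(t, v) for t, v in zip(times, values) if not pd.isna(t)]
    t0 = min(t for t, _ in pairs)
    tmax = max(t for t, _ in pairs)
    rows = []
    start = t0
    while start <= tmax:
        inside = [v for t, v in pairs if start <= t < start + width
                  and not pd.isna(v)]
        n = len(inside)
        mean = statistics.fmean(inside) if n else float("nan")
        sd = statistics.stdev(inside) if n >= 2 else float("nan")
        cv = sd / mean if n >= 2 and mean != 0 else float("nan")
        rows.append((start, min(start + width - 1, tmax), n, mean, sd, cv))
        start += width
    return rows


def test_two_windows_of_five_years():
    table = pd.DataFrame({"year": range(2020, 2030), "v": range(1, 11)})
    out = analysis.time_window_summary(table, "v", "year", 5)
    assert len(out) == 2
    assert out["mean"].tolist() == [3.0, 8.0]
    assert out["sd"].iloc[0] == pytest.approx(1.5811, abs=1e-4)
    assert out["window_start"].tolist() == [2020, 2025]
    assert out["window_end"].tolist() == [2024, 2029]


def test_eighty_years_width_twenty_gives_four_windows():
    table = pd.DataFrame({"year": range(2020, 2100), "v": 1.0})
    out = analysis.time_window_summary(table, "v", "year", 20)
    assert len(out) == 4


def test_constant_value_has_zero_cv():
    table = pd.DataFrame({"t": range(8), "v": 2.0})
    out = analysis.time_window_summary(table, "v", "t", 4)
    assert (out["mean"] == 2.0).all()
    assert (out["sd"] == 0.0).all()
    assert (out["cv"] == 0.0).all()


def test_zero_mean_cv_missing():
    table = pd.DataFrame({"t": range(4), "v": 0.0})
    out = analysis.time_window_summary(table, "v", "t", 4)
    assert out["sd"].iloc[0] == 0.0
    assert out["cv"].isna().all()


def test_partial_final_window_flagged():
    table = pd.DataFrame({"t": range(2000, 2007), "v": 1.0})
    out = analysis.time_window_summary(table, "v", "t", 5)
    assert out["window_end"].tolist() == [2004, 2006]


def test_width_and_column_validation():
    table = pd.DataFrame({"t": [1], "v": [1.0]})
    with pytest.raises(ValidationError, match="width"):
        analysis.time_window_summary(table, "v", "t", 0)
    with pytest.raises(ValidationError, match="missing_col"):
        analysis.time_window_summary(table, "missing_col", "t", 1)


def test_windows_match_brute_force_oracle():
    rng = np.random.default_rng(7)
    times = rng.integers(1990, 2041, 200)
    values = rng.normal(5, 2, 200)
    values[rng.random(200) < 0.15] = np.nan
    table = pd.DataFrame({"t": times, "v": values})
    out = analysis.time_window_summary(table, "v", "t", 7)
    oracle = brute_force_windows(times, values, 7)
    assert len(out) == len(oracle)
    for row, (start, end, n, mean, sd, cv) in zip(out.itertuples(), oracle):
        assert row.window_start == start and row.window_end == end
        assert row.n == n
        if n:
            assert row.mean == pytest.approx(mean, abs=1e-9)
        if n >= 2:
            assert row.sd == pytest.approx(sd, abs=1e-9)


@given(st.lists(st.tuples(st.integers(0, 50),
                          st.one_of(st.none(), st.floats(-50, 50))),
                min_size=1, max_size=60),
       st.integers(1, 9))
def test_window_partition_property(records, width):
    """Every non-missing record is counted in exactly one window."""
    table = pd.DataFrame(records, columns=["t", "v"])
    out = analysis.time_window_summary(table, "v", "t", width)
    assert out["n"].sum() == table["v"].notna().sum()
    starts = out["window_start"].to_numpy()
    assert np.allclose(np.diff(starts), width)


def test_grouped_windows_align_across_groups():
    table = pd.DataFrame({
        "g": ["a"] * 5 + ["b"] * 5,
        "t": [2000, 2001, 2002, 2003, 2004, 2003, 2004, 2005, 2006, 2007],
        "v": 1.0,
    })
    out = analysis.time_window_summary(table, "v", "t", 4, ["g"])
    # windows anchored at the global minimum (2000), aligned for both groups
    assert sorted(out["window_start"].unique()) == [2000, 2004]
    assert out["n"].sum() == 10


# ------------------------------------------------------------ regression

def test_perfect_line():
    table = pd.DataFrame({"x": [1, 2, 3], "y": [2, 4, 6]})
    out = analysis.linear_regression(table, "y", "x")
    row = out.iloc[0]
    assert row["slope"] == pytest.approx(2.0)
    assert row["intercept"] == pytest.approx(0.0)
    assert row["r_squared"] == pytest.approx(1.0)
    assert row["p_value"] == pytest.approx(0.0, abs=1e-12)


def test_hand_computed_ols():
    table = pd.DataFrame({"x": [1, 2, 3], "y": [1, 3, 2]})
    row = analysis.linear_regression(table, "y", "x").iloc[0]
    assert row["slope"] == pytest.approx(0.5)
    assert row["intercept"] == pytest.approx(1.0)
    assert row["r_squared"] == pytest.approx(0.25)


def test_groupwise_independence():
    table = pd.DataFrame({
        "g": ["up"] * 3 + ["down"] * 3,
        "x": [0, 1, 2, 0, 1, 2],
        "y": [0, 1, 2, 0, -1, -2],
    })
    out = analysis.linear_regression(table, "y", "x", ["g"]).set_index("g")
    assert out.loc["up", "slope"] == pytest.approx(1.0)
    assert out.loc["down", "slope"] == pytest.approx(-1.0)


def test_constant_y_r_squared_missing():
    table = pd.DataFrame({"x": [1, 2, 3], "y": 5.0})
    row = analysis.linear_regression(table, "y", "x").iloc[0]
    assert row["slope"] == pytest.approx(0.0)
    assert math.isnan(row["r_squared"])


def test_degenerate_x_warns_and_yields_missing_slope(caplog):
    table = pd.DataFrame({"x": [2, 2, 2], "y": [1, 2, 3]})
    with caplog.at_level("WARNING"):
        row = analysis.linear_regression(table, "y", "x").iloc[0]
    assert math.isnan(row["slope"])
    assert any("degenerate" in r.message for r in caplog.records)


def test_too_few_points_gives_missing_fields():
    table = pd.DataFrame({"x": [1.0], "y": [2.0]})
    row = analysis.linear_regression(table, "y", "x").iloc[0]
    assert row["n"] == 1
    assert math.isnan(row["slope"]) and math.isnan(row["p_value"])


def _statsmodels_oracle(x, y):
    import statsmodels.api as sm
    model = sm.OLS(y, sm.add_constant(np.asarray(x, dtype=float))).fit()
    return {"slope": model.params[1], "intercept": model.params[0],
            "r_squared": model.rsquared, "p_value": model.pvalues[1]}


@pytest.mark.parametrize("seed", range(10))
def test_ols_matches_statsmodels(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 30))
    x = rng.normal(0, 3, n)
    y = 1.5 * x + rng.normal(0, 2, n)
    fit = analysis.ols_fit(x, y)
    oracle = _statsmodels_oracle(x, y)
    for key, value in oracle.items():
        assert fit[key] == pytest.approx(value, abs=1e-9), key


def test_p_value_is_two_sided_student_t():
    from scipy import stats
    rng = np.random.default_rng(0)
    x = rng.normal(size=12)
    y = 0.4 * x + rng.normal(size=12)
    fit = analysis.ols_fit(x, y)
    # reconstruct the t statistic from the reported quantities
    n = fit["n"]
    r2 = fit["r_squared"]
    t = math.copysign(math.sqrt(r2 * (n - 2) / (1 - r2)), fit["slope"])
    assert fit["p_value"] == pytest.approx(2 * stats.t.sf(abs(t), n - 2), rel=1e-9)
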