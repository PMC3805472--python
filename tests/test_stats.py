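"""Robust regression, slope tests, rates, binning, interaction GLMs."""

import numpy as np
import pandas as pd
import pytest

import delaychoice as dc
from delaychoice import stats


def test_robust_fit_noiseless_line():
    x = np.linspace(-3, 3, 30)
    fit = stats.robust_fit(x, 2.0 * x)
    assert fit.coef[1] == pytest.approx(2.0, abs=1e-8)
    assert fit.coef[0] == pytest.approx(0.0, abs=1e-8)


def test_robust_fit_matches_ols_on_clean_gaussian_data():
    rng = np.random.default_rng(1)
    x = rng.normal(size=200)
    y = 1.0 + 0.7 * x + rng.normal(scale=0.5, size=200)
    robust = stats.robust_fit(x, y)
    ols = np.polyfit(x, y, 1)
    assert robust.coef[1] == pytest.approx(ols[0], rel=0.02)


def test_robust_fit_resists_gross_outlier():
    """One wild response barely moves the robust slope but wrecks OLS."""
    rng = np.random.default_rng(2)
    x = rng.normal(size=40)
    y = 2.0 * x + rng.normal(scale=0.3, size=40)
    clean = stats.robust_fit(x, y).coef[1]
    y_out = y.copy()
    y_out[np.argmax(x)] += 100 * y.std()
    robust = stats.robust_fit(x, y_out).coef[1]
    ols_clean = np.polyfit(x, y, 1)[0]
    ols_out = np.polyfit(x, y_out, 1)[0]
    assert abs(robust - clean) / abs(clean) < 0.05
    assert abs(ols_out - ols_clean) / abs(ols_clean) > 0.20


def test_robust_fit_errors():
    with pytest.raises(ValueError, match="constant response"):
        stats.robust_fit([1, 2, 3, 4], [5, 5, 5, 5])
    with pytest.raises(ValueError, match="rank-deficient"):
        stats.robust_fit(np.ones((6, 2)), np.arange(6.0))
    with pytest.raises(ValueError, match="more observations"):
        stats.robust_fit([1.0, 2.0], [1.0, 2.0])


def test_per_subject_slope_test_power_and_degeneracy():
    rng = np.random.default_rng(3)
    tables = []
    for _ in range(12):
        x = rng.uniform(0, 20, 30)
        tables.append(pd.DataFrame({"x": x, "y": 0.5 * x + rng.normal(0, 0.5, 30)}))
    res = stats.per_subject_slope_test(tables, "x", "y", side="greater")
    assert res.p < 0.001 and res.df == 11
    assert res.detail["mean_slope"] == pytest.approx(0.5, abs=0.1)
    with pytest.raises(ValueError, match="at least 2 subjects"):
        stats.per_subject_slope_test(tables[:1], "x", "y")
    with pytest.raises(ValueError, match="3 usable trials"):
        stats.per_subject_slope_test([tables[0].iloc[:2]], "x", "y")


def test_nonimpulsive_rate_hand_counts():
    df = pd.DataFrame({
        "choice": ["nonimpulsive", "nonimpulsive", "nonimpulsive", "impulsive"],
        "condition": ["ecological"] * 2 + ["control"] * 2,
    })
    assert stats.nonimpulsive_rate(df) == 0.75
    assert stats.nonimpulsive_rate(df, "ecological") == 1.0
    assert stats.nonimpulsive_rate(
        df.assign(choice="impulsive")) == 0.0
    with pytest.raises(ValueError):
        stats.nonimpulsive_rate(df[df["condition"] == "nope"])


def test_bin_summary_hand_computed():
    # 18 points into 9 bins -> 2 points per bin, means checkable by hand
    x = np.arange(18.0)
    y = x ** 2
    out = stats.bin_summary(pd.DataFrame({"x": x, "y": y}), "x", "y", 9)
    assert len(out) == 9
    assert out["x_mean"].tolist() == pytest.approx([0.5, 2.5, 4.5, 6.5, 8.5,
                                                    10.5, 12.5, 14.5, 16.5])
    assert out["y_mean"].iloc[0] == pytest.approx((0 + 1) / 2)
    assert out["y_mean"].iloc[-1] == pytest.approx((16 ** 2 + 17 ** 2) / 2)
    assert out["y_mean"].is_monotonic_increasing


def test_bin_summary_single_bin_and_mass_conservation():
    rng = np.random.default_rng(4)
    df = pd.DataFrame({"x": rng.uniform(size=101), "y": rng.normal(size=101)})
    one = stats.bin_summary(df, "x", "y", 1)
    assert one["y_mean"].iloc[0] == pytest.approx(df["y"].mean())
    # weighted mean of bin means (weights = bin counts) equals the overall mean
    nine = stats.bin_summary(df, "x", "y", 9)
    per = df.copy()
    order = np.argsort(per["x"].to_numpy(), kind="stable")
    bins = np.empty(len(per), int)
    bins[order] = (np.arange(len(per)) * 9) // len(per)
    w = pd.Series(bins).value_counts().sort_index().to_numpy()
    assert float(np.average(nine["y_mean"], weights=w)) == pytest.approx(df["y"].mean())


def _interaction_data(rng, n=19, slope_eco=1.0, slope_ctl=0.0, noise=0.3):
    x = rng.normal(size=n)
    rows = []
    for i in range(n):
        rows.append({"subject": i, "condition": "ecological", "X": x[i],
                     "Y": slope_eco * x[i] + rng.normal(0, noise)})
        rows.append({"subject": i, "condition": "control", "X": x[i],
                     "Y": slope_ctl * x[i] + rng.normal(0, noise)})
    return pd.DataFrame(rows)


def test_interaction_correlation_test_detects_condition_specific_slope():
    rng = np.random.default_rng(5)
    data = _interaction_data(rng)
    res = stats.interaction_correlation_test(data, side="greater")
    assert res.interaction_t > 2 and res.interaction_p < 0.05
    assert res.coef["X:Z"] == pytest.approx(1.0, abs=0.4)


def test_interaction_correlation_test_errors():
    rng = np.random.default_rng(6)
    data = _interaction_data(rng)
    with pytest.raises(ValueError, match="missing condition"):
        stats.interaction_correlation_test(data.iloc[:-1])
    data2 = data.copy()
    data2["agecopy"] = data2["X"]  # perfectly collinear covariate
    with pytest.raises(ValueError, match="rank-deficient"):
        stats.interaction_correlation_test(data2, covariates=("agecopy",))


def _rates_frame(rng, n=15, eco_shift_a=0.0):
    rows = []
    for g, shift in (("A", eco_shift_a), ("B", 0.0)):
        for i in range(n):
            base = rng.normal(0.5, 0.1)
            rows.append({"subject": f"{g}{i}", "group": g, "condition": "control",
                         "nonimpulsive_rate": base + rng.normal(0, 0.05)})
            rows.append({"subject": f"{g}{i}", "group": g, "condition": "ecological",
                         "nonimpulsive_rate": base - shift + rng.normal(0, 0.05)})
    return pd.DataFrame(rows)


def test_group_condition_interaction_detects_built_in_effect():
    rng = np.random.default_rng(7)
    res = stats.group_condition_interaction(_rates_frame(rng, eco_shift_a=0.25))
    assert res.p < 0.01
    assert res.df == (1.0, 28.0)
    with pytest.raises(ValueError):
        stats.group_condition_interaction(_rates_frame(rng).iloc[:4])


def test_covariate_adjusted_group_test():
    rng = np.random.default_rng(8)
    n = 15
    group = ["AD"] * n + ["CTL"] * n
    age = rng.normal(75, 5, 2 * n)
    delta = np.where(np.array(group) == "AD", -0.3, 0.0) + rng.normal(0, 0.05, 2 * n)
    res = stats.covariate_adjusted_group_test(delta, group, age)
    assert res["group"].p < 0.001
    assert res["age"].p > 0.05
    with pytest.warns(UserWarning, match="age is constant"):
        res = stats.covariate_adjusted_group_test(delta, group, np.full(2 * n, 70.0))
    assert "age" not in res and res["group"].p < 0.001


def test_one_sided_p_is_half_two_sided_on_correct_side():
    assert stats._one_sided_p(2.0, 10, "greater") == pytest.approx(
        stats._one_sided_p(2.0, 10, "two-sided") / 2)
    # on the wrong side the one-sided p is large, not halved
    assert stats._one_sided_p(-2.0, 10, "greater") > 0.95
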