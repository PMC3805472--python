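"""Discounting model: value transform, softmax, likelihood, ML fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import delaychoice as dc
from delaychoice.model import GRID_LNBETA, GRID_LOG10K, ModelParams, _grid_nll, _unpack
from conftest import synth_trials

finite = st.floats(-50, 50)


def test_transform_monetary_endpoints_and_midpoint():
    out = dc.transform_monetary([0.5, 72.0])
    assert out == pytest.approx([-10.0, 10.0])
    out = dc.transform_monetary([0.5, 36.25, 72.0])
    assert out == pytest.approx([-10.0, 0.0, 10.0])
    # an explicit theoretical range can replace the empirical one
    out = dc.transform_monetary([36.25], amount_range=(0.5, 72.0))
    assert out == pytest.approx([0.0])
    with pytest.raises(ValueError, match="degenerate"):
        dc.transform_monetary([3.0, 3.0, 3.0])


def test_discounted_value_examples():
    assert dc.discounted_value(10, 0, 0.5) == 10.0
    assert dc.discounted_value(8, 365, 1 / 365) == pytest.approx(4.0)
    # negative values shrink toward zero with delay
    assert dc.discounted_value(-5, 365, 1 / 365) == pytest.approx(-2.5)
    with pytest.raises(ValueError):
        dc.discounted_value(5, -1, 0.01)
    with pytest.raises(ValueError):
        dc.discounted_value(5, 10, -0.01)


@given(R=st.floats(0.1, 20), k=st.floats(1e-4, 1), d1=st.floats(1, 3000),
       dd=st.floats(1, 1000))
@settings(max_examples=60, derandomize=True)
def test_discounting_monotone_in_delay(R, k, d1, dd):
    """V is strictly decreasing in D for positive R, increasing for negative R."""
    assert dc.discounted_value(R, d1 + dd, k) < dc.discounted_value(R, d1, k)
    assert dc.discounted_value(-R, d1 + dd, k) > dc.discounted_value(-R, d1, k)


def test_choice_probability_examples():
    assert dc.choice_probability(3.3, 3.3, 1.7) == pytest.approx(0.5)
    assert dc.choice_probability(10, 0, 10) == pytest.approx(1 / (1 + math.exp(-1)))
    # overflow-safe at extreme value differences
    p = dc.choice_probability(-500, 500, 1)
    assert 0 <= p < 1e-100
    with pytest.raises(ValueError):
        dc.choice_probability(1, 2, 0.0)


@given(vi=finite, vd=finite, beta=st.floats(0.01, 100))
@settings(max_examples=80, derandomize=True)
def test_softmax_complementarity(vi, vd, beta):
    """P(imp|Vi,Vd) + P(imp|Vd,Vi) = 1 for all finite inputs."""
    assert dc.choice_probability(vi, vd, beta) + dc.choice_probability(vd, vi, beta) \
        == pytest.approx(1.0, abs=1e-12)


def test_nll_equal_values_is_n_log2():
    n = 37
    trials = pd.DataFrame({
        "Vi": np.full(n, 2.0), "R_d": np.full(n, 4.0), "D_days": np.full(n, 365.0),
        "choice": ["impulsive", "nonimpulsive"] * 18 + ["impulsive"],
    })
    # k chosen so Vd = 4/2 = 2 = Vi on every trial
    params = ModelParams(k=1 / 365, beta=1.3)
    assert dc.negative_log_likelihood(params, trials) == pytest.approx(n * math.log(2))


def test_nll_single_trial():
    trials = pd.DataFrame({"Vi": [10.0], "R_d": [0.0], "D_days": [365.0],
                           "choice": ["impulsive"]})
    nll = dc.negative_log_likelihood(ModelParams(k=0.01, beta=10.0), trials)
    assert nll == pytest.approx(-math.log(1 / (1 + math.exp(-1))), abs=1e-4)
    with pytest.raises(ValueError, match="empty"):
        dc.negative_log_likelihood(ModelParams(k=0.01, beta=1.0), trials.iloc[:0])


def test_fit_recovers_parameters_and_beats_coinflip(rng):
    trials = synth_trials(k=0.01, beta=2.0, n=720, rng=rng)
    fit = dc.fit_parameters(trials)
    assert abs(math.log10(fit.params.k) - math.log10(0.01)) < 0.2
    assert 1.0 < fit.params.beta < 4.0
    assert not fit.boundary
    # fitted model at least as good as coin-flipping
    assert -fit.log_likelihood <= len(trials) * math.log(2) + 1e-6
    # and the returned optimum beats the true parameters (it is the MLE)
    assert -fit.log_likelihood <= dc.negative_log_likelihood(
        ModelParams(0.01, 2.0), trials) + 1e-6


def test_fit_agrees_with_dense_grid_oracle(rng):
    """Grid+refine optimum matches an independent dense brute-force search."""
    dense_k = np.linspace(-5, 0, 151)
    dense_b = np.linspace(-2, 3, 151)
    for rep in range(10):
        trials = synth_trials(k=10 ** rng.uniform(-3.5, -1), beta=rng.uniform(1, 4),
                              n=120, rng=rng)
        fit = dc.fit_parameters(trials)
        vi, rd, d, sign = _unpack(trials)
        nll, kg, bg = _grid_nll(vi, rd, d, sign, dense_k, dense_b)
        ik, ib = np.unravel_index(np.argmin(nll), nll.shape)
        # the refined optimum is at least as good as the dense-grid optimum
        assert -fit.log_likelihood <= nll[ik, ib] + 1e-6
        if not fit.boundary:
            assert abs(math.log10(fit.params.k) - dense_k[ik]) <= 2 * (5 / 150)
            assert abs(math.log(fit.params.beta) - dense_b[ib]) <= 2 * (5 / 150)


def test_fit_is_invariant_to_trial_order(rng):
    trials = synth_trials(k=0.02, beta=2.0, n=72, rng=rng)
    shuffled = trials.sample(frac=1.0, random_state=3).reset_index(drop=True)
    f1, f2 = dc.fit_parameters(trials), dc.fit_parameters(shuffled)
    assert f1.params.k == pytest.approx(f2.params.k, rel=1e-6)
    assert f1.params.beta == pytest.approx(f2.params.beta, rel=1e-6)


def test_group_fit_pools_trials(rng):
    """A group fit on two identical subjects equals the subject fit on one."""
    trials = synth_trials(k=0.01, beta=2.0, n=144, rng=rng)
    pooled = pd.concat([trials, trials], ignore_index=True)
    f1 = dc.fit_parameters(trials, mode="subject")
    f2 = dc.fit_parameters(pooled, mode="group")
    assert f2.mode == "group"
    assert f1.params.k == pytest.approx(f2.params.k, rel=1e-4)
    assert f1.params.beta == pytest.approx(f2.params.beta, rel=1e-4)


def test_degenerate_choices_flagged_not_raised(rng):
    trials = synth_trials(k=0.01, beta=2.0, n=40, rng=rng)
    trials["choice"] = "nonimpulsive"
    fit = dc.fit_parameters(trials)
    assert fit.degenerate and fit.boundary


def test_prediction_score_limits_and_recount(rng):
    trials = synth_trials(k=0.01, beta=2.0, n=300, rng=rng)
    params = ModelParams(k=0.01, beta=2.0)
    vd = dc.discounted_value(trials["R_d"], trials["D_days"], 0.01)
    argmax = np.where(trials["Vi"].to_numpy() > vd, "impulsive", "nonimpulsive")
    det = trials.copy()
    det["choice"] = argmax
    assert dc.prediction_score(params, det[det["Vi"] != vd]) == 100.0
    anti = trials.copy()
    anti["choice"] = np.where(argmax == "impulsive", "nonimpulsive", "impulsive")
    assert dc.prediction_score(params, anti[anti["Vi"] != vd]) == 0.0
    # brute-force recount over the simulated table
    score = dc.prediction_score(params, trials)
    correct = tot = 0
    for _, row in trials.iterrows():
        v_del = row["R_d"] / (1 + 0.01 * row["D_days"])
        if row["Vi"] == v_del:
            continue
        tot += 1
        model_says = "impulsive" if row["Vi"] > v_del else "nonimpulsive"
        correct += (model_says == row["choice"])
    assert score == pytest.approx(100 * correct / tot)
    assert 50 < score < 100


def test_prediction_score_excludes_ties():
    trials = pd.DataFrame({
        "Vi": [2.0, 2.0, 5.0], "R_d": [4.0, 4.0, 4.0], "D_days": [365.0] * 3,
        "choice": ["impulsive", "nonimpulsive", "impulsive"],
    })
    params = ModelParams(k=1 / 365, beta=1.0)  # Vd = 2 on every trial
    # first two trials tie (Vi == Vd) and drop out; third is a correct call
    assert dc.prediction_score(params, trials) == 100.0


def test_value_difference_hand_computed():
    trials = pd.DataFrame({
        "Vi": [3.0, -2.0, 0.0], "R_d": [8.0, 4.0, -6.0],
        "D_days": [365.0, 365.0, 730.0],
        "choice": ["impulsive", "nonimpulsive", "impulsive"],
    })
    out = dc.value_difference(trials, ModelParams(k=1 / 365, beta=1.0))
    assert out["Vd"].tolist() == pytest.approx([4.0, 2.0, -2.0])
    assert out["dv_imm_del"].tolist() == pytest.approx([-1.0, -4.0, 2.0])
    # chosen-minus-unchosen flips sign for nonimpulsive choices
    assert out["dv_chosen_unchosen"].tolist() == pytest.approx([-1.0, 4.0, 2.0])


def test_value_difference_small_k_limit():
    """As k -> 0 the delayed option keeps its undiscounted value."""
    trials = pd.DataFrame({"Vi": [1.0], "R_d": [7.0], "D_days": [3650.0],
                           "choice": ["impulsive"]})
    out = dc.value_difference(trials, ModelParams(k=1e-12, beta=1.0))
    assert out["Vd"].iloc[0] == pytest.approx(7.0)


def test_model_params_validation():
    with pytest.raises(ValueError):
        ModelParams(k=0.0, beta=1.0)
    with pytest.raises(ValueError):
        ModelParams(k=0.01, beta=-1.0)
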