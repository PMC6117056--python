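"""Normality-gated comparisons, correlations, stepwise regression."""

import numpy as np
import pandas as pd
import pytest

from lunghetero.stats import (
    benjamini_hochberg,
    compare_groups,
    correlate,
    stepwise_regression,
)


def _two_group_table(a, b):
    return pd.DataFrame(
        {
            "group": ["COPD"] * len(a) + ["control"] * len(b),
            "v": np.concatenate([a, b]),
        }
    )


def test_identical_groups_give_t_zero_p_one():
    rng = np.random.default_rng(0)
    sample = rng.normal(10, 2, 15)
    res = compare_groups(_two_group_table(sample, sample), "v")
    assert res.test_used == "t"
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.pvalue == pytest.approx(1.0)


def test_constant_variable_reported_degenerate():
    res = compare_groups(_two_group_table(np.full(5, 3.0), np.arange(5.0)), "v")
    assert res.test_used == "degenerate"
    assert np.isnan(res.pvalue)
    assert "constant" in res.note


def test_lognormal_skew_triggers_mann_whitney_gate():
    """The Shapiro-Wilk gate should catch a heavily log-skewed group in the
    vast majority of replicates at n=20."""
    triggered = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        skewed = np.exp(rng.normal(0.0, 1.5, 20))
        normal = rng.normal(5.0, 1.0, 20)
        res = compare_groups(_two_group_table(skewed, normal), "v")
        triggered += res.test_used == "Mann-Whitney"
    assert triggered > 90


def test_gate_consistency_between_fields():
    rng = np.random.default_rng(1)
    res = compare_groups(_two_group_table(rng.normal(0, 1, 12), rng.normal(1, 1, 12)), "v")
    gate_fails = min(res.normality_p.values()) < res.alpha_normality
    assert (res.test_used == "Mann-Whitney") == gate_fails


def test_summaries_report_median_and_quartiles():
    a = np.arange(1.0, 12.0)
    rng = np.random.default_rng(2)
    res = compare_groups(_two_group_table(a, rng.normal(6, 1, 11)), "v")
    s = res.summaries["COPD"]
    assert s["median"] == 6.0
    assert s["q25"] == 3.5
    assert s["q75"] == 8.5


def test_correlate_exact_linear_relations():
    x = np.arange(10.0)
    t = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": -x})
    assert correlate(t, "x", "y").r == pytest.approx(1.0)
    assert correlate(t, "x", "z").r == pytest.approx(-1.0)


def test_correlate_hand_computed_five_points():
    t = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]})
    res = correlate(t, "x", "y")
    assert res.method == "pearson"
    assert res.r == pytest.approx(0.8, abs=1e-12)


def test_correlate_switches_to_spearman_on_skew():
    rng = np.random.default_rng(3)
    x = np.exp(rng.normal(0, 1.5, 30))
    t = pd.DataFrame({"x": x, "y": x + rng.normal(0, 0.1, 30)})
    assert correlate(t, "x", "y").method == "spearman"


def test_correlate_requires_four_pairs():
    t = pd.DataFrame({"x": [1.0, 2, 3], "y": [1.0, 2, 3]})
    with pytest.raises(ValueError, match="complete pairs"):
        correlate(t, "x", "y")


# ---------------------------------------------------------------------------
# stepwise


def _stepwise_table(seed, n=40, signal=True):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 4))
    y = 2.0 * X[:, 0] + rng.normal(0, 0.1, n) if signal else rng.standard_normal(n)
    return pd.DataFrame(
        {"y": y, "x1": X[:, 0], "x2": X[:, 1], "x3": X[:, 2], "x4": X[:, 3]}
    )


def test_strong_single_signal_selected():
    rep = stepwise_regression(_stepwise_table(0), "y", ["x1", "x2", "x3", "x4"])
    assert "x1" in rep.selected
    assert rep.r_squared > 0.99


def test_null_outcome_yields_empty_selection_r2_zero():
    # a fixed seed where no null candidate clears p_enter
    for seed in range(20):
        rep = stepwise_regression(
            _stepwise_table(seed, signal=False), "y", ["x1", "x2", "x3", "x4"]
        )
        if not rep.selected:
            assert rep.r_squared == 0.0
            assert set(rep.unselected) == {"x1", "x2", "x3", "x4"}
            return
    raise AssertionError("no replicate produced an empty selection")


def test_single_predictor_standardized_beta_equals_pearson_r():
    rng = np.random.default_rng(5)
    x = rng.standard_normal(40)
    y = 0.6 * x + rng.normal(0, 0.8, 40)
    t = pd.DataFrame({"y": y, "x1": x})
    rep = stepwise_regression(t, "y", ["x1"])
    r = correlate(t, "x1", "y").r
    assert rep.selected["x1"]["beta"] == pytest.approx(r, abs=1e-9)


def test_forward_trace_r2_non_decreasing():
    rng = np.random.default_rng(6)
    X = rng.standard_normal((60, 4))
    y = X[:, 0] + 0.5 * X[:, 1] + 0.25 * X[:, 2] + rng.normal(0, 0.3, 60)
    t = pd.DataFrame({"y": y, **{f"x{i+1}": X[:, i] for i in range(4)}})
    rep = stepwise_regression(t, "y", ["x1", "x2", "x3", "x4"])
    adds = [s["r_squared"] for s in rep.trace if s["action"] == "add"]
    assert all(b >= a - 1e-12 for a, b in zip(adds, adds[1:]))
    assert 0.0 <= rep.r_squared <= 1.0


def test_collinear_candidate_skipped_with_warning():
    rng = np.random.default_rng(7)
    x = rng.standard_normal(40)
    t = pd.DataFrame({"y": x + rng.normal(0, 0.1, 40), "x1": x, "x2": x})
    with pytest.warns(UserWarning, match="collinear"):
        rep = stepwise_regression(t, "y", ["x1", "x2"])
    assert len(rep.selected) == 1


def test_report_table_mirrors_dash_layout():
    rep = stepwise_regression(_stepwise_table(0), "y", ["x1", "x2", "x3", "x4"])
    frame = rep.to_frame()
    assert list(frame["variable"]) == ["x1", "x2", "x3", "x4"]
    assert frame.loc[frame.variable == "x1", "selected"].item()
    unsel = frame[~frame.selected]
    assert unsel["beta"].isna().all()
    assert "cumulative R^2" in rep.summary()


def test_benjamini_hochberg_monotone():
    p = np.array([0.001, 0.01, 0.04, 0.2, 0.9])
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p)
    assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)
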