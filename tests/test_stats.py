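"""ANOVA, Tukey-Kramer, cubic trend, subjective scores, correlations."""

import numpy as np
import pandas as pd
import pytest

from neurolap import (correlate_subjective_objective, fit_polynomial_trend,
                      one_way_anova, subjective_scores, tukey_hsd)
from neurolap.synthetic import NEGATIVE_EMOTIONS, POSITIVE_EMOTIONS

CUBIC = (0.0039, -0.0614, 0.2623, -0.1343)


# -- ANOVA ---------------------------------------------------------------

def test_identical_groups_give_zero_f():
    g = {"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]}
    res = one_way_anova(g)
    assert res.F == 0.0
    assert res.eta_squared == 0.0


def test_hand_computed_two_group_anova():
    res = one_way_anova({"a": [1.0, 2.0], "b": [5.0, 6.0]})
    assert res.ss_between == pytest.approx(16.0)
    assert res.ss_within == pytest.approx(1.0)
    assert res.F == pytest.approx(32.0)
    assert res.eta_squared == pytest.approx(16.0 / 17.0)
    assert (res.df_between, res.df_within) == (1, 2)


def test_df_structure_for_cohort_sized_input():
    # 15 participants x 7 pathway means in tiers of 10/2/3
    rng = np.random.default_rng(0)
    groups = {"Potential": rng.normal(size=70),
              "Normal": rng.normal(size=14),
              "NoPotential": rng.normal(size=21)}
    res = one_way_anova(groups)
    assert (res.df_between, res.df_within) == (2, 102)


def test_ss_decomposition_identity_and_eta_interpretation():
    rng = np.random.default_rng(1)
    groups = {k: rng.normal(loc=i, size=rng.integers(5, 30))
              for i, k in enumerate("abcd")}
    res = one_way_anova(groups)
    all_vals = np.concatenate(list(groups.values()))
    sst = ((all_vals - all_vals.mean()) ** 2).sum()
    assert res.ss_between + res.ss_within == pytest.approx(sst, rel=1e-10)
    # eta^2 equals squared correlation with the group-mean prediction
    pred = np.concatenate([np.full(len(v), np.mean(v))
                           for v in groups.values()])
    r = np.corrcoef(all_vals, pred)[0, 1]
    assert res.eta_squared == pytest.approx(r ** 2, rel=1e-9)


def test_anova_agrees_with_scipy():
    from scipy.stats import f_oneway
    rng = np.random.default_rng(2)
    groups = {k: rng.normal(loc=i * 0.3, size=12) for i, k in enumerate("abc")}
    res = one_way_anova(groups)
    ref = f_oneway(*groups.values())
    assert res.F == pytest.approx(ref.statistic, rel=1e-10)
    assert res.p == pytest.approx(ref.pvalue, rel=1e-8)


def test_empty_group_rejected():
    with pytest.raises(ValueError, match="no observations"):
        one_way_anova({"a": [1.0, 2.0], "b": []})


# -- Tukey ---------------------------------------------------------------

def test_tukey_identical_groups():
    t = tukey_hsd({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
    row = t.iloc[0]
    assert row["mean_diff"] == 0.0
    assert row["p_adj"] == pytest.approx(1.0)


def test_tukey_detects_shifted_group():
    rng = np.random.default_rng(3)
    g = {"a": rng.normal(0, 1, 10), "b": rng.normal(0.1, 1, 10),
         "c": rng.normal(8, 1, 10)}
    t = tukey_hsd(g).set_index(["group1", "group2"])
    assert t.loc[("a", "c"), "p_adj"] < 0.001
    assert t.loc[("b", "c"), "p_adj"] < 0.001
    assert t.loc[("a", "b"), "p_adj"] > 0.5


def test_tukey_pair_order_antisymmetric():
    g = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 7.0], "c": [0.0, 1.0, 2.5]}
    t1 = tukey_hsd(g).set_index(["group1", "group2"])
    g_flipped = {"b": g["b"], "a": g["a"], "c": g["c"]}
    t2 = tukey_hsd(g_flipped).set_index(["group1", "group2"])
    assert t1.loc[("a", "b"), "mean_diff"] == pytest.approx(
        -t2.loc[("b", "a"), "mean_diff"])
    assert t1.loc[("a", "b"), "p_adj"] == pytest.approx(
        t2.loc[("b", "a"), "p_adj"])


def test_tukey_agrees_with_statsmodels():
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    rng = np.random.default_rng(4)
    groups = {"a": rng.normal(0, 1, 8), "b": rng.normal(0.8, 1, 12),
              "c": rng.normal(1.5, 1, 6)}
    ours = tukey_hsd(groups)
    vals = np.concatenate(list(groups.values()))
    labs = np.concatenate([[k] * len(v) for k, v in groups.items()])
    ref = pairwise_tukeyhsd(vals, labs)
    ref_p = {tuple(sorted((r[0], r[1]))): float(r[3])
             for r in ref.summary().data[1:]}
    for _, row in ours.iterrows():
        key = tuple(sorted((row["group1"], row["group2"])))
        assert row["p_adj"] == pytest.approx(ref_p[key], abs=2e-3)


def test_tukey_not_less_conservative_than_t():
    from scipy.stats import ttest_ind
    rng = np.random.default_rng(5)
    g = {"a": rng.normal(0, 1, 9), "b": rng.normal(0.7, 1, 9),
         "c": rng.normal(0.2, 1, 9)}
    t = tukey_hsd(g)
    for _, row in t.iterrows():
        p_t = ttest_ind(g[row["group1"]], g[row["group2"]]).pvalue
        assert row["p_adj"] >= p_t - 1e-12


def test_singleton_group_rejected():
    with pytest.raises(ValueError, match="fewer than 2"):
        tukey_hsd({"a": [1.0], "b": [1.0, 2.0]})


# -- trend fit -----------------------------------------------------------

def test_cubic_recovered_exactly_from_its_own_points():
    x = np.arange(2, 13, dtype=float)
    y = np.polyval(CUBIC, x)
    fit = fit_polynomial_trend(x, y, degree=3)
    assert np.allclose(fit.coefficients, CUBIC, atol=1e-9)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_constant_series_flat_fit():
    fit = fit_polynomial_trend(np.arange(2, 13.0), np.full(11, 0.45))
    assert np.allclose(fit.coefficients[:3], 0.0, atol=1e-12)
    assert fit.r_squared == 0.0


def test_linear_data_nested_in_cubic():
    x = np.arange(2, 13, dtype=float)
    fit = fit_polynomial_trend(x, 0.01 * x + 0.4)
    assert abs(fit.coefficients[0]) < 1e-12
    assert fit.r_squared == pytest.approx(1.0)


def test_r_squared_invariant_to_affine_y():
    rng = np.random.default_rng(6)
    x = np.arange(2, 13, dtype=float)
    y = np.polyval(CUBIC, x) + rng.normal(0, 0.05, len(x))
    f1 = fit_polynomial_trend(x, y)
    f2 = fit_polynomial_trend(x, 3.0 * y - 7.0)
    assert f1.r_squared == pytest.approx(f2.r_squared, rel=1e-9)
    # residuals orthogonal to the design
    X = np.vander(x, 4)
    assert np.allclose(X.T @ f1.residuals, 0.0, atol=1e-8)


def test_too_few_points_rejected():
    with pytest.raises(ValueError, match="at least 5"):
        fit_polynomial_trend([1, 2, 3, 4], [1, 2, 3, 4], degree=3)


# -- subjective ----------------------------------------------------------

def questionnaire_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, index=[f"P{i}" for i in range(len(rows))])


def full_row(pos=5, neg=5, exp=5, resp=5):
    row = {e: pos for e in POSITIVE_EMOTIONS}
    row.update({e: neg for e in NEGATIVE_EMOTIONS})
    row["driving_experience"] = exp
    row["car_responsive_feel"] = resp
    return row


def test_subjective_score_formulas():
    q = questionnaire_frame([full_row(pos=10, neg=0, exp=6, resp=8),
                             full_row(pos=4, neg=4, exp=5, resp=5)])
    s = subjective_scores(q)
    assert s["valence"].iloc[0] == pytest.approx(10.0)
    assert s["feel_index"].iloc[0] == pytest.approx(7.0)
    assert s["valence"].iloc[1] == 0.0
    assert s["arousal"].iloc[1] == 0.0


def test_out_of_range_rating_rejected():
    q = questionnaire_frame([full_row()])
    q.loc[:, "excited"] = 11
    with pytest.raises(ValueError, match=r"\[0, 10\]"):
        subjective_scores(q)


# -- correlations --------------------------------------------------------

def test_perfect_rank_correlations():
    subj = pd.DataFrame({"feel_index": [1.0, 2, 3, 4, 5]},
                        index=list("abcde"))
    obj = pd.DataFrame({"up": [10.0, 20, 30, 40, 50],
                        "down": [5.0, 4, 3, 2, 1]}, index=list("abcde"))
    c = correlate_subjective_objective(subj, obj).set_index("objective")
    assert c.loc["up", "rho"] == pytest.approx(1.0)
    assert c.loc["down", "rho"] == pytest.approx(-1.0)


def test_constant_column_reported_missing():
    subj = pd.DataFrame({"feel_index": [1.0, 1, 1]}, index=list("abc"))
    obj = pd.DataFrame({"x": [1.0, 2, 3]}, index=list("abc"))
    c = correlate_subjective_objective(subj, obj)
    assert np.isnan(c["rho"].iloc[0])


def test_null_correlation_stays_small():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        subj = pd.DataFrame({"s": rng.normal(size=200)})
        obj = pd.DataFrame({"o": rng.normal(size=200)})
        c = correlate_subjective_objective(subj, obj)
        if abs(c["rho"].iloc[0]) < 0.2:
            hits += 1
    assert hits >= 95
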