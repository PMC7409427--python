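"""Statistical layer: correlation, regression, ANOVA, ANCOVA, normality."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from octachoroid.phantom import generate_cohort
from octachoroid.stats import (
    ancova_group_effect,
    anova_from_summary,
    anova_raw,
    compare_groups,
    fit_cvd_regression,
    ks_normality,
    match_controls,
    pearson_corr,
)


def _generator_cvd_frame(n_h, n_c, effect, seed, match_sct=False):
    rows = []
    for rec, cfg in generate_cohort(n_h, n_c, effect=effect, slope=3.9,
                                    seed=seed, match_sct=match_sct):
        rows.append({
            "age": rec.age, "axial_length": rec.axial_length, "sct": rec.sct,
            "group": "csc" if rec.is_csc else "healthy",
            "cvd": 100 * next(iter(cfg.lumen_fraction_by_depth.values())),
        })
    return pd.DataFrame(rows)


# --- Pearson ---------------------------------------------------------------

def test_pearson_perfect_correlations():
    x = np.arange(10.0)
    assert pearson_corr(x, 2 * x + 1)[0] == pytest.approx(1.0)
    assert pearson_corr(x, -x)[0] == pytest.approx(-1.0)


def test_pearson_independent_samples_near_zero(rng):
    x, y = rng.normal(size=1000), rng.normal(size=1000)
    r, p = pearson_corr(x, y)
    assert abs(r) < 0.1


def test_pearson_zero_variance_rejected():
    with pytest.raises(ValueError, match="variance"):
        pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# --- ANOVA -----------------------------------------------------------------

def _data_with_summary(mean, sd, n, rng):
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return x * sd + mean


def test_summary_anova_reproduces_published_p_at_three_decimals():
    f, p = anova_from_summary(62.3, 6.6, 22, 54.1, 8.0, 22)
    assert round(p, 3) == 0.001


def test_summary_anova_equals_raw_anova_to_10_sig_figs(rng):
    g1 = _data_with_summary(62.3, 6.6, 22, rng)
    g2 = _data_with_summary(54.1, 8.0, 22, rng)
    f_sum, p_sum = anova_from_summary(62.3, 6.6, 22, 54.1, 8.0, 22)
    f_raw, p_raw = anova_raw(g1, g2)
    assert f_sum == pytest.approx(f_raw, rel=1e-10)
    assert p_sum == pytest.approx(p_raw, rel=1e-10)


def test_two_group_f_is_squared_pooled_t(rng):
    g1 = rng.normal(10, 2, 15)
    g2 = rng.normal(12, 2, 20)
    f, _ = anova_raw(g1, g2)
    t, _ = sps.ttest_ind(g1, g2)
    assert f == pytest.approx(t**2, rel=1e-10)


def test_identical_group_summaries_give_f0_p1():
    f, p = anova_from_summary(50.0, 5.0, 10, 50.0, 7.0, 12)
    assert f == 0.0 and p == 1.0


@pytest.mark.parametrize("bad", [
    dict(mean1=1, sd1=0, n1=5, mean2=2, sd2=1, n2=5),
    dict(mean1=1, sd1=1, n1=1, mean2=2, sd2=1, n2=5),
])
def test_summary_anova_rejects_invalid_inputs(bad):
    with pytest.raises(ValueError):
        anova_from_summary(**bad)


# --- regression ------------------------------------------------------------

def test_regression_recovers_generator_slope():
    df = _generator_cvd_frame(91, 0, 0.0, seed=77)
    rep = fit_cvd_regression(df)
    sct = rep.coefficients["sct"]
    assert sct.ci_low <= 3.9 <= sct.ci_high
    assert sct.ci_low <= sct.estimate <= sct.ci_high


def test_regression_constant_cvd_gives_zero_slopes():
    df = pd.DataFrame({
        "age": np.arange(12.0), "axial_length": np.linspace(22, 25, 12),
        "sct": np.linspace(200, 500, 12), "cvd": np.full(12, 55.0),
    })
    rep = fit_cvd_regression(df)
    assert rep.coefficients["sct"].estimate == 0.0
    assert rep.coefficients["age"].p == 1.0


def test_null_age_coefficient_is_calibrated():
    """Type-I rate of the age slope stays near the nominal 5% when the
    generator assigns age no effect."""
    hits = 0
    n_rep = 200
    for i in range(n_rep):
        df = _generator_cvd_frame(40, 0, 0.0, seed=20_000 + i)
        hits += fit_cvd_regression(df).coefficients["age"].p < 0.05
    rate = hits / n_rep
    assert 0.05 - 3 * 0.0154 <= rate <= 0.05 + 3 * 0.0154


def test_regression_requires_minimum_n():
    df = _generator_cvd_frame(5, 0, 0.0, seed=1)
    with pytest.raises(ValueError):
        fit_cvd_regression(df)


# --- ANCOVA ----------------------------------------------------------------

def test_ancova_with_constant_covariate_equals_anova():
    rng = np.random.default_rng(3)
    df = pd.DataFrame({
        "cvd": np.concatenate([rng.normal(55, 5, 12), rng.normal(60, 5, 12)]),
        "group": ["a"] * 12 + ["b"] * 12,
        "sct": np.full(24, 350.0),
    })
    with pytest.warns(UserWarning, match="constant"):
        res = ancova_group_effect(df)
    _, p_anova = anova_raw(df.loc[df.group == "a", "cvd"],
                           df.loc[df.group == "b", "cvd"])
    assert res.p == pytest.approx(p_anova)
    assert res.covariate_constant


def test_ancova_removes_sct_confound():
    """Zero injected group effect with CVD tracking SCT and the CSC group
    shifted to thicker choroids: the raw ANOVA flags a difference, the
    SCT-adjusted ANCOVA does not (single deterministic cohort)."""
    df = _generator_cvd_frame(44, 44, 0.0, seed=4242)
    gc = compare_groups(df)
    assert gc.anova_p < 0.05
    assert gc.ancova_p > 0.05
    # adjusted means nearly coincide once SCT is accounted for
    means = list(gc.adjusted_means.values())
    assert abs(means[0] - means[1]) < 4.0


def test_ancova_detects_true_group_effect():
    df = _generator_cvd_frame(22, 22, 8.2, seed=7, match_sct=True)
    res = ancova_group_effect(df)
    assert res.p < 0.05
    assert res.adjusted_means["csc"] > res.adjusted_means["healthy"]


def test_ancova_requires_groups():
    df = pd.DataFrame({"cvd": [1.0] * 5, "group": ["a"] * 5,
                       "sct": np.arange(5.0)})
    with pytest.raises(ValueError):
        ancova_group_effect(df)


# --- normality -------------------------------------------------------------

def test_lilliefors_accepts_normal_rejects_exponential():
    n_rep, n = 100, 500
    ok_norm = ok_exp = 0
    for i in range(n_rep):
        r = np.random.default_rng(i)
        ok_norm += ks_normality(r.normal(size=n))[1] > 0.05
        ok_exp += ks_normality(r.exponential(size=n))[1] < 0.05
    assert ok_norm >= 0.9 * n_rep
    assert ok_exp >= 0.9 * n_rep


def test_lilliefors_rejects_constant_vector():
    with pytest.raises(ValueError):
        ks_normality(np.ones(20))


# --- matching --------------------------------------------------------------

def test_match_controls_exact_sex_nearest_demographics():
    cases = pd.DataFrame({
        "eye_id": ["c1", "c2"], "age": [40.0, 60.0], "sex": ["M", "F"],
        "axial_length": [23.0, 24.0],
    })
    pool = pd.DataFrame({
        "eye_id": ["p1", "p2", "p3", "p4"],
        "age": [41.0, 70.0, 59.0, 30.0],
        "sex": ["M", "M", "F", "F"],
        "axial_length": [23.1, 23.0, 24.1, 24.0],
    })
    matched = match_controls(cases, pool)
    assert list(matched["eye_id"]) == ["p1", "p3"]
    assert list(matched["sex"]) == list(cases["sex"])


def test_match_controls_without_replacement():
    cases = pd.DataFrame({"eye_id": ["c1", "c2"], "age": [40.0, 40.0],
                          "sex": ["F", "F"], "axial_length": [23.0, 23.0]})
    pool = pd.DataFrame({"eye_id": ["p1", "p2"], "age": [40.0, 50.0],
                         "sex": ["F", "F"], "axial_length": [23.0, 23.0]})
    matched = match_controls(cases, pool)
    assert set(matched["eye_id"]) == {"p1", "p2"}
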