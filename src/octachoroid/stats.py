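"""Cohort statistics for vascular-density analyses.

Covers the statistical toolkit the CVD analysis needs: Lilliefors-type
normality screening, Pearson correlation, ordinary least squares of CVD on
age, axial length and subfoveal choroidal thickness (with the SCT slope
reported per 100 um), one-way two-group ANOVA (from raw data or from
published summary statistics), SCT-adjusted ANCOVA, and demographic
matching of control eyes.  All tests are two-sided; alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "CoefficientEstimate",
    "RegressionReport",
    "AncovaResult",
    "GroupComparisonReport",
    "pearson_corr",
    "fit_cvd_regression",
    "anova_from_summary",
    "anova_raw",
    "ancova_group_effect",
    "ks_normality",
    "match_controls",
    "compare_groups",
]


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-based p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: a vector has zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CoefficientEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class RegressionReport:
    """OLS fit of CVD on age (years), axial length (mm) and SCT.

    The SCT coefficient is reported per 100 um of choroidal thickness.
    """

    coefficients: dict[str, CoefficientEstimate]
    n: int


def fit_cvd_regression(table: pd.DataFrame) -> RegressionReport:
    """Multivariable OLS: cvd ~ age + axial_length + sct.

    ``table`` needs columns age, axial_length, sct, cvd.  The sct slope,
    CI and nothing else are rescaled to per-100-um units.  A poorly
    conditioned design triggers a warning.
    """
    required = {"age", "axial_length", "sct", "cvd"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns: {sorted(missing)}")
    n = len(table)
    if n < 10:
        raise ValueError(f"need n >= 10 eyes, got {n}")
    y = table["cvd"].to_numpy(float)
    names = ["const", "age", "axial_length", "sct"]
    if np.ptp(y) == 0:
        # constant response: every slope is exactly zero, nothing to test
        coefs = {
            name: CoefficientEstimate(
                estimate=float(y[0]) if name == "const" else 0.0,
                ci_low=float(y[0]) if name == "const" else 0.0,
                ci_high=float(y[0]) if name == "const" else 0.0,
                p=1.0,
            )
            for name in names
        }
        return RegressionReport(coefficients=coefs, n=n)
    X = sm.add_constant(table[["age", "axial_length", "sct"]].to_numpy(float))
    fit = sm.OLS(y, X).fit()
    if np.linalg.cond(X) > 1e8:
        warnings.warn("design matrix is ill-conditioned (collinear predictors)")
    ci = fit.conf_int()
    coefs: dict[str, CoefficientEstimate] = {}
    for i, name in enumerate(names):
        scale = 100.0 if name == "sct" else 1.0
        coefs[name] = CoefficientEstimate(
            estimate=float(fit.params[i]) * scale,
            ci_low=float(ci[i, 0]) * scale,
            ci_high=float(ci[i, 1]) * scale,
            p=float(fit.pvalues[i]),
        )
    return RegressionReport(coefficients=coefs, n=n)


def anova_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Two-group one-way ANOVA reconstructed from summary statistics.

    Exact for two groups: between- and within-group sums of squares are
    recovered from the means, sample SDs and sizes, so the result equals a
    raw-data ANOVA on any dataset with those summaries.  Returns (F, p)
    with (1, n1 + n2 - 2) degrees of freedom.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("sds must be > 0")
    n = n1 + n2
    grand = (n1 * mean1 + n2 * mean2) / n
    ss_between = n1 * (mean1 - grand) ** 2 + n2 * (mean2 - grand) ** 2
    ss_within = (n1 - 1) * sd1**2 + (n2 - 1) * sd2**2
    df_within = n - 2
    if ss_between == 0:
        return 0.0, 1.0
    f = ss_between / (ss_within / df_within)
    p = float(sps.f.sf(f, 1, df_within))
    return float(f), p


def anova_raw(*groups: Sequence[float]) -> tuple[float, float]:
    """One-way ANOVA on raw per-eye values (wraps scipy)."""
    f, p = sps.f_oneway(*[np.asarray(g, float) for g in groups])
    return float(f), float(p)


@dataclass
class AncovaResult:
    p: float                            # group effect, SCT-adjusted
    f: float
    adjusted_means: dict[str, float]    # at the grand-mean SCT
    covariate_constant: bool = False


def ancova_group_effect(table: pd.DataFrame) -> AncovaResult:
    """SCT-adjusted group comparison of CVD (common-slope ANCOVA).

    ``table`` needs columns cvd, group, sct.  The group effect is tested by
    the extra-sum-of-squares F test between ``cvd ~ sct`` and
    ``cvd ~ group + sct``; adjusted group means are evaluated at the
    grand-mean SCT.  A group-by-SCT interaction is checked and reported as
    a warning only (the common-slope model is still fitted).  With a
    constant covariate the test reduces to one-way ANOVA.
    """
    required = {"cvd", "group", "sct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns: {sorted(missing)}")
    groups = sorted(table["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    counts = table["group"].value_counts()
    if (counts < 3).any():
        raise ValueError("each group needs n >= 3")

    y = table["cvd"].to_numpy(float)
    sct = table["sct"].to_numpy(float)
    dummies = np.column_stack(
        [(table["group"] == g).to_numpy(float) for g in groups[1:]]
    )
    n = len(y)

    if np.ptp(sct) == 0:
        warnings.warn("SCT is constant: ANCOVA reduces to one-way ANOVA")
        f, p = anova_raw(*[y[table["group"].to_numpy() == g] for g in groups])
        means = {g: float(y[table["group"].to_numpy() == g].mean()) for g in groups}
        return AncovaResult(p=p, f=f, adjusted_means=means, covariate_constant=True)

    X_full = sm.add_constant(np.column_stack([dummies, sct]))
    X_red = sm.add_constant(sct)
    fit_full = sm.OLS(y, X_full).fit()
    fit_red = sm.OLS(y, X_red).fit()
    df_diff = len(groups) - 1
    df_resid = n - X_full.shape[1]
    f = ((fit_red.ssr - fit_full.ssr) / df_diff) / (fit_full.ssr / df_resid)
    p = float(sps.f.sf(f, df_diff, df_resid))

    # advisory homogeneity-of-slopes check
    inter = dummies * sct[:, None]
    X_int = sm.add_constant(np.column_stack([dummies, sct, inter]))
    fit_int = sm.OLS(y, X_int).fit()
    df_int = inter.shape[1]
    df_resid_int = n - X_int.shape[1]
    if df_resid_int > 0 and fit_int.ssr > 0:
        f_int = ((fit_full.ssr - fit_int.ssr) / df_int) / (
            fit_int.ssr / df_resid_int
        )
        p_int = float(sps.f.sf(f_int, df_int, df_resid_int))
        if p_int < 0.05:
            warnings.warn(
                f"group x SCT interaction detected (p = {p_int:.3g}); "
                "common-slope ANCOVA may be inappropriate"
            )

    grand_sct = float(sct.mean())
    adjusted: dict[str, float] = {}
    beta = fit_full.params
    for i, g in enumerate(groups):
        pred = beta[0] + beta[-1] * grand_sct
        if i > 0:
            pred += beta[i]
        adjusted[g] = float(pred)
    return AncovaResult(p=p, f=float(f), adjusted_means=adjusted)


def ks_normality(x: Sequence[float]) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality screen with estimated parameters.

    Lilliefors variant: the reference Normal uses the sample mean and SD.
    Advisory only — nothing downstream is gated on it.
    """
    x = np.asarray(x, float)
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    if np.std(x) == 0:
        raise ValueError("normality test undefined for a constant vector")
    stat, p = lilliefors(x, dist="norm")
    return float(stat), float(p)


# Table-scale SDs used to put age (years) and axial length (mm) on a common
# footing when matching controls.
_AGE_SCALE = 12.3
_AL_SCALE = 1.18


def match_controls(
    cases: pd.DataFrame, pool: pd.DataFrame
) -> pd.DataFrame:
    """Greedy one-to-one demographic matching of control eyes to cases.

    Exact on sex; nearest neighbour on |d age| / 12.3 + |d AL| / 1.18
    (cohort-scale SDs), without replacement, in case order.  Both frames
    need columns eye_id, age, sex, axial_length.  Returns the matched rows
    of ``pool`` in case order.
    """
    for df, name in ((cases, "cases"), (pool, "pool")):
        missing = {"eye_id", "age", "sex", "axial_length"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} lacks columns: {sorted(missing)}")
    available = pool.copy().reset_index(drop=True)
    taken = np.zeros(len(available), bool)
    picks: list[int] = []
    for _, case in cases.iterrows():
        cand = (~taken) & (available["sex"] == case["sex"]).to_numpy()
        if not cand.any():
            raise ValueError(
                f"no unmatched control of sex {case['sex']!r} left for "
                f"case {case['eye_id']!r}"
            )
        dist = (
            np.abs(available["age"].to_numpy(float) - float(case["age"])) / _AGE_SCALE
            + np.abs(
                available["axial_length"].to_numpy(float) - float(case["axial_length"])
            )
            / _AL_SCALE
        )
        dist[~cand] = np.inf
        j = int(np.argmin(dist))
        taken[j] = True
        picks.append(j)
    return available.iloc[picks].reset_index(drop=True)


@dataclass
class GroupComparisonReport:
    """CSC-vs-control comparison of CVD, unadjusted and SCT-adjusted."""

    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    anova_f: float
    anova_p: float
    ancova_f: float
    ancova_p: float
    adjusted_means: dict[str, float]


def compare_groups(table: pd.DataFrame) -> GroupComparisonReport:
    """One-way ANOVA plus SCT-adjusted ANCOVA of CVD between groups.

    ``table`` needs columns cvd, group, sct.
    """
    groups = sorted(table["group"].unique())
    vals = {g: table.loc[table["group"] == g, "cvd"].to_numpy(float) for g in groups}
    f, p = anova_raw(*vals.values())
    anc = ancova_group_effect(table)
    return GroupComparisonReport(
        group_means={g: float(v.mean()) for g, v in vals.items()},
        group_sds={g: float(np.std(v, ddof=1)) for g, v in vals.items()},
        group_ns={g: int(len(v)) for g, v in vals.items()},
        anova_f=f,
        anova_p=p,
        ancova_f=anc.f,
        ancova_p=anc.p,
        adjusted_means=anc.adjusted_means,
    )
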