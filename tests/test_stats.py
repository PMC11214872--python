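"""Statistics engine: ANCOVA, effect sizes, partial correlations, families."""

import math

import numpy as np
import pandas as pd
import pytest

from semfluency import (
    ancova_group_effect,
    bonferroni_alpha,
    demographics_tests,
    partial_correlation,
    partial_eta_sq_from_F,
    posthoc_t,
)
from semfluency.pipeline import fmt_alpha


# ---------------------------------------------------------------------------
# independent oracles: explicit normal-equation solves

def ols_rss_normal_equations(X, y):
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    r = y - X @ beta
    return float(r @ r)


def ancova_F_oracle(y, g, Z):
    levels = sorted(set(g))
    dummies = np.column_stack([(g == lev).astype(float) for lev in levels[1:]])
    ones = np.ones((len(y), 1))
    X_full = np.hstack([ones, dummies, Z])
    X_red = np.hstack([ones, Z])
    rss_full = ols_rss_normal_equations(X_full, y)
    rss_red = ols_rss_normal_equations(X_red, y)
    df1 = len(levels) - 1
    df2 = len(y) - len(levels) - Z.shape[1]
    return ((rss_red - rss_full) / df1) / (rss_full / df2), df1, df2


def partial_r_oracle(x, y, Z):
    X = np.hstack([np.ones((len(x), 1)), Z])
    rx = x - X @ np.linalg.solve(X.T @ X, X.T @ x)
    ry = y - X @ np.linalg.solve(X.T @ X, X.T @ y)
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "F, df1, df2, expected",
    [
        (25.59, 2, 97, 0.35),
        (5.55, 2, 97, 0.10),
        (8.65, 2, 97, 0.15),
        (4.03, 2, 97, 0.08),
        (0.0, 2, 97, 0.0),
    ],
)
def test_partial_eta_sq_from_F(F, df1, df2, expected):
    assert round(partial_eta_sq_from_F(F, df1, df2), 2) == expected


def test_partial_eta_sq_domain():
    with pytest.raises(ValueError):
        partial_eta_sq_from_F(-1.0, 2, 97)


@pytest.mark.parametrize(
    "m, alpha, display",
    [(4, 0.0125, ".013"), (3, 0.05 / 3, ".017"), (2, 0.025, ".025"),
     (13, 0.05 / 13, ".004"), (1, 0.05, ".05")],
)
def test_bonferroni_families(m, alpha, display):
    a = bonferroni_alpha(0.05, m)
    assert a == pytest.approx(alpha)
    assert fmt_alpha(a).startswith(display) or fmt_alpha(a) == display


def test_bonferroni_domain():
    with pytest.raises(ValueError):
        bonferroni_alpha(0.05, 0)
    with pytest.raises(ValueError):
        bonferroni_alpha(0.0, 3)


def test_ancova_df_reconstruction():
    """27/35/40 with age+education covariates gives the F[2, 97] design."""
    rng = np.random.default_rng(0)
    g = np.repeat(["PSP_RS", "PD", "HC"], [27, 35, 40])
    y = rng.normal(size=102)
    Z = rng.normal(size=(102, 2))
    res = ancova_group_effect(y, g, Z)
    assert res.df == (2.0, 97.0)


def test_ancova_constant_outcome_gives_zero_F():
    g = np.repeat(["A", "B", "C"], 5)
    res = ancova_group_effect(np.ones(15), g, None)
    assert res.statistic == 0.0
    assert res.partial_eta_sq == 0.0


def test_ancova_eta_identity():
    """partial_eta_sq always equals F*df1/(F*df1+df2) on emitted results."""
    rng = np.random.default_rng(5)
    for _ in range(10):
        g = np.repeat(["A", "B", "C"], [6, 7, 8])
        y = rng.normal(size=21) + (g == "A") * rng.normal()
        Z = rng.normal(size=(21, 2))
        res = ancova_group_effect(y, g, Z)
        df1, df2 = res.df
        assert res.partial_eta_sq == pytest.approx(
            res.statistic * df1 / (res.statistic * df1 + df2), abs=1e-12)


def test_ancova_matches_normal_equation_oracle():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(12, 31))
        g = rng.choice(["A", "B", "C"], size=n)
        while min((g == lev).sum() for lev in "ABC") < 2:
            g = rng.choice(["A", "B", "C"], size=n)
        k = int(rng.integers(0, 3))
        Z = rng.normal(size=(n, k))
        y = rng.normal(size=n) + (g == "B") * rng.normal() + Z.sum(axis=1) * 0.5
        res = ancova_group_effect(y, g, Z if k else None)
        F_exp, df1, df2 = ancova_F_oracle(y, g, Z)
        assert res.statistic == pytest.approx(F_exp, abs=1e-8)
        assert res.df == (df1, df2)


def test_ancova_zero_variance_covariate_equals_plain_anova():
    from scipy.stats import f_oneway

    rng = np.random.default_rng(3)
    g = np.repeat(["A", "B", "C"], 8)
    y = rng.normal(size=24) + (g == "C")
    const = np.full((24, 1), 7.0)
    res = ancova_group_effect(y, g, const)
    F, p = f_oneway(y[g == "A"], y[g == "B"], y[g == "C"])
    assert res.statistic == pytest.approx(float(F), abs=1e-10)
    assert res.df == (2.0, 21.0)
    assert res.extra["dropped_covariates"] == ["cov0"]


def test_ancova_rank_deficient_raises():
    rng = np.random.default_rng(9)
    g = np.repeat(["A", "B", "C"], 6)
    y = rng.normal(size=18)
    Z = rng.normal(size=(18, 1))
    with pytest.raises(np.linalg.LinAlgError, match="rank-deficient"):
        ancova_group_effect(y, g, np.hstack([Z, Z]))


def test_ancova_drops_missing_rows():
    rng = np.random.default_rng(13)
    g = np.repeat(["A", "B", "C"], 10)
    y = rng.normal(size=30)
    y[3] = np.nan
    res = ancova_group_effect(y, g, None)
    assert res.n_dropped == 1
    assert res.df == (2.0, 26.0)


@pytest.mark.parametrize("n_a, n_b, expected_df", [(27, 35, 60), (27, 40, 65)])
def test_posthoc_t_df(n_a, n_b, expected_df):
    rng = np.random.default_rng(1)
    res = posthoc_t(rng.normal(size=n_a), rng.normal(size=n_b))
    assert res.df == expected_df


def test_posthoc_t_identical_samples():
    res = posthoc_t([1.0, 1.0, 1.0], [1.0, 1.0])
    assert res.statistic == 0.0 and res.p == 1.0


def test_posthoc_t_zero_variance_unequal_means():
    res = posthoc_t([1.0, 1.0], [2.0, 2.0])
    assert math.isinf(res.statistic) and res.statistic < 0
    assert res.p == 0.0


def test_posthoc_t_sign_flip_preserves_p():
    rng = np.random.default_rng(2)
    a, b = rng.normal(1, 1, 20), rng.normal(0, 1, 25)
    res = posthoc_t(a, b)
    flipped = posthoc_t(-a, -b)
    assert flipped.statistic == pytest.approx(-res.statistic)
    assert flipped.p == pytest.approx(res.p)


def test_partial_correlation_perfect_linear():
    x = np.arange(10.0)
    res = partial_correlation(x, 2 * x + 1, None)
    assert res.r == pytest.approx(1.0)
    assert res.p == pytest.approx(0.0, abs=1e-12)


def test_partial_correlation_no_covariates_is_pearson():
    rng = np.random.default_rng(8)
    for _ in range(20):
        x, y = rng.normal(size=25), rng.normal(size=25)
        res = partial_correlation(x, y, None)
        assert res.r == pytest.approx(float(np.corrcoef(x, y)[0, 1]), abs=1e-12)


def test_partial_correlation_y_in_covariate_space_raises():
    rng = np.random.default_rng(4)
    z = rng.normal(size=20)
    with pytest.raises(ValueError, match="constant residual"):
        partial_correlation(rng.normal(size=20), z, z.reshape(-1, 1))


def test_partial_correlation_matches_oracle_and_pingouin():
    import pingouin as pg

    rng = np.random.default_rng(77)
    for i in range(100):
        n = 30
        Z = rng.normal(size=(n, 3))
        x = rng.normal(size=n) + Z @ [0.5, -0.2, 0.1]
        y = rng.normal(size=n) + Z @ [0.1, 0.4, -0.3] + 0.3 * x
        res = partial_correlation(x, y, Z)
        assert res.r == pytest.approx(partial_r_oracle(x, y, Z), abs=1e-8)
        if i < 5:  # pingouin cross-check on a handful (r and p)
            df = pd.DataFrame(
                {"x": x, "y": y, "z0": Z[:, 0], "z1": Z[:, 1], "z2": Z[:, 2]})
            ref = pg.partial_corr(df, x="x", y="y", covar=["z0", "z1", "z2"])
            assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
            assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)


def test_partial_correlation_orthogonal_covariate_inert():
    # covariate orthogonal to x and y (exact arithmetic fixture)
    x = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0, 1.5, -1.5])
    y = np.array([2.0, -2.0, 1.0, -1.0, 2.5, -2.5, 0.5, -0.5])
    z = np.ones_like(x)
    z[::2] = 1.0
    z[1::2] = 1.0  # constant -> exactly in the intercept span
    r0 = partial_correlation(x, y, None).r
    r1 = partial_correlation(x, y, z.reshape(-1, 1)).r
    assert abs(r1 - r0) < 1e-10


def test_partial_correlation_symmetry():
    rng = np.random.default_rng(6)
    x, y, Z = rng.normal(size=20), rng.normal(size=20), rng.normal(size=(20, 2))
    assert partial_correlation(x, y, Z).r == pytest.approx(
        partial_correlation(y, x, Z).r, abs=1e-12)


def test_demographics_tests():
    rng = np.random.default_rng(10)
    sex = (["M"] * 14 + ["F"] * 13 + ["M"] * 18 + ["F"] * 17
           + ["M"] * 20 + ["F"] * 20)
    group = ["PSP_RS"] * 27 + ["PD"] * 35 + ["HC"] * 40
    table = pd.DataFrame({
        "group": group,
        "sex": sex,
        "age": rng.normal(62, 7, 102).round(),
        "constant_feature": np.ones(102),
        "skewed": rng.exponential(1.0, 102) ** 3,
    })
    results = {r.outcome: r for r in demographics_tests(table)}

    chi = results["sex"]
    assert chi.test == "chi_square"
    assert chi.df == 2.0
    assert chi.p > 0.9  # printed contingency 14:13/18:17/20:20 is near-null

    assert results["constant_feature"].p == 1.0
    assert results["skewed"].test == "kruskal_wallis"
    for r in results.values():
        assert r.alpha_corrected == pytest.approx(0.05 / 13)
        assert 0.0 <= r.p <= 1.0
    assert fmt_alpha(0.05 / 13) == ".004"
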