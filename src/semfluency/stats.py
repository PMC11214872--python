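"""Covariate-adjusted group inference and partial correlations.

The inference plan this module implements:

* one-way ANCOVA — a linear model ``outcome ~ intercept + group (2 dummies)
  + covariates``; the group effect is tested by model comparison (residual sum
  of squares of the group-dropped model minus the full model), giving
  F with df1 = 2 and df2 = n - 3 - n_covariates, and the partial eta squared
  effect size SS_group / (SS_group + SS_error);
* post hoc pooled-variance (Student) two-sample t-tests, df = n_a + n_b - 2;
* partial correlation by residualization: x and y are each regressed on
  [intercept, covariates] by least squares and r is the Pearson correlation of
  the residuals, with p from t = r * sqrt((n - 2 - k) / (1 - r^2));
* Bonferroni families: the corrected alpha is family_alpha / m;
* demographics screening: per numeric feature, one-way ANOVA when a per-group
  Shapiro-Wilk normality screen passes, Kruskal-Wallis otherwise; chi-square
  independence for sex counts.

Missing values are removed listwise per analysis and the number of dropped
rows is recorded on the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "PartialCorrResult",
    "ancova_group_effect",
    "partial_eta_sq_from_F",
    "posthoc_t",
    "partial_correlation",
    "bonferroni_alpha",
    "demographics_tests",
]


@dataclass
class StatResult:
    outcome: str
    test: str  # ancova_F | t_pooled | kruskal_wallis | chi_square | anova_F
    statistic: float
    df: tuple[float, float] | float
    p: float
    partial_eta_sq: float | None = None
    alpha_corrected: float = 0.05
    n_dropped: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p < self.alpha_corrected


@dataclass
class PartialCorrResult:
    x: str
    y: str
    covariates: list[str]
    r: float
    n: int
    p: float
    alpha_corrected: float = 0.05
    n_dropped: int = 0

    @property
    def significant(self) -> bool:
        return self.p < self.alpha_corrected


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-test alpha for a declared family of m tests."""
    if not 0 < family_alpha <= 1:
        raise ValueError("family_alpha must be in (0, 1]")
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return family_alpha / m


def partial_eta_sq_from_F(F: float, df1: int, df2: int) -> float:
    """Effect size F*df1 / (F*df1 + df2) for an F-test."""
    if F < 0:
        raise ValueError("F must be non-negative")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be positive")
    return F * df1 / (F * df1 + df2)


def _drop_missing(*columns: np.ndarray) -> tuple[list[np.ndarray], int]:
    mask = np.ones(len(columns[0]), dtype=bool)
    for col in columns:
        if np.issubdtype(np.asarray(col).dtype, np.number):
            mask &= np.isfinite(np.asarray(col, dtype=float))
    kept = [np.asarray(col)[mask] for col in columns]
    return kept, int((~mask).sum())


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def ancova_group_effect(
    values: Sequence[float],
    group: Sequence,
    covariates: np.ndarray | None = None,
    outcome: str = "outcome",
    alpha_corrected: float = 0.05,
    covariate_names: Sequence[str] | None = None,
) -> StatResult:
    """Group F-test from the full-vs-reduced linear model comparison.

    ``group`` may have any number >= 2 of levels; with the study's three
    groups and two covariates on n participants the test has df = (2, n-5).
    Rows with a non-finite outcome or covariate are dropped (listwise) and
    counted in ``n_dropped``.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(group)
    if covariates is None:
        Z = np.empty((len(y), 0))
    else:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != len(y):
            Z = Z.T
    (y, g, *zcols), n_dropped = _drop_missing(y, g, *Z.T)
    Z = np.column_stack(zcols) if zcols else np.empty((len(y), 0))

    # zero-variance covariates carry no information beyond the intercept;
    # drop them so the model degrades to plain one-way ANOVA (df2 adjusted)
    dropped_covariates = []
    keep = []
    for j in range(Z.shape[1]):
        if np.ptp(Z[:, j]) == 0:
            dropped_covariates.append(
                covariate_names[j] if covariate_names is not None else f"cov{j}")
        else:
            keep.append(j)
    Z = Z[:, keep]
    if covariate_names is not None:
        covariate_names = [covariate_names[j] for j in keep]

    levels = sorted(set(g.tolist()))
    if len(levels) < 2:
        raise ValueError("need at least 2 group levels")
    counts = {lev: int((g == lev).sum()) for lev in levels}
    if min(counts.values()) < 2:
        raise ValueError(f"every group needs >= 2 participants, got {counts}")

    n = len(y)
    dummies = np.column_stack([(g == lev).astype(float) for lev in levels[1:]])
    intercept = np.ones((n, 1))
    X_full = np.hstack([intercept, dummies, Z])
    X_red = np.hstack([intercept, Z])

    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        names = ["intercept"] + [f"group[{lev}]" for lev in levels[1:]] + [
            (covariate_names[i] if covariate_names is not None else f"cov{i}")
            for i in range(Z.shape[1])
        ]
        raise np.linalg.LinAlgError(
            f"rank-deficient ANCOVA design (rank {rank} < {X_full.shape[1]}); "
            f"columns: {names}"
        )

    rss_full = _ols_rss(X_full, y)
    rss_red = _ols_rss(X_red, y)
    ss_group = max(rss_red - rss_full, 0.0)
    df1 = len(levels) - 1
    df2 = n - len(levels) - Z.shape[1]
    if df2 < 1:
        raise ValueError("no residual degrees of freedom")
    if rss_full <= 0:
        F = 0.0 if ss_group <= 0 else math.inf
    else:
        F = (ss_group / df1) / (rss_full / df2)
    p = float(sps.f.sf(F, df1, df2)) if math.isfinite(F) else 0.0
    eta = ss_group / (ss_group + rss_full) if (ss_group + rss_full) > 0 else 0.0
    return StatResult(
        outcome=outcome,
        test="ancova_F",
        statistic=float(F),
        df=(float(df1), float(df2)),
        p=p,
        partial_eta_sq=float(eta),
        alpha_corrected=alpha_corrected,
        n_dropped=n_dropped,
        extra={"group_sizes": counts,
               "dropped_covariates": dropped_covariates},
    )


def posthoc_t(
    values_a: Sequence[float],
    values_b: Sequence[float],
    outcome: str = "outcome",
    alpha_corrected: float = 0.05,
) -> StatResult:
    """Pooled-variance (Student) two-sample t-test, two-tailed."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    df = len(a) + len(b) - 2
    pooled_var = (
        (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
    ) / df
    if pooled_var == 0.0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = math.inf if a.mean() > b.mean() else -math.inf
            p = 0.0
    else:
        res = sps.ttest_ind(a, b, equal_var=True)
        t, p = float(res.statistic), float(res.pvalue)
    return StatResult(
        outcome=outcome,
        test="t_pooled",
        statistic=t,
        df=float(df),
        p=p,
        alpha_corrected=alpha_corrected,
    )


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | None = None,
    x_name: str = "x",
    y_name: str = "y",
    covariate_names: Sequence[str] | None = None,
    alpha_corrected: float = 0.05,
) -> PartialCorrResult:
    """Partial Pearson correlation of x and y given covariates.

    Residualizes x and y separately on [intercept, covariates] and correlates
    the residuals; with an empty covariate set this reduces exactly to the
    plain Pearson correlation.  Rows with any non-finite value are dropped.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if covariates is None:
        Z = np.empty((len(xv), 0))
    else:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != len(xv):
            Z = Z.T
    (xv, yv, *zcols), n_dropped = _drop_missing(xv, yv, *Z.T)
    Z = np.column_stack(zcols) if zcols else np.empty((len(xv), 0))
    n, k = len(xv), Z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")

    X = np.hstack([np.ones((n, 1)), Z])
    bx, *_ = np.linalg.lstsq(X, xv, rcond=None)
    by, *_ = np.linalg.lstsq(X, yv, rcond=None)
    rx = xv - X @ bx
    ry = yv - X @ by
    if np.allclose(rx, 0.0, atol=1e-12) or np.allclose(ry, 0.0, atol=1e-12):
        raise ValueError(
            "constant residual vector: a variable lies in the covariate "
            "column space; partial correlation undefined"
        )
    r = float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))
    r = max(-1.0, min(1.0, r))
    dof = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(dof / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), dof))
    return PartialCorrResult(
        x=x_name,
        y=y_name,
        covariates=list(covariate_names) if covariate_names is not None
        else [f"cov{i}" for i in range(k)],
        r=r,
        n=n,
        p=p,
        alpha_corrected=alpha_corrected,
        n_dropped=n_dropped,
    )


def demographics_tests(
    table,
    group_col: str = "group",
    sex_col: str | None = "sex",
    normality_alpha: float = 0.05,
    family_alpha: float = 0.05,
    family_m: int = 13,
) -> list[StatResult]:
    """Per-feature group-difference screening for a demographics table.

    ``table`` is a pandas DataFrame with a group column, optionally a
    categorical sex column, and numeric feature columns.  Each numeric
    feature gets a one-way ANOVA when every group passes a Shapiro-Wilk
    normality screen at ``normality_alpha``, else Kruskal-Wallis; the sex
    column gets a chi-square test of independence.  All tests share one
    Bonferroni family (default m=13 -> corrected alpha .004).
    """
    import pandas as pd

    alpha_c = bonferroni_alpha(family_alpha, family_m)
    groups = sorted(table[group_col].astype(str).unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    results: list[StatResult] = []

    if sex_col is not None and sex_col in table.columns:
        contingency = pd.crosstab(table[group_col], table[sex_col])
        chi2, p, df, _ = sps.chi2_contingency(contingency)
        results.append(
            StatResult(
                outcome=sex_col,
                test="chi_square",
                statistic=float(chi2),
                df=float(df),
                p=float(p),
                alpha_corrected=alpha_c,
                extra={"contingency": contingency.to_dict()},
            )
        )

    numeric_cols = [
        c for c in table.columns
        if c not in (group_col, sex_col)
        and np.issubdtype(table[c].dtype, np.number)
    ]
    for col in numeric_cols:
        samples = []
        skip = False
        for gname in groups:
            vals = table.loc[table[group_col].astype(str) == gname, col]
            vals = np.asarray(vals, dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                skip = True
                break
            samples.append(vals)
        if skip:
            continue
        normal = True
        for vals in samples:
            if len(vals) < 3 or np.ptp(vals) == 0:
                normal = False
                break
            if sps.shapiro(vals).pvalue < normality_alpha:
                normal = False
                break
        if all(np.ptp(v) == 0 for v in samples) and len(
            {v[0] for v in samples}
        ) == 1:
            # feature identical everywhere: no group effect by definition
            results.append(
                StatResult(outcome=col, test="kruskal_wallis", statistic=0.0,
                           df=float(len(samples) - 1), p=1.0,
                           alpha_corrected=alpha_c))
            continue
        if normal:
            stat, p = sps.f_oneway(*samples)
            n = sum(len(v) for v in samples)
            results.append(
                StatResult(outcome=col, test="anova_F", statistic=float(stat),
                           df=(float(len(samples) - 1),
                               float(n - len(samples))),
                           p=float(p), alpha_corrected=alpha_c))
        else:
            stat, p = sps.kruskal(*samples)
            results.append(
                StatResult(outcome=col, test="kruskal_wallis",
                           statistic=float(stat),
                           df=float(len(samples) - 1), p=float(p),
                           alpha_corrected=alpha_c))
    return results
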