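"""Behavioral and intersubject statistics.

Covers the analysis layer around the choice model: robust regression with
tests on studentized coefficients, per-subject slope tests aggregated by a
one-sample t test, nonimpulsive choice rates, quantile-binned summaries for
rate-vs-value plots, the PPI-style intersubject interaction GLM (is the
brain-behaviour correlation stronger in the ecological than the control
condition?), the Group x Condition mixed-design ANOVA, and the
covariate-adjusted group GLM used when groups differ in age.

Robust fits use iteratively reweighted least squares with the Tukey
bisquare weight function (tuning constant 4.685) and MAD/0.6745 residual
scale, via statsmodels RLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "TestResult",
    "InteractionResult",
    "robust_fit",
    "per_subject_slope_test",
    "nonimpulsive_rate",
    "bin_summary",
    "interaction_correlation_test",
    "group_condition_interaction",
    "covariate_adjusted_group_test",
]

TUKEY_C = 4.685


@dataclass
class RegressionResult:
    """Coefficients and studentized statistics from a (robust) linear fit."""

    coef: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray        # studentized coefficients, coef / SE
    scale: float
    iterations: int
    converged: bool
    names: list = field(default_factory=list)

    def slope(self, i: int = 1) -> float:
        return float(self.coef[i])


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    side: str
    detail: dict = field(default_factory=dict)


@dataclass
class InteractionResult:
    """Stacked-rows GLM with an X*Z interaction; the interaction is the test."""

    coef: pd.Series
    se: pd.Series
    tvalues: pd.Series
    interaction_t: float
    interaction_p: float
    df_resid: float
    side: str


def _one_sided_p(t: float, df: float, side: str) -> float:
    if side == "two-sided":
        return float(2 * sps.t.sf(abs(t), df))
    if side == "greater":
        return float(sps.t.sf(t, df))
    if side == "less":
        return float(sps.t.cdf(t, df))
    raise ValueError(f"unknown sidedness {side!r}")


def robust_fit(x, y, add_intercept: bool = True,
               maxiter: int = 50, tol: float = 1e-8) -> RegressionResult:
    """IRLS robust regression (Tukey bisquare, c=4.685, MAD scale).

    ``x`` is a vector or (n, p) matrix of predictors; an intercept column is
    prepended unless ``add_intercept=False``. Raises on rank-deficient
    designs or constant response; non-convergence is reported on the result,
    not raised.
    """
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    rlm = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=TUKEY_C))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = rlm.fit(scale_est="mad", maxiter=maxiter, tol=tol, conv="coefs")
    iters = len(fit.fit_history.get("params", [])) or maxiter
    if fit.scale == 0 or not np.isfinite(fit.bse).all():
        # degenerate MAD scale (e.g. a binary response where most residuals
        # vanish): the bisquare weights collapse, so fall back to OLS, which
        # is the all-weights-one limit of the IRLS scheme
        ols = sm.OLS(y, X).fit()
        return RegressionResult(
            coef=np.asarray(ols.params),
            se=np.asarray(ols.bse),
            tvalues=np.asarray(ols.tvalues),
            scale=float(np.sqrt(ols.scale)),
            iterations=int(iters),
            converged=True,
            names=(["intercept"] if add_intercept else [])
                  + [f"x{i}" for i in range(X.shape[1] - int(add_intercept))],
        )
    return RegressionResult(
        coef=np.asarray(fit.params),
        se=np.asarray(fit.bse),
        tvalues=np.asarray(fit.params) / np.asarray(fit.bse),
        scale=float(fit.scale),
        iterations=int(iters),
        converged=bool(iters < maxiter),
        names=(["intercept"] if add_intercept else [])
              + [f"x{i}" for i in range(X.shape[1] - int(add_intercept))],
    )


def per_subject_slope_test(tables, x: str, y: str,
                           side: str = "greater") -> TestResult:
    """Robust slope per subject, then a one-sample t test on the slopes.

    ``tables`` is an iterable of per-subject trial DataFrames holding
    columns ``x`` and ``y``. Subjects need >= 3 usable rows; the group-level
    test needs >= 2 subjects. Subjects whose response is constant (e.g. a
    participant who never chose the delayed option) have no estimable slope
    and are excluded from the group-level test.
    """
    slopes = []
    for t in tables:
        sub = t[[x, y]].dropna()
        if len(sub) < 3:
            raise ValueError("each subject needs at least 3 usable trials")
        if sub[y].nunique() == 1 or sub[x].nunique() == 1:
            continue
        slopes.append(robust_fit(sub[x], sub[y]).slope())
    if len(slopes) < 2:
        raise ValueError("slope test needs at least 2 subjects (df >= 1)")
    alternative = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[side]
    res = sps.ttest_1samp(slopes, 0.0, alternative=alternative)
    return TestResult(statistic=float(res.statistic), df=len(slopes) - 1,
                      p=float(res.pvalue), side=side,
                      detail={"slopes": slopes, "mean_slope": float(np.mean(slopes))})


def nonimpulsive_rate(choices: pd.DataFrame, condition: str | None = None) -> float:
    """Fraction of trials on which the delayed option was chosen.

    ``choices`` needs a ``choice`` column; if ``condition`` is given the
    table is first filtered on its ``condition`` column.
    """
    sub = choices if condition is None else choices[choices["condition"] == condition]
    if len(sub) == 0:
        raise ValueError("no trials left after filtering")
    return float((sub["choice"] == "nonimpulsive").mean())


def bin_summary(tables, x: str, y: str, n_bins: int) -> pd.DataFrame:
    """Quantile-binned means averaged across subjects, with intersubject SEM.

    For each subject, x is cut into ``n_bins`` equal-count bins (ties broken
    by stable order) and the bin means of x and y computed; the per-bin
    means are then averaged across subjects. Returns columns ``bin, x_mean,
    y_mean, y_sem, n_subjects``. A single table is accepted as one subject.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    per_subject = []
    for t in tables:
        sub = t[[x, y]].dropna().reset_index(drop=True)
        if len(sub) < n_bins:
            raise ValueError(f"need >= {n_bins} trials per subject to form {n_bins} bins")
        order = np.argsort(sub[x].to_numpy(), kind="stable")
        bins = np.empty(len(sub), dtype=int)
        bins[order] = (np.arange(len(sub)) * n_bins) // len(sub)
        g = sub.groupby(bins).agg(x_mean=(x, "mean"), y_mean=(y, "mean"),
                                  n=(y, "size"))
        g.index.name = "bin"
        per_subject.append(g)
    stacked = pd.concat(per_subject, keys=range(len(per_subject)),
                        names=["subject", "bin"]).reset_index()
    out = stacked.groupby("bin").agg(
        x_mean=("x_mean", "mean"),
        y_mean=("y_mean", "mean"),
        y_sem=("y_mean", lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v)))
               if len(v) > 1 else np.nan),
        n_subjects=("subject", "nunique"),
    ).reset_index()
    return out


def interaction_correlation_test(data: pd.DataFrame, y: str = "Y", x: str = "X",
                                 condition: str = "condition",
                                 covariates: tuple = (),
                                 side: str = "greater") -> InteractionResult:
    """PPI-style intersubject interaction GLM.

    ``data`` is long-format with one row per subject x condition: the
    outcome ``y`` (e.g., a neural contrast), the behavioural regressor ``x``
    (same value in both condition rows of a subject), a binary ``condition``
    column (ecological coded 1, control 0), and optional per-subject
    covariates. Fits Y ~ 1 + X + Z + X*Z + covariates by OLS and tests the
    X*Z coefficient — positive when the X-Y correlation is stronger in the
    ecological condition.
    """
    cond = data[condition]
    if cond.nunique() != 2:
        raise ValueError("need exactly two conditions")
    if "subject" in data.columns:
        per = data.groupby("subject")[condition].nunique()
        if (per != 2).any():
            raise ValueError(f"missing condition rows for subjects "
                             f"{per.index[per != 2].tolist()}")
    z = (cond == ("ecological" if "ecological" in set(cond) else sorted(set(cond))[1])
         ).astype(float).to_numpy()
    X = np.column_stack([data[x].to_numpy(float), z,
                         data[x].to_numpy(float) * z]
                        + [data[c].to_numpy(float) for c in covariates])
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear covariate?)")
    fit = sm.OLS(data[y].to_numpy(float), X).fit()
    names = ["intercept", "X", "Z", "X:Z", *covariates]
    coef = pd.Series(fit.params, index=names)
    t_int = float(fit.tvalues[3])
    p_int = _one_sided_p(t_int, fit.df_resid, side)
    return InteractionResult(
        coef=coef,
        se=pd.Series(fit.bse, index=names),
        tvalues=pd.Series(fit.tvalues, index=names),
        interaction_t=t_int,
        interaction_p=p_int,
        df_resid=float(fit.df_resid),
        side=side,
    )


def group_condition_interaction(rates: pd.DataFrame, dv: str = "nonimpulsive_rate",
                                group: str = "group", condition: str = "condition",
                                subject: str = "subject") -> TestResult:
    """Group x Condition interaction from a mixed-design ANOVA.

    Condition is the within-subject factor (one rate per subject per
    condition), group the between-subject factor. df convention: between df
    = groups - 1, error df = N - groups.
    """
    n_per_group = rates.groupby(group)[subject].nunique()
    if (n_per_group < 2).any():
        raise ValueError("each group needs >= 2 subjects for the interaction test")
    if rates[group].nunique() < 2:
        raise ValueError("need at least two groups")
    aov = pg.mixed_anova(data=rates, dv=dv, within=condition,
                         subject=subject, between=group)
    row = aov.loc[aov["Source"] == "Interaction"].iloc[0]
    return TestResult(statistic=float(row["F"]),
                      df=(float(row["DF1"]), float(row["DF2"])),
                      p=float(row["p_unc"]), side="two-sided",
                      detail={"anova_table": aov})


def covariate_adjusted_group_test(delta_rate, group, age,
                                  side: str = "two-sided") -> dict:
    """OLS of the condition effect (ecological - control rate) on group + age.

    Returns t tests for the group indicator and the age covariate. A
    constant age column is dropped with a warning (its effect is not
    identifiable next to the intercept); the group test is still returned.
    """
    delta = np.asarray(delta_rate, float)
    grp = pd.Series(group)
    if grp.nunique() != 2:
        raise ValueError("group must have exactly two levels")
    levels = sorted(grp.unique())
    gind = (grp == levels[1]).astype(float).to_numpy()
    age = np.asarray(age, float)
    cols, names = [gind], ["group"]
    if np.ptp(age) == 0:
        warnings.warn("age is constant; dropping the age covariate", UserWarning)
    else:
        cols.append(age)
        names.append("age")
    X = sm.add_constant(np.column_stack(cols))
    fit = sm.OLS(delta, X).fit()
    out = {"levels": levels, "reference": levels[0], "df_resid": float(fit.df_resid)}
    for i, name in enumerate(names, start=1):
        t = float(fit.tvalues[i])
        out[name] = TestResult(statistic=t, df=float(fit.df_resid),
                               p=_one_sided_p(t, fit.df_resid, side), side=side,
                               detail={"coef": float(fit.params[i]),
                                       "se": float(fit.bse[i])})
    return out
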