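"""Group-level statistical battery.

Implements the analysis toolkit used for subject-level covariates: Pearson
and partial correlations with Fisher-z 95% confidence intervals, standardized
multiple regression with t-based coefficient CIs, variance inflation factors
(auxiliary-regression definition, alarm rule VIF > 10), Gaussian BIC and
adjusted R-squared, a Shapiro-Wilk residual-normality gate (normal at
p > 0.05), pooled-variance t-tests with Cohen's d, and BIC-based model
comparison across regressions.

Partial correlations residualize both variables on the controls and
correlate the residuals; the degrees of freedom are n - 2 - (number of
controls).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "CorrelationReport",
    "RegressionReport",
    "GroupDifference",
    "correlation",
    "standardized_regression",
    "vif_screen",
    "group_difference",
    "compare_models_bic",
]


class DegenerateDataError(ValueError):
    """Input with no variance where variance is required."""


class CollinearityError(ValueError):
    """Rank-deficient regression design."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"design is rank deficient; offending columns: {self.columns}")


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson (or partial) correlation with Fisher-z 95% CI."""

    r: float
    df: int
    p: float
    ci95: tuple[float, float]
    n: int
    partial_on: tuple[str, ...] = ()


@dataclass(frozen=True)
class RegressionReport:
    """Standardized OLS regression summary.

    ``coefficients`` has one row per predictor: standardized coefficient,
    t-based 95% CI, two-sided p, and VIF.
    """

    outcome: str
    coefficients: pd.DataFrame
    bic: float
    adj_r2: float
    shapiro_p: float
    normality_ok: bool
    n: int

    @property
    def vif(self) -> pd.Series:
        return self.coefficients["vif"]


@dataclass(frozen=True)
class GroupDifference:
    """Pooled-variance t-test and Cohen's d with 95% CI."""

    t: float
    df: int
    p: float
    tail: str
    cohens_d: float
    d_ci95: tuple[float, float]


def _zscore(x: np.ndarray, name: str = "variable") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0.0:
        raise DegenerateDataError(f"{name} has no variance")
    return (x - x.mean()) / sd


def correlation(
    x: Sequence[float],
    y: Sequence[float],
    control: pd.DataFrame | np.ndarray | None = None,
) -> CorrelationReport:
    """Pearson correlation of x and y, optionally partialled on controls.

    With controls, both variables are residualized on an intercept plus the
    control columns before correlating. The 95% CI uses the Fisher z
    transform with se = 1/sqrt(n - 3 - k); the p-value is two-sided from the
    t distribution with df = n - 2 - k.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    names: tuple[str, ...] = ()
    k = 0
    if control is not None:
        c = pd.DataFrame(control)
        names = tuple(str(col) for col in c.columns)
        k = c.shape[1]
        z = sm.add_constant(c.to_numpy(dtype=float))
        x = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
        y = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    df = n - 2 - k
    if df < 2:
        raise ValueError(f"need n >= 4 + number of controls, got n={n}, k={k}")
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        raise DegenerateDataError("correlation undefined for constant input")
    r = float(np.clip(np.dot(x - x.mean(), y - y.mean()) / (n * sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    se_z = 1.0 / np.sqrt(n - 3 - k)
    zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    zcrit = stats.norm.ppf(0.975)
    ci = (float(np.tanh(zr - zcrit * se_z)), float(np.tanh(zr + zcrit * se_z)))
    return CorrelationReport(r=r, df=df, p=p, ci95=ci, n=n, partial_on=names)


def standardized_regression(
    outcome: Sequence[float] | pd.Series,
    predictors: pd.DataFrame,
) -> RegressionReport:
    """OLS on z-scored outcome and predictors.

    Coefficient CIs come from the t distribution; VIF_j = 1/(1 - R^2_j) from
    the auxiliary regression of predictor j on the others; BIC uses the
    Gaussian likelihood with the ML variance estimate, counting intercept,
    slopes and variance as parameters; residual normality is gated by
    Shapiro-Wilk at p > 0.05.
    """
    yname = getattr(outcome, "name", None) or "outcome"
    y = _zscore(np.asarray(outcome, dtype=float), yname)
    names = [str(c) for c in predictors.columns]
    n, k = predictors.shape
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 observations, got n={n}, k={k}")
    X = np.column_stack([_zscore(predictors[c].to_numpy(), c) for c in predictors.columns])

    # rank check with explicit naming of dependent columns
    corr_rank = np.linalg.matrix_rank(X, tol=1e-8 * np.sqrt(n))
    if corr_rank < k:
        offending = []
        for j in range(k):
            others = np.delete(X, j, axis=1)
            if others.size == 0:
                continue
            resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            if resid.std() < 1e-8:
                offending.append(names[j])
        raise CollinearityError(offending or names)

    model = sm.OLS(y, sm.add_constant(X)).fit()
    ci = model.conf_int(alpha=0.05)
    vifs = np.empty(k)
    for j in range(k):
        if k == 1:
            vifs[j] = 1.0
            continue
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2_aux = sm.OLS(X[:, j], others).fit().rsquared
        vifs[j] = 1.0 / (1.0 - r2_aux)
    coef = pd.DataFrame(
        {
            "predictor": names,
            "coef": model.params[1:],
            "ci_low": ci[1:, 0],
            "ci_high": ci[1:, 1],
            "p": model.pvalues[1:],
            "vif": vifs,
        }
    )
    # Gaussian BIC counting intercept + k slopes + residual variance
    bic = float((k + 2) * np.log(n) - 2.0 * model.llf)
    shapiro_p = float(stats.shapiro(model.resid).pvalue)
    return RegressionReport(
        outcome=str(yname),
        coefficients=coef,
        bic=bic,
        adj_r2=float(model.rsquared_adj),
        shapiro_p=shapiro_p,
        normality_ok=shapiro_p > 0.05,
        n=n,
    )


def vif_screen(report: RegressionReport, threshold: float = 10.0) -> dict[str, bool]:
    """Per-predictor multicollinearity alarm: True where VIF strictly exceeds
    the threshold (default 10)."""
    return {
        row.predictor: bool(row.vif > threshold)
        for row in report.coefficients.itertuples()
    }


def group_difference(
    a: Sequence[float],
    b: Sequence[float],
    tail: Literal["one", "two"] = "two",
) -> GroupDifference:
    """Student's t-test (pooled variance) and Cohen's d for two groups.

    For ``tail="one"`` the alternative is mean(a) < mean(b) — pass the group
    hypothesized to score lower first. Cohen's d uses the pooled sd; its CI
    is the large-sample normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if pooled_var == 0.0:
        raise DegenerateDataError("zero pooled variance")
    alternative = "less" if tail == "one" else "two-sided"
    res = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
    d = float((a.mean() - b.mean()) / np.sqrt(pooled_var))
    se_d = np.sqrt((n1 + n2) / (n1 * n2) + d * d / (2.0 * df))
    zcrit = stats.norm.ppf(0.975)
    return GroupDifference(
        t=float(res.statistic),
        df=df,
        p=float(res.pvalue),
        tail=tail,
        cohens_d=d,
        d_ci95=(d - zcrit * se_d, d + zcrit * se_d),
    )


def compare_models_bic(reports: Sequence[RegressionReport]) -> pd.DataFrame:
    """Rank regression models of the same outcome by BIC (ascending)."""
    if len(reports) == 0:
        raise ValueError("no reports to compare")
    outcomes = {r.outcome for r in reports}
    ns = {r.n for r in reports}
    if len(outcomes) != 1:
        raise ValueError(f"reports model different outcomes: {sorted(outcomes)}")
    if len(ns) != 1:
        raise ValueError(f"reports cover different n: {sorted(ns)}")
    df = pd.DataFrame(
        {
            "model": [" + ".join(r.coefficients["predictor"]) for r in reports],
            "bic": [r.bic for r in reports],
            "adj_r2": [r.adj_r2 for r in reports],
        }
    ).sort_values("bic", kind="mergesort", ignore_index=True)
    df["delta_bic"] = df["bic"] - df["bic"].iloc[0]
    return df
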