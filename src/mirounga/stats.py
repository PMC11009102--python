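"""The regression and test battery shared by the fitness and diving analyses.

Thin, contract-stable wrappers around statsmodels/scipy: ordinary least
squares with the F statistic reported as r^2-based overall fit, multiple
regression with centred pairwise interactions, the pooled-variance
two-sample t test, and the chi-square / normal tail helpers the categorical
tests rely on.  Incomplete cases are dropped listwise with the effective n
logged and reported, matching field practice where each analysis has its
own n.  One-sided p values are always an explicit flag, never silent.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "ols",
    "multiple_regression_interactions",
    "two_sample_t",
    "chi2_upper_tail",
    "normal_cdf",
    "reproductive_fitness_battery",
]


@dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r2: float
    adj_r2: float
    fvalue: float
    f_pvalue: float
    df_model: int
    df_resid: int
    n: int

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        t = sps.t.ppf(1.0 - alpha / 2.0, self.df_resid)
        return pd.DataFrame(
            {"lower": self.params - t * self.bse, "upper": self.params + t * self.bse}
        )

    def summary_row(self, term: str) -> dict:
        return {
            "term": term,
            "estimate": self.params[term],
            "se": self.bse[term],
            "p": self.pvalues[term],
            "r2": self.r2,
            "F": self.fvalue,
            "n": self.n,
        }


def _find_collinear(X: pd.DataFrame) -> list[str]:
    _, r = np.linalg.qr(np.asarray(X, dtype=float))
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    return [c for c, d in zip(X.columns, diag) if d <= tol]


def ols(y, X, add_intercept: bool = True) -> RegressionResult:
    """Least-squares fit with listwise deletion of incomplete rows.

    ``F = (r^2/k) / ((1 - r^2)/(n - k - 1))`` with p from the F distribution.
    A singular design raises, naming the collinear columns.
    """
    X = pd.DataFrame(X).copy()
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="y")
    complete = y.notna() & X.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("ols: dropped %d incomplete rows (n = %d)", n_dropped, int(complete.sum()))
    y, X = y[complete], X[complete]
    design = sm.add_constant(X, has_constant="add") if add_intercept else X
    if np.linalg.matrix_rank(np.asarray(design, dtype=float)) < design.shape[1]:
        bad = _find_collinear(design)
        raise ValueError(f"singular design matrix; collinear columns: {bad}")
    fit = sm.OLS(y, design).fit()
    return RegressionResult(
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        fvalue=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        n=int(fit.nobs),
    )


def multiple_regression_interactions(y, factors: pd.DataFrame) -> RegressionResult:
    """Main effects plus all pairwise interactions of centred factors.

    Factors are mean-centred before multiplication so interaction terms are
    not dominated by the scale of the mains; per-term p values are the
    coefficient t tests (equivalent to type-III tests for this
    parameterization).
    """
    factors = pd.DataFrame(factors).copy()
    centred = factors - factors.mean()
    design = factors.copy()
    for a, b in itertools.combinations(factors.columns, 2):
        design[f"{a}:{b}"] = centred[a] * centred[b]
    return ols(y, design)


def two_sample_t(a, b, equal_variance: bool = True) -> tuple[float, float, float]:
    """Two-sample t test: (t, df, two-sided p).

    Pooled-variance by default (df = n1 + n2 - 2); Welch optional.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=equal_variance)
    if equal_variance:
        pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        if pooled == 0:
            raise ValueError("zero pooled variance")
        df = float(len(a) + len(b) - 2)
    else:
        df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def chi2_upper_tail(x: float, df: int = 1) -> float:
    """Chi-square survival function (upper tail)."""
    if x < 0 or df < 1:
        raise ValueError("require x >= 0 and df >= 1")
    return float(sps.chi2.sf(x, df))


def normal_cdf(z: float) -> float:
    return float(sps.norm.cdf(z))


def reproductive_fitness_battery(
    females: pd.DataFrame,
    froh: pd.Series,
    burden_strict: pd.Series,
    burden_all: pd.Series,
) -> dict[str, RegressionResult]:
    """The female lifetime-reproductive-success regression battery.

    Expects per-female phenotype columns ``weaned_per_year``, ``total_weaned``,
    ``fecundity``, ``longevity``, ``birth_year``, ``first_weaning_year``
    (missing cells allowed; each fit uses its own complete cases) and
    per-female F_ROH and LOF-burden series aligned on sample_id.

    Returns the named fits:
    weaned~froh, weaned~lof_strict, weaned~lof_all, total~froh,
    longevity~froh, fecundity~froh, environment (birth year + first weaning
    year), environment+froh with pairwise interactions.
    """
    df = females.set_index("sample_id") if "sample_id" in females.columns else females
    df = df.join(froh.rename("froh")).join(burden_strict.rename("lof_strict")).join(
        burden_all.rename("lof_all")
    )
    out: dict[str, RegressionResult] = {}
    out["weaned_froh"] = ols(df["weaned_per_year"], df[["froh"]])
    out["weaned_lof_strict"] = ols(df["weaned_per_year"], df[["lof_strict"]])
    out["weaned_lof_all"] = ols(df["weaned_per_year"], df[["lof_all"]])
    out["total_weaned_froh"] = ols(df["total_weaned"], df[["froh"]])
    out["longevity_froh"] = ols(df["longevity"], df[["froh"]])
    out["fecundity_froh"] = ols(df["fecundity"], df[["froh"]])
    env = df[["birth_year", "first_weaning_year"]]
    out["environment"] = multiple_regression_interactions(df["weaned_per_year"], env)
    out["environment_froh"] = multiple_regression_interactions(
        df["weaned_per_year"], df[["birth_year", "first_weaning_year", "froh"]]
    )
    return out
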