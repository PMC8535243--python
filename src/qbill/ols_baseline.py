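"""OLS mean-regression baseline with residual-normality diagnostics.

Mean regression is the conventional tool for billing analyses, but the
aggressiveness response is strongly right-skewed and leptokurtic, so the
homoscedastic-normal error assumptions behind classical OLS inference
fail.  This module provides the baseline fit (classical standard errors
and t-test p-values), a Monte-Carlo Lilliefors test of residual
normality, and Q-Q plot data — the evidence that motivates moving to
quantile regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike
from scipy import stats

__all__ = ["OlsFit", "fit_ols", "lilliefors_test", "qq_data"]


@dataclass
class OlsFit:
    beta: np.ndarray
    se: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    sigma2: float
    residuals: np.ndarray = field(repr=False)
    r_squared: float
    feature_names: list[str]
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None

    def table(self) -> pd.DataFrame:
        """Estimate / s.e. / p-value table, one row per variable."""
        return pd.DataFrame(
            {"estimate": self.beta, "se": self.se, "p_value": self.p_values},
            index=["(Intercept)"] + list(self.feature_names),
        ).rename_axis("variable")


def fit_ols(
    X: ArrayLike,
    y: ArrayLike,
    feature_names: list[str] | None = None,
    robust: bool = False,
    ci_level: float = 0.95,
) -> OlsFit:
    """Ordinary least squares with classical (homoscedastic) inference.

    ``robust=True`` switches to HC1 heteroscedasticity-consistent
    standard errors.  Rank deficiency is fatal, naming the columns.
    """
    import statsmodels.api as sm

    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p+1 observations (n={n}, p+1={p + 1})")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(1, p + 1)]
    Xa = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        from .quantile_core import _check_rank

        _check_rank(Xa, list(feature_names))  # raises with offending columns
    res = sm.OLS(y, Xa).fit(cov_type="HC1" if robust else "nonrobust")
    ci = res.conf_int(alpha=1.0 - ci_level)
    return OlsFit(
        beta=np.asarray(res.params),
        se=np.asarray(res.bse),
        t_stats=np.asarray(res.tvalues),
        p_values=np.asarray(res.pvalues),
        sigma2=float(res.mse_resid),
        residuals=np.asarray(res.resid),
        r_squared=float(res.rsquared),
        feature_names=list(feature_names),
        ci_lower=np.asarray(ci)[:, 0],
        ci_upper=np.asarray(ci)[:, 1],
    )


def _lilliefors_statistic(x: np.ndarray) -> float:
    """Sup distance between the ECDF of ``x`` and a normal CDF with the
    sample's estimated mean and sd."""
    n = x.shape[0]
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - cdf, cdf - (i - 1) / n)))


def _null_statistics(n: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """Null distribution of the Lilliefors statistic at sample size n,
    vectorized over Monte-Carlo replicates."""
    z = rng.standard_normal((reps, n))
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
    z.sort(axis=1)
    cdf = stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    d = np.maximum(i / n - cdf, cdf - (i - 1) / n)
    return d.max(axis=1)


def lilliefors_test(
    residuals: ArrayLike, mc_reps: int = 10_000, seed: int | np.random.SeedSequence = 0
) -> tuple[float, float]:
    """Lilliefors (KS-with-estimated-parameters) test of normality.

    The p-value is Monte Carlo: ``mc_reps`` samples of n standard normals
    run through the same estimate-then-KS step, and
    ``p = (1 + #{D* >= D}) / (mc_reps + 1)``.  Exact for any n and
    reproducible given the seed.  Zero-variance residuals are degenerate
    and return p = 0.
    """
    x = np.asarray(residuals, dtype=float)
    if x.shape[0] < 5:
        raise ValueError(f"need at least 5 residuals, got {x.shape[0]}")
    if x.std(ddof=1) == 0:
        return 0.0, 0.0
    d = _lilliefors_statistic(x)
    rng = np.random.default_rng(seed)
    null = _null_statistics(x.shape[0], mc_reps, rng)
    p = (1.0 + float(np.sum(null >= d))) / (mc_reps + 1.0)
    return d, p


def qq_data(residuals: ArrayLike) -> pd.DataFrame:
    """Normal Q-Q pairs for standardized residuals.

    Order statistics of the standardized residuals against standard-normal
    quantiles at plotting positions (i - 0.5)/n; plot-ready CSV shape.
    """
    x = np.asarray(residuals, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 residuals, got {n}")
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    pos = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({"theoretical": stats.norm.ppf(pos), "sample": z})
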