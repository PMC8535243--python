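"""Check-loss and asymmetric-Laplace primitives, and exact quantile regression.

The conditional :math:`\\tau`-quantile model is ``y_i = x_i' beta(tau) + e_i``
with ``P(e <= 0 | x) = tau``.  Estimation minimizes the summed check
(pinball) loss, which is equivalent to maximum likelihood under an
asymmetric Laplace error law.  Two check-loss conventions circulate in the
literature; both are supported and give identical minimizers:

* ``"standard"`` (Koenker):  rho_tau(e) = e * (tau - I(e < 0))
* ``"factor2"``:             rho_tau(e) = e * (2*tau - 2*I(e < 0))

The factor-2 convention is the package default because the associated ALD
density ``tau*(1-tau)/sigma * exp(-rho_tau(e)/(2*sigma))`` is then properly
normalized.

The minimization is solved exactly as a linear program.  We solve the
*dual* LP -- maximize ``y'a`` subject to ``X'a = 0`` and
``a_i in [tau-1, tau]`` -- whose equality-constraint marginals are the
primal coefficients.  With n box variables and only p+1 rows this is much
faster than the primal residual-split formulation and numerically
identical (both are solved by HiGHS to vertex solutions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike
from scipy.optimize import linprog

__all__ = [
    "DEFAULT_QUANTILES",
    "check_loss",
    "ald_logpdf",
    "ald_cdf",
    "ald_ppf",
    "QuantileFit",
    "fit_quantreg",
    "bootstrap_ci",
    "BootstrapResult",
    "residual_sign_diagnostic",
    "significance_stars",
    "quantile_table",
]

logger = logging.getLogger(__name__)

#: Quantile levels used throughout the billing-aggressiveness study: both
#: tails (0.01/0.99: extremely conservative vs. extremely aggressive
#: providers), the shoulders, and the median.
DEFAULT_QUANTILES = (0.01, 0.05, 0.25, 0.50, 0.75, 0.95, 0.99)

_SIGN_TOL = 1e-9  # residual magnitude below this counts as "on the fit"


def check_loss(e: ArrayLike, tau: float, convention: str = "factor2"):
    """Check (pinball) loss of residual(s) ``e`` at quantile level ``tau``.

    ``convention="factor2"`` returns exactly twice the standard Koenker
    loss; the minimizer is unaffected.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    e = np.asarray(e, dtype=float)
    rho = e * (tau - (e < 0))
    if convention == "factor2":
        return 2.0 * rho
    if convention == "standard":
        return rho
    raise ValueError(f"unknown check-loss convention {convention!r}")


# ---------------------------------------------------------------------------
# Asymmetric Laplace distribution, parameterized by (mu, sigma, tau) with
# density  f(e) = tau*(1-tau)/sigma * exp(-rho_tau(e - mu) / (2*sigma))
# under the factor-2 check loss, so that P(E <= mu) = tau exactly.
# ---------------------------------------------------------------------------

def _check_ald_params(sigma: float, tau: float) -> None:
    if sigma <= 0:
        raise ValueError(f"ALD scale sigma must be > 0, got {sigma}")
    if not 0.0 < tau < 1.0:
        raise ValueError(f"ALD asymmetry tau must be in (0, 1), got {tau}")


def ald_logpdf(e: ArrayLike, mu: float = 0.0, sigma: float = 1.0, tau: float = 0.5):
    """Log-density of the asymmetric Laplace law at ``e``."""
    _check_ald_params(sigma, tau)
    e = np.asarray(e, dtype=float)
    return np.log(tau * (1.0 - tau) / sigma) - check_loss(e - mu, tau) / (2.0 * sigma)


def ald_cdf(e: ArrayLike, mu: float = 0.0, sigma: float = 1.0, tau: float = 0.5):
    """CDF of the asymmetric Laplace law.

    Piecewise exponential: ``tau * exp((1-tau) z / sigma)`` below the
    location, ``1 - (1-tau) * exp(-tau z / sigma)`` above (z = e - mu).
    """
    _check_ald_params(sigma, tau)
    z = np.asarray(e, dtype=float) - mu
    lower = tau * np.exp((1.0 - tau) * np.minimum(z, 0.0) / sigma)
    upper = 1.0 - (1.0 - tau) * np.exp(-tau * np.maximum(z, 0.0) / sigma)
    return np.where(z <= 0, lower, upper)


def ald_ppf(q: ArrayLike, mu: float = 0.0, sigma: float = 1.0, tau: float = 0.5):
    """Quantile function of the asymmetric Laplace law; ``ald_ppf(tau) == mu``."""
    _check_ald_params(sigma, tau)
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("quantile levels must be in the open interval (0, 1)")
    lower = sigma / (1.0 - tau) * np.log(q / tau)
    upper = -sigma / tau * np.log((1.0 - q) / (1.0 - tau))
    return mu + np.where(q <= tau, lower, upper)


# ---------------------------------------------------------------------------
# Exact quantile regression via the dual LP
# ---------------------------------------------------------------------------

@dataclass
class QuantileFit:
    """Result of one quantile-regression fit.

    ``beta[0]`` is the intercept; ``objective`` is the minimized summed
    check loss in the factor-2 convention (``objective_standard`` is the
    Koenker-convention value, exactly half).
    """

    tau: float
    beta: np.ndarray
    objective: float
    objective_standard: float
    n_below: int
    n_above: int
    n_zero: int
    n_obs: int
    feature_names: list[str]
    method: str = "dual-lp-highs"
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    p_values: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.beta[0] + X @ self.beta[1:]


def _design_with_intercept(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.column_stack([np.ones(X.shape[0]), X])


def _check_rank(Xa: np.ndarray, feature_names: list[str]) -> None:
    from scipy.linalg import qr

    _, r, piv = qr(Xa, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(Xa.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < Xa.shape[1]:
        names = ["(intercept)"] + list(feature_names)
        bad = [names[j] for j in piv[rank:]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {Xa.shape[1]}); "
            f"offending columns: {bad}"
        )


def fit_quantreg(
    X: ArrayLike,
    y: ArrayLike,
    tau: float,
    feature_names: list[str] | None = None,
    check_rank: bool = True,
) -> QuantileFit:
    """Fit ``quantile(y | x) = beta0 + x' beta`` by exact LP minimization.

    Parameters
    ----------
    X : (n, p) array of covariates (no intercept column; one is added).
    y : (n,) response.
    tau : quantile level in (0, 1).

    Raises
    ------
    numpy.linalg.LinAlgError
        If the design (with intercept) is rank deficient; the offending
        columns are named.
    RuntimeError
        If the LP solver does not converge.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    y = np.asarray(y, dtype=float)
    Xa = _design_with_intercept(X)
    n, p1 = Xa.shape
    if n <= p1:
        raise ValueError(f"need n > p+1 observations (n={n}, p+1={p1})")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(1, p1)]
    if check_rank:
        _check_rank(Xa, feature_names)

    res = linprog(
        -y,
        A_eq=Xa.T,
        b_eq=np.zeros(p1),
        bounds=[(tau - 1.0, tau)] * n,
        method="highs",
    )
    if res.status != 0:
        raise RuntimeError(f"quantile LP failed (tau={tau}): {res.message}")
    beta = -np.asarray(res.eqlin.marginals, dtype=float)
    resid = y - Xa @ beta
    obj_std = float(np.sum(check_loss(resid, tau, "standard")))
    return QuantileFit(
        tau=tau,
        beta=beta,
        objective=2.0 * obj_std,
        objective_standard=obj_std,
        n_below=int(np.sum(resid < -_SIGN_TOL)),
        n_above=int(np.sum(resid > _SIGN_TOL)),
        n_zero=int(np.sum(np.abs(resid) <= _SIGN_TOL)),
        n_obs=n,
        feature_names=list(feature_names),
    )


def residual_sign_diagnostic(fit: QuantileFit) -> tuple[float, bool]:
    """Share of negative residuals and whether LP optimality sign bounds hold.

    At any optimum, ``#{r_i < 0} <= n*tau`` and ``#{r_i > 0} <= n*(1-tau)``;
    the check-loss subgradient condition forces both.
    """
    n, tau = fit.n_obs, fit.tau
    ok = (fit.n_below <= n * tau + 1e-9) and (fit.n_above <= n * (1.0 - tau) + 1e-9)
    return fit.n_below / n, ok


# ---------------------------------------------------------------------------
# xy-pair bootstrap confidence bands
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    tau: float
    level: float
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    betas: np.ndarray = field(repr=False)
    n_redrawn: int = 0


def bootstrap_ci(
    X: ArrayLike,
    y: ArrayLike,
    tau: float,
    B: int = 1000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence = 0,
    max_redraws: int = 100,
) -> BootstrapResult:
    """Percentile bootstrap intervals for quantile-regression coefficients.

    Resamples (x_i, y_i) pairs with replacement, which is valid under the
    heteroscedastic (location-scale) error structure the billing data
    exhibit.  Also returns a two-sided proportion-based p-value analogue
    per coefficient, ``2 * min(P*(b <= 0), P*(b >= 0))``, used for the
    star annotations of the coefficient tables.

    Rank-deficient resamples (possible with categorical-ish covariates)
    are redrawn and counted.
    """
    if B < 100:
        raise ValueError(f"need B >= 100 bootstrap replicates, got {B}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    rng = np.random.default_rng(seed)

    betas = np.empty((B, X.shape[1] + 1))
    n_redrawn = 0
    for b in range(B):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            try:
                fit = fit_quantreg(X[idx], y[idx], tau, check_rank=True)
            except np.linalg.LinAlgError:
                n_redrawn += 1
                continue
            betas[b] = fit.beta
            break
        else:  # pragma: no cover - pathological design
            raise RuntimeError("bootstrap: too many rank-deficient resamples")
    if n_redrawn:
        logger.info("bootstrap_ci: redrew %d rank-deficient resamples", n_redrawn)

    alpha = 1.0 - level
    lo = np.quantile(betas, alpha / 2.0, axis=0)
    hi = np.quantile(betas, 1.0 - alpha / 2.0, axis=0)
    p_le = np.mean(betas <= 0.0, axis=0)
    p_ge = np.mean(betas >= 0.0, axis=0)
    pvals = np.minimum(1.0, 2.0 * np.minimum(p_le, p_ge))
    return BootstrapResult(
        tau=tau, level=level, ci_lower=lo, ci_upper=hi,
        p_values=pvals, betas=betas, n_redrawn=n_redrawn,
    )


def significance_stars(p: float) -> str:
    """Star annotation: [0, 0.001) -> ***, [0.001, 0.01) -> **, [0.01, 0.05) -> *."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def quantile_table(fits: list[QuantileFit]):
    """Assemble per-quantile coefficient estimates into a variables x
    quantiles table, with star annotations in a parallel column set when
    bootstrap p-values are attached to the fits."""
    import pandas as pd

    if not fits:
        raise ValueError("no fits supplied")
    names = ["(Intercept)"] + list(fits[0].feature_names)
    data, stars = {}, {}
    has_p = all(f.p_values is not None for f in fits)
    for f in sorted(fits, key=lambda f: f.tau):
        if list(f.feature_names) != names[1:]:
            raise ValueError("fits have mismatched feature names")
        data[f"{f.tau:g}"] = f.beta
        if has_p:
            stars[f"stars_{f.tau:g}"] = [significance_stars(p) for p in f.p_values]
    out = pd.DataFrame(data, index=names)
    out.index.name = "variable"
    if has_p:
        for k, v in stars.items():
            out[k] = v
    return out
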