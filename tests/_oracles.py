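"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles with plain
numpy (no qbill internals), so agreement between the package and these
oracles is a genuine cross-check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def pinball(e: np.ndarray, tau: float) -> np.ndarray:
    """Standard-convention check loss, written independently."""
    e = np.asarray(e, dtype=float)
    return np.where(e >= 0, tau * e, (tau - 1.0) * e)


def enum_quantile_objective(X: np.ndarray, y: np.ndarray, tau: float) -> float:
    """Exhaustive basic-solution oracle for unpenalized quantile regression.

    An optimal LP vertex interpolates p+1 observations (generic position),
    so the global minimum equals the best check loss over all exact fits
    through every subset of p+1 points.  Returns the standard-convention
    objective.
    """
    Xa = np.column_stack([np.ones(len(y)), X])
    n, k = Xa.shape
    best = np.inf
    for idx in combinations(range(n), k):
        A = Xa[list(idx)]
        try:
            beta = np.linalg.solve(A, y[list(idx)])
        except np.linalg.LinAlgError:
            continue
        obj = float(np.sum(pinball(y - Xa @ beta, tau)))
        best = min(best, obj)
    return best


def l1_grid_objective(
    x: np.ndarray,
    y: np.ndarray,
    tau: float,
    lam: float,
    n_refine: int = 6,
    n_points: int = 41,
):
    """2-D grid-search oracle for the single-covariate penalized problem.

    Minimizes ``sum 2*pinball + lam*n*|b1|`` over (b0, b1) on the
    *standardized* covariate by grid refinement inside a box that provably
    contains the minimizer: the penalty bounds ``|b1| <= obj(q_tau, 0) /
    (lam n)``, and the optimal b0 is a quantile of ``y - xs*b1``.  Returns
    (best objective, grid tolerance bound), where the bound is a Lipschitz
    bound on how far the grid minimum can sit above the true minimum.
    """
    n = len(y)
    xs = (x - x.mean()) / x.std(ddof=1)

    def obj(b0, b1):
        return float(np.sum(2.0 * pinball(y - b0 - xs * b1, tau))) + lam * n * abs(b1)

    # rigorous bounding box for the minimizer
    r = obj(np.quantile(y, tau), 0.0) / (lam * n)
    b1_lo, b1_hi = -r, r
    xmax = float(np.abs(xs).max())
    b0_lo, b0_hi = y.min() - xmax * r, y.max() + xmax * r

    best = (np.inf, 0.0, 0.0)
    h0 = h1 = np.inf
    for _ in range(n_refine):
        b0s = np.linspace(b0_lo, b0_hi, n_points)
        b1s = np.linspace(b1_lo, b1_hi, n_points)
        grid = np.array([[obj(b0, b1) for b1 in b1s] for b0 in b0s])
        i, j = np.unravel_index(np.argmin(grid), grid.shape)
        if grid[i, j] < best[0]:
            best = (float(grid[i, j]), b0s[i], b1s[j])
        h0 = b0s[1] - b0s[0] if n_points > 1 else b0_hi - b0_lo
        h1 = b1s[1] - b1s[0] if n_points > 1 else b1_hi - b1_lo
        # window of +-3 cells around the incumbent for the next sweep
        b0_lo, b0_hi = best[1] - 3 * h0, best[1] + 3 * h0
        b1_lo, b1_hi = best[2] - 3 * h1, best[2] + 3 * h1
    lip = 2.0 * n * max(tau, 1.0 - tau) * (1.0 + xmax) + lam * n
    tol = lip * max(h0, h1)
    return best[0], tol


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form OLS coefficients via the normal equations."""
    Xa = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(Xa.T @ Xa, Xa.T @ y)


def ks_sup_distance_vs_fitted_normal(x: np.ndarray) -> float:
    """Direct sup-norm computation of the Lilliefors statistic by scanning
    both one-sided ECDF gaps at every order statistic."""
    from scipy.stats import norm

    n = len(x)
    z = np.sort((x - np.mean(x)) / np.std(x, ddof=1))
    d = 0.0
    for i in range(n):
        f = norm.cdf(z[i])
        d = max(d, abs((i + 1) / n - f), abs(f - i / n))
    return d
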