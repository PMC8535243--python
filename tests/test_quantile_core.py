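"""Check-loss, ALD and exact quantile-regression fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from qbill.quantile_core import (
    DEFAULT_QUANTILES,
    ald_cdf,
    ald_logpdf,
    ald_ppf,
    bootstrap_ci,
    check_loss,
    fit_quantreg,
    quantile_table,
    residual_sign_diagnostic,
    significance_stars,
)

from ._oracles import enum_quantile_objective, pinball
from .conftest import random_instance


@pytest.mark.parametrize(
    "tau,e,expected",
    [(0.5, 3.0, 3.0), (0.25, -2.0, 3.0), (0.9, 0.0, 0.0), (0.5, -1.0, 1.0)],
)
def test_check_loss_values(tau, e, expected):
    assert check_loss(e, tau) == pytest.approx(expected, abs=1e-12)
    assert check_loss(e, tau, "standard") == pytest.approx(expected / 2.0, abs=1e-12)


@given(st.floats(-50, 50), st.floats(0.01, 0.99))
def test_check_loss_convention_and_nonnegativity(e, tau):
    f2 = float(check_loss(e, tau))
    assert f2 == pytest.approx(2.0 * float(check_loss(e, tau, "standard")), rel=1e-12)
    assert f2 >= 0.0
    assert f2 == pytest.approx(2.0 * float(pinball(e, tau)), rel=1e-12, abs=1e-12)


ALD_GRID = [(0.3, 0.1), (0.5, 0.3), (1.0, 0.5), (2.0, 0.8), (0.7, 0.95)]


@pytest.mark.parametrize("sigma,tau", ALD_GRID)
def test_ald_density_normalizes_by_quadrature(sigma, tau):
    total, err = integrate.quad(
        lambda e: np.exp(ald_logpdf(e, 0.0, sigma, tau)), -np.inf, np.inf
    )
    assert total == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("sigma,tau", ALD_GRID)
def test_ald_mass_below_location_is_tau(sigma, tau):
    mass, err = integrate.quad(
        lambda e: np.exp(ald_logpdf(e, 0.0, sigma, tau)), -np.inf, 0.0
    )
    assert mass == pytest.approx(tau, abs=1e-6)
    assert float(ald_cdf(0.0, 0.0, sigma, tau)) == pytest.approx(tau, abs=1e-12)


def test_ald_matches_scipy_asymmetric_laplace():
    """Our (mu, sigma, tau) parameterization maps onto scipy's
    laplace_asymmetric with kappa = sqrt(tau/(1-tau)), scale = sigma/sqrt(tau(1-tau))."""
    e = np.linspace(-4, 5, 41)
    for sigma, tau in ALD_GRID:
        kappa = np.sqrt(tau / (1.0 - tau))
        scale = sigma / np.sqrt(tau * (1.0 - tau))
        ref = stats.laplace_asymmetric.logpdf(e, kappa, loc=0.0, scale=scale)
        np.testing.assert_allclose(ald_logpdf(e, 0.0, sigma, tau), ref, atol=1e-10)


@given(st.floats(0.01, 0.99), st.floats(0.05, 3.0), st.floats(0.05, 0.95))
def test_ald_ppf_inverts_cdf(q, sigma, tau):
    x = float(ald_ppf(q, 0.0, sigma, tau))
    assert float(ald_cdf(x, 0.0, sigma, tau)) == pytest.approx(q, abs=1e-10)


def test_ald_logpdf_at_location():
    # exponent vanishes at the location: f(0) = tau*(1-tau)/sigma
    assert float(ald_logpdf(0.0, 0.0, 0.5, 0.5)) == pytest.approx(np.log(0.5))
    with pytest.raises(ValueError):
        ald_logpdf(0.0, sigma=-1.0)


def test_intercept_only_median():
    y = np.array([1.0, 2.0, 9.0])
    fit = fit_quantreg(np.empty((3, 0)), y, 0.5, check_rank=False)
    assert fit.beta[0] == pytest.approx(2.0, abs=1e-9)
    # factor-2 loss at tau=0.5 reduces to sum |r|
    assert fit.objective == pytest.approx(8.0, abs=1e-9)


@pytest.mark.parametrize("tau", [0.1, 0.5, 0.9])
def test_exact_interpolation(tau):
    x = np.array([0.0, 1.0, 2.0])
    y = 1.5 + 2.0 * x
    fit = fit_quantreg(x[:, None], y, tau)
    np.testing.assert_allclose(fit.beta, [1.5, 2.0], atol=1e-9)
    assert fit.objective == pytest.approx(0.0, abs=1e-9)


def test_matches_enumeration_oracle():
    rng = np.random.default_rng(42)
    for _ in range(30):
        X, y = random_instance(rng)
        tau = float(rng.uniform(0.05, 0.95))
        fit = fit_quantreg(X, y, tau)
        assert fit.objective_standard == pytest.approx(
            enum_quantile_objective(X, y, tau), abs=1e-9
        )


def test_matches_statsmodels_quantreg():
    """Cross-check against the iteratively-reweighted implementation in
    statsmodels; the LP optimum can only be at least as good."""
    import statsmodels.api as sm

    rng = np.random.default_rng(3)
    X = rng.standard_normal((200, 3))
    y = 1.0 + X @ np.array([0.5, -1.0, 2.0]) + rng.standard_normal(200)
    for tau in (0.25, 0.5, 0.9):
        fit = fit_quantreg(X, y, tau)
        ref = sm.QuantReg(y, sm.add_constant(X)).fit(q=tau)
        ref_obj = float(np.sum(pinball(y - sm.add_constant(X) @ ref.params, tau)))
        assert fit.objective_standard <= ref_obj + 1e-6
        np.testing.assert_allclose(fit.beta, np.asarray(ref.params), atol=5e-3)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_equivariance(seed):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((40, 2))
    y = rng.standard_normal(40)
    tau = 0.3
    base = fit_quantreg(X, y, tau)
    scaled = fit_quantreg(X, 3.0 * y, tau)
    np.testing.assert_allclose(scaled.beta, 3.0 * base.beta, atol=1e-7)
    gamma = np.array([1.0, -2.0])
    shifted = fit_quantreg(X, y + X @ gamma, tau)
    np.testing.assert_allclose(shifted.beta[1:], base.beta[1:] + gamma, atol=1e-7)
    np.testing.assert_allclose(shifted.beta[0], base.beta[0], atol=1e-7)


def test_monotone_quantile_curve_intercept_only():
    rng = np.random.default_rng(5)
    y = rng.lognormal(1.0, 0.8, 120)
    fitted = [fit_quantreg(np.empty((120, 0)), y, t, check_rank=False).beta[0]
              for t in DEFAULT_QUANTILES]
    assert np.all(np.diff(fitted) >= -1e-12)


def test_residual_sign_shares():
    rng = np.random.default_rng(9)
    y = rng.standard_normal(101)
    fit = fit_quantreg(np.empty((101, 0)), y, 0.5, check_rank=False)
    share, ok = residual_sign_diagnostic(fit)
    assert ok
    assert 0.49 <= share <= 0.51
    # interpolated data: all residuals zero
    x = np.arange(4.0)
    ifit = fit_quantreg(x[:, None], 2.0 * x, 0.5)
    share, ok = residual_sign_diagnostic(ifit)
    assert share == 0.0 and ok


def test_sign_bounds_at_extreme_quantile():
    rng = np.random.default_rng(11)
    X = rng.standard_normal((2000, 3))
    y = X @ np.array([1.0, 0.5, -0.5]) + rng.standard_normal(2000)
    fit = fit_quantreg(X, y, 0.95)
    share, ok = residual_sign_diagnostic(fit)
    assert ok
    assert 0.95 - 4.0 / 2000 <= share <= 0.95


def test_rank_deficiency_names_columns():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(30)
    X = np.column_stack([x, 2.0 * x])
    # either member of the collinear pair may be flagged by pivoted QR
    with pytest.raises(np.linalg.LinAlgError, match="x[12]"):
        fit_quantreg(X, rng.standard_normal(30), 0.5, feature_names=["x1", "x2"])


def test_objective_recomputes_from_residuals(small_study):
    X = small_study.X.to_numpy(dtype=float)
    y = small_study.y
    fit = fit_quantreg(X, y, 0.75)
    resid = y - fit.predict(X)
    assert fit.objective == pytest.approx(float(np.sum(check_loss(resid, 0.75))), abs=1e-9)


def test_bootstrap_deterministic_and_degenerate():
    rng = np.random.default_rng(21)
    X = rng.standard_normal((60, 2))
    y_noisy = X @ np.array([1.0, -1.0]) + rng.standard_normal(60)
    b1 = bootstrap_ci(X, y_noisy, 0.5, B=150, seed=123)
    b2 = bootstrap_ci(X, y_noisy, 0.5, B=150, seed=123)
    np.testing.assert_array_equal(b1.betas, b2.betas)
    # noiseless linear data: every resample refits the same line exactly
    y_exact = 0.5 + X @ np.array([1.0, -1.0])
    b = bootstrap_ci(X, y_exact, 0.5, B=150, seed=1)
    np.testing.assert_allclose(b.ci_upper - b.ci_lower, 0.0, atol=1e-8)
    with pytest.raises(ValueError):
        bootstrap_ci(X, y_noisy, 0.5, B=50)


def test_bootstrap_coverage_on_ald_design():
    """Percentile intervals should cover the true quantile coefficients at
    close to nominal rate on location-scale ALD data (scaled-down run)."""
    from qbill.quantile_core import ald_ppf

    covered = total = 0
    tau = 0.5
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        X = rng.standard_normal((300, 3))
        beta_true = np.array([1.0, 1.0, -1.0, 0.5])
        u, v = rng.exponential(1.0, 300), rng.exponential(1.0, 300)
        eps = 0.4 * (u / 0.5 - v / 0.5)  # symmetric ALD, median 0
        y = beta_true[0] + X @ beta_true[1:] + eps
        boot = bootstrap_ci(X, y, tau, B=150, seed=seed)
        covered += int(np.sum((boot.ci_lower <= beta_true) & (beta_true <= boot.ci_upper)))
        total += 4
    assert covered / total >= 0.85


def test_significance_stars_scheme():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.001) == "**"
    assert significance_stars(0.01) == "*"
    assert significance_stars(0.05) == ""


def test_quantile_table_shape(small_study):
    X = small_study.X.to_numpy(dtype=float)
    fits = []
    for tau in (0.25, 0.75):
        f = fit_quantreg(X, small_study.y, tau, feature_names=list(small_study.X.columns))
        b = bootstrap_ci(X, small_study.y, tau, B=100, seed=0)
        f.ci_lower, f.ci_upper, f.p_values = b.ci_lower, b.ci_upper, b.p_values
        fits.append(f)
    tbl = quantile_table(fits)
    assert list(tbl.columns) == ["0.25", "0.75", "stars_0.25", "stars_0.75"]
    assert tbl.shape[0] == 15
    assert tbl.index[0] == "(Intercept)"
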