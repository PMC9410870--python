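"""Distribution-function properties of the TIHLBX-G family."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import kstest

import tihlburr as t
from tihlburr.family import series_pdf

from conftest import PARAM_GRID, TABLE4_ITALY


def _quad_pdf(params, a, b):
    return quad(lambda v: t.pdf(params, v), a, b, limit=200)[0]


@pytest.mark.parametrize("theta", PARAM_GRID)
def test_density_normalizes(theta):
    params = t.tihlbw_params(*theta)
    upper = t.quantile(params, 1 - 1e-12)
    assert _quad_pdf(params, 0, upper) == pytest.approx(1.0, abs=1e-6)


def test_cdf_boundary_values(default_params):
    assert t.cdf(default_params, 0.0) == 0.0
    assert t.cdf(default_params, np.inf) == 1.0
    x = np.linspace(1e-3, 5, 200)
    F = t.cdf(default_params, x)
    assert np.all(np.diff(F) >= 0)
    assert np.all((F >= 0) & (F <= 1))


def test_cdf_matches_density_quadrature(italy_params):
    # CDF at x = 0.1 against adaptive quadrature of the density from 0
    val = _quad_pdf(italy_params, 0, 0.1)
    assert t.cdf(italy_params, 0.1) == pytest.approx(val, abs=1e-8)


@pytest.mark.parametrize("theta", [(1.2, 0.5, 1.5, 1.5), TABLE4_ITALY, (3.0, 2.0, 3.0, 0.5)])
def test_pdf_matches_cdf_derivative(theta):
    params = t.tihlbw_params(*theta)
    h = 1e-6
    for p in (0.1, 0.3, 0.5, 0.7, 0.9):
        x = float(t.quantile(params, p))
        deriv = (t.cdf(params, x + h) - t.cdf(params, x - h)) / (2 * h)
        assert t.pdf(params, x) == pytest.approx(deriv, rel=1e-5)


def test_pdf_at_italy_estimates_points(italy_params):
    # spot value via the CDF-derivative oracle at the application's scale
    x = 0.15
    h = 1e-7
    deriv = (t.cdf(italy_params, x + h) - t.cdf(italy_params, x - h)) / (2 * h)
    assert t.pdf(italy_params, x) == pytest.approx(deriv, rel=1e-4)


def test_hazard_identity_and_sign(default_params):
    xs = np.linspace(0.02, 2.0, 50)
    sf = t.sf(default_params, xs)
    mask = sf > 1e-12
    ratio = t.hazard(default_params, xs[mask]) * sf[mask] / t.pdf(default_params, xs[mask])
    assert np.max(np.abs(ratio - 1)) < 1e-10
    assert np.all(t.hazard(default_params, xs) >= 0)
    # beyond numerical support the convention is +inf
    assert np.isposinf(t.hazard(default_params, 1e6))


def test_cumulative_hazard_quadrature(default_params):
    for x in (0.3, 0.8, 1.2):
        ch = quad(lambda v: t.hazard(default_params, v), 0, x, limit=200)[0]
        assert ch == pytest.approx(-np.log(t.sf(default_params, x)), abs=1e-6)


@pytest.mark.parametrize("theta", PARAM_GRID[:8])
def test_quantile_roundtrip(theta):
    params = t.tihlbw_params(*theta)
    p = np.array([1e-6, 1e-4, 0.01, 0.1, 0.5, 0.9, 0.99, 1 - 1e-4, 1 - 1e-6])
    x = t.quantile(params, p)
    assert np.max(np.abs(t.cdf(params, x) - p)) < 1e-10
    assert np.all(np.diff(x) >= 0)
    assert t.quantile(params, 0.0) == 0.0
    assert np.isposinf(t.quantile(params, 1.0))


def test_quantile_agrees_with_bisection(default_params):
    x_bis = brentq(lambda v: t.cdf(default_params, v) - 0.5, 1e-9, 100, xtol=1e-12)
    assert float(t.quantile(default_params, 0.5)) == pytest.approx(x_bis, abs=1e-9)


def test_rvs_deterministic_and_calibrated(default_params):
    a = t.rvs(default_params, 10, seed=42)
    b = t.rvs(default_params, 10, seed=42)
    np.testing.assert_array_equal(a, b)

    x = t.rvs(default_params, 5000, seed=7)
    # one-sample KS against the package's own cdf must not reject at 1%
    res = kstest(x, lambda v: t.cdf(default_params, v))
    assert res.pvalue > 0.01

    mean_quad = quad(lambda v: v * t.pdf(default_params, v), 0, 20, limit=200)[0]
    var_quad = quad(lambda v: (v - mean_quad) ** 2 * t.pdf(default_params, v), 0, 20,
                    limit=200)[0]
    se = np.sqrt(var_quad / 5000)
    assert abs(x.mean() - mean_quad) < 3 * se


def test_rvs_validates_n(default_params):
    with pytest.raises(ValueError):
        t.rvs(default_params, 0, seed=1)


@pytest.mark.parametrize("lam,alpha,probs", [
    (2.0, 1.0, (0.05, 0.2, 0.4)),
    (1.2, 1.0, (0.05, 0.2, 0.4)),
    (3.0, 2.0, (0.05, 0.1, 0.15)),
    (1.5, 3.0, (0.01, 0.03, 0.05)),
])
def test_series_pdf_matches_density(lam, alpha, probs):
    """The re-derived exponentiated-Weibull double series converges to the
    density inside its convergence region (integer Burr X shape); larger
    shape values shrink the region, so the probe points scale with them."""
    params = t.tihlbw_params(lam, alpha, 1.5, 1.5)
    for p in probs:
        x = float(t.quantile(params, p))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val = float(np.atleast_1d(series_pdf(params, x, 40, 40))[0])
        assert val == pytest.approx(t.pdf(params, x), abs=1e-6)


def test_series_pdf_truncation_refines():
    params = t.tihlbw_params(2.0, 1.0, 1.5, 1.5)
    x = float(t.quantile(params, 0.3))
    errs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for m in (0, 2, 5, 10, 20, 40):
            val = float(np.atleast_1d(series_pdf(params, x, m, m))[0])
            errs.append(abs(val - t.pdf(params, x)))
    assert all(e1 >= e2 for e1, e2 in zip(errs, errs[1:]))


def test_series_pdf_mass_matches_cdf_on_validity_region():
    """Quadrature of the truncated series against the CDF.

    The w-series has a finite convergence radius, so the check integrates up
    to a point safely inside it and compares with the CDF there rather than
    integrating the whole support.
    """
    params = t.tihlbw_params(1.0, 1.0, 1.5, 1.5)
    xc = float(t.quantile(params, 0.5))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mass = quad(
            lambda v: float(np.atleast_1d(series_pdf(params, v, 60, 60))[0]),
            1e-9, xc, limit=100,
        )[0]
    assert mass == pytest.approx(float(t.cdf(params, xc)), abs=1e-4)


def test_series_pdf_requires_integer_alpha():
    with pytest.raises(ValueError, match="integer"):
        series_pdf(t.tihlbw_params(1.2, 0.82, 0.5, 1.9), 0.15)


def test_exponential_baseline_is_unit_shape_weibull():
    pw = t.tihlbw_params(1.3, 0.7, 1.0, 2.0)
    pe = t.ModelParams(1.3, 0.7, t.exponential(2.0))
    x = np.linspace(0.01, 3, 40)
    np.testing.assert_allclose(t.cdf(pw, x), t.cdf(pe, x), atol=1e-12)
    np.testing.assert_allclose(t.pdf(pw, x), t.pdf(pe, x), rtol=1e-12)


def test_cdf_ordering_in_delta():
    # larger delta shifts mass toward 0, so the CDF increases pointwise
    x = np.linspace(0.05, 2, 30)
    prev = t.cdf(t.tihlbw_params(1.2, 0.5, 1.5, 0.5), x)
    for delta in (1.0, 1.5, 2.5, 4.0):
        cur = t.cdf(t.tihlbw_params(1.2, 0.5, 1.5, delta), x)
        assert np.all(cur >= prev - 1e-14)
        prev = cur


def test_lomax_baseline_functions():
    pl = t.ModelParams(1.5, 1.0, t.lomax(2.0, 1.0))
    p = np.array([0.1, 0.5, 0.9])
    x = t.quantile(pl, p)
    assert np.max(np.abs(t.cdf(pl, x) - p)) < 1e-10
    assert _quad_pdf(pl, 0, float(t.quantile(pl, 1 - 1e-10))) == pytest.approx(1.0, abs=1e-6)


def test_input_validation(default_params):
    with pytest.raises(ValueError):
        t.cdf(default_params, -0.5)
    with pytest.raises(ValueError):
        t.quantile(default_params, 1.5)
    with pytest.raises(ValueError):
        t.tihlbw_params(-1, 1, 1, 1)
    with pytest.raises(ValueError):
        t.tihlbw_params(1, 0, 1, 1)
    with pytest.raises(ValueError):
        t.Baseline("gompertz", (1.0,))
    with pytest.raises(ValueError):
        t.weibull(1.0, -2.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    lam=st.floats(0.3, 5), alpha=st.floats(0.3, 5),
    beta=st.floats(0.3, 5), delta=st.floats(0.3, 5),
    p=st.floats(1e-6, 1 - 1e-6),
)
def test_distribution_sanity_properties(lam, alpha, beta, delta, p):
    params = t.tihlbw_params(lam, alpha, beta, delta)
    x = float(t.quantile(params, p))
    assert x > 0
    assert abs(float(t.cdf(params, x)) - p) < 1e-9
    assert float(t.pdf(params, x)) >= 0
    assert float(t.hazard(params, x)) >= 0
    assert float(t.logsf(params, x)) <= 0
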