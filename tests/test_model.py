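"""Kinetic fitting, derived quantities and non-dimensional collapse."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from inflarec.model import (DEFAULT_TAU_GRID, PltFit, RecoveryFit, WbcFit,
                            adjusted_r2, fit_plt_growth, fit_wbc_decay,
                            half_life, mean_residence, nondimensionalize)


# ---------------------------------------------------------------------------
# Independent oracle: dense profile search over the decay rate, with the
# linear parameters (a, b) solved exactly by least squares at each rate.
# ---------------------------------------------------------------------------

def grid_oracle_wbc(t, y, c_grid=None):
    if c_grid is None:
        c_grid = np.linspace(0.05, 3.0, 1200)
    best = None
    for c in c_grid:
        X = np.column_stack([np.ones_like(t), np.exp(-c * t)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        ssr = float(np.sum((y - X @ coef) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, coef[0], coef[1], c)
    return best[1], best[2], best[3]


@pytest.mark.parametrize("a,b,c", [(7.0, 8.0, 0.75), (7.0, 8.0, 0.5)])
def test_fit_wbc_decay_recovers_noiseless(a, b, c):
    t = np.arange(0.0, 5.01, 0.5)
    y = a + b * np.exp(-c * t)
    fit = fit_wbc_decay(t, y, t_peak=0.0)
    assert fit.a == pytest.approx(a, rel=1e-6)
    assert fit.b == pytest.approx(b, rel=1e-6)
    assert fit.c == pytest.approx(c, rel=1e-6)
    assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)
    # independent dense-grid profile oracle agrees to its own resolution
    _, _, c_oracle = grid_oracle_wbc(t, y)
    assert abs(c_oracle - c) < 0.005


def test_fit_wbc_decay_constant_series_unidentifiable():
    t = np.arange(0.0, 5.01, 0.5)
    fit = fit_wbc_decay(t, np.full_like(t, 7.0), t_peak=0.0)
    assert fit.unidentifiable and fit.b == 0.0 and fit.a == 7.0
    assert np.isnan(fit.c)


def test_fit_wbc_decay_requires_four_points():
    with pytest.raises(ValueError):
        fit_wbc_decay([0.0, 1.0, 2.0], [10.0, 9.0, 8.0], t_peak=0.0)


def test_fit_wbc_decay_window_is_five_days():
    # points beyond t_peak + 5 d must not influence the fit
    t = np.arange(0.0, 9.01, 0.5)
    y = 7.0 + 8.0 * np.exp(-0.75 * t)
    y[t > 5.0] += 5.0  # corrupt out-of-window data
    fit = fit_wbc_decay(t, y, t_peak=0.0)
    assert fit.c == pytest.approx(0.75, rel=1e-6)


# ---------------------------------------------------------------------------
# PLT growth with lag
# ---------------------------------------------------------------------------

def test_fit_plt_growth_flat_then_linear():
    t = np.arange(0.0, 5.01, 0.25)
    y = np.where(t < 2.0, 150.0, 150.0 + 25.0 * (t - 2.0))
    fit = fit_plt_growth(t, y, t_peak=0.0)
    assert fit.tau == pytest.approx(2.0, abs=1e-9)
    assert fit.f == pytest.approx(25.0, rel=1e-9)


def test_fit_plt_growth_pure_linear_has_zero_lag():
    t = np.arange(0.0, 5.01, 0.5)
    fit = fit_plt_growth(t, 150.0 + 20.0 * t, t_peak=0.0)
    assert fit.tau == 0.0
    assert fit.f == pytest.approx(20.0, rel=1e-9)


def test_fit_plt_growth_constant_series_flagged():
    t = np.arange(0.0, 5.01, 0.5)
    fit = fit_plt_growth(t, np.full_like(t, 150.0), t_peak=0.0)
    assert fit.unidentifiable and fit.f == 0.0 and np.isnan(fit.adj_r2)


def test_fit_plt_growth_lag_identified_between_sparse_samples():
    # breakpoint at 2.0 falls between samples at 1.4 and 2.3; the refined lag
    # must land on the true value via the plateau/line intersection
    t = np.array([0.2, 0.8, 1.4, 2.3, 3.1, 3.9, 4.7])
    y = np.where(t < 2.0, 160.0, 160.0 + 18.0 * (t - 2.0))
    fit = fit_plt_growth(t, y, t_peak=0.0)
    assert fit.tau == pytest.approx(2.0, abs=1e-9)
    assert fit.f == pytest.approx(18.0, rel=1e-9)


def test_fit_plt_growth_insufficient_points():
    with pytest.raises(ValueError):
        fit_plt_growth([0.0, 1.0], [150.0, 160.0], t_peak=0.0)


# ---------------------------------------------------------------------------
# Adjusted R^2 and kinetic identities
# ---------------------------------------------------------------------------

def test_adjusted_r2_values():
    obs = np.arange(10.0)
    assert adjusted_r2(obs, obs, 3) == 1.0
    # predicting the mean: R^2 = 0 -> 1 - 9/7
    assert adjusted_r2(obs, np.full(10, obs.mean()), 2) == pytest.approx(-9 / 7 + 1)
    # construct R^2 = 0.9 with n = 11: SST = 110, SSR = 11
    obs = np.arange(11.0)
    pred = obs + np.ones(11)
    assert adjusted_r2(obs, pred, 3) == pytest.approx(1 - 0.1 * 10 / 7)


def test_adjusted_r2_small_n_raises():
    with pytest.raises(ValueError):
        adjusted_r2([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 2)


@settings(max_examples=50, deadline=None)
@given(st.integers(min_value=8, max_value=40), st.integers(min_value=1, max_value=4))
def test_adjusted_r2_monotone_in_n_params(n, p):
    rng = np.random.default_rng(n * 7 + p)
    obs = rng.normal(size=n)
    pred = obs + 0.3 * rng.normal(size=n)
    assert adjusted_r2(obs, pred, p + 1) <= adjusted_r2(obs, pred, p) + 1e-12


@settings(max_examples=100, deadline=None)
@given(st.floats(min_value=0.01, max_value=10.0, allow_nan=False))
def test_kinetic_identities(c):
    assert half_life(c) * c == pytest.approx(np.log(2.0), rel=1e-12)
    assert mean_residence(c) * c == pytest.approx(1.0, rel=1e-12)


def test_kinetic_quantities_reject_nonpositive_rate():
    for bad in (0.0, -1.0):
        with pytest.raises(ValueError):
            half_life(bad)
        with pytest.raises(ValueError):
            mean_residence(bad)


# ---------------------------------------------------------------------------
# Non-dimensionalization
# ---------------------------------------------------------------------------

def _exact_fit(a=7.0, b=8.0, c=0.8, d=140.0, f=20.0, tau=2.0, t_peak=1.0):
    return RecoveryFit("P", t_peak, WbcFit(a, b, c, 1.0), PltFit(d, f, tau, 1.0))


def test_nondimensionalize_exact_model_data():
    fit = _exact_fit()
    t = fit.t_peak + np.arange(0.0, 5.01, 0.25)
    wbc = fit.wbc.a + fit.wbc.b * np.exp(-fit.wbc.c * (t - fit.t_peak))
    plt_lag = fit.plt.d + fit.plt.f * fit.plt.tau
    plt = np.where(t - fit.t_peak < fit.plt.tau, plt_lag,
                   plt_lag + fit.plt.f * (t - fit.t_peak - fit.plt.tau))
    traj = nondimensionalize(fit, t, wbc, plt)
    assert traj.w[0] == pytest.approx(1.0, abs=1e-12)  # w = 1 at the peak
    np.testing.assert_allclose(traj.w, np.exp(-traj.t_star), atol=1e-12)
    k = fit.wbc.c
    on_line = traj.t_star >= fit.plt.tau * k
    np.testing.assert_allclose(traj.p[on_line],
                               traj.t_star[on_line] - fit.plt.tau * k, atol=1e-9)
    # p = 0 exactly at t* = tau * k
    assert np.interp(fit.plt.tau * k, traj.t_star, traj.p) == pytest.approx(0.0, abs=1e-9)
    # w = 1/e at t* = 1
    assert np.interp(1.0, traj.t_star, np.exp(-traj.t_star)) == pytest.approx(
        np.exp(-1.0), abs=1e-9)


def test_nondimensionalize_undefined_cases():
    t = np.arange(0.0, 5.01, 0.5)
    flat = RecoveryFit("P", 0.0, WbcFit(7.0, 0.0, 1.0, np.nan, True),
                       PltFit(150.0, 0.0, 0.0, np.nan, True))
    with pytest.raises(ValueError):
        nondimensionalize(flat, t, wbc=np.full_like(t, 7.0))
    with pytest.raises(ValueError):
        nondimensionalize(flat, t, plt=np.full_like(t, 150.0))
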