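"""Exponential-WBC / delayed-linear-PLT recovery kinetics.

The favorable acute inflammatory recovery is modeled, for times after the peak
WBC (``t_peak``), as

* WBC(t) = a + b * exp(-c * (t - t_peak)) — exponential decay from the peak
  toward the homeostatic setpoint ``a`` with rate ``c`` (day^-1); ``b``
  estimates WBC_max - WBC_setpoint;
* PLT(t) = d + f * (t - t_peak) for t >= t_peak + tau — linear growth with
  slope ``f`` (10^3/(uL*day)) starting a lag ``tau`` (~2 days) after the peak.

Both models are fit over the first 5 days after the peak. Non-dimensionalizing
with w = (WBC - a)/b, p = (PLT - PLT(t_peak + tau)) / (f/c) and
t* = (t - t_peak) * c collapses every recovery onto the universal curves
w(t*) = exp(-t*) and p(t*) = t* - tau*c.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .cohort import Cohort, PatientRecord, POST_PEAK_SPAN_DAYS, find_peak_wbc

logger = logging.getLogger("inflarec")

#: Multi-start initial decay rates (day^-1) guarding against local minima.
C_STARTS = (0.1, 0.3, 0.5, 0.75, 1.0, 1.5, 3.0)
C_BOUNDS = (0.01, 5.0)

#: Default lag search grid (days).
DEFAULT_TAU_GRID = np.arange(0.0, 4.0 + 1e-9, 0.25)

_TIE_TOL = 1e-9  # adjusted-R^2 improvements smaller than this are ties


@dataclass
class WbcFit:
    a: float  # WBC setpoint estimate, 10^3/uL
    b: float  # decay amplitude, 10^3/uL
    c: float  # decay rate, day^-1
    adj_r2: float
    unidentifiable: bool = False


@dataclass
class PltFit:
    d: float  # intercept at t_peak, 10^3/uL
    f: float  # growth slope, 10^3/(uL*day)
    tau: float  # growth lag after peak WBC, days
    adj_r2: float
    unidentifiable: bool = False


@dataclass
class RecoveryFit:
    """Combined per-patient kinetic fit with derived quantities."""

    patient_id: str
    t_peak: float
    wbc: WbcFit
    plt: PltFit

    @property
    def half_life_days(self) -> float:
        return half_life(self.wbc.c)

    @property
    def mean_residence_days(self) -> float:
        return mean_residence(self.wbc.c)


@dataclass
class DimensionlessTrajectory:
    """A recovery trajectory in the universal (t*, w, p) coordinates."""

    t_star: np.ndarray
    w: np.ndarray | None
    p: np.ndarray | None


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

def adjusted_r2(observed, predicted, n_params: int) -> float:
    """Adjusted R^2: 1 - (1 - R^2)(n - 1)/(n - n_params - 1).

    Returns NaN for a constant observed series (R^2 undefined); raises for
    n <= n_params + 1, where the penalty is undefined.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    n = observed.size
    if n <= n_params + 1:
        raise ValueError(f"adjusted R^2 needs n > n_params + 1 (n={n}, p={n_params})")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    r2 = 1.0 - float(np.sum((observed - predicted) ** 2)) / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def half_life(c: float) -> float:
    """WBC decay half-life ln(2)/c in days (c in day^-1)."""
    if c <= 0:
        raise ValueError("decay rate must be positive")
    return float(np.log(2.0) / c)


def mean_residence(c: float) -> float:
    """Mean circulation time 1/c (days) of excess WBCs removed at random."""
    if c <= 0:
        raise ValueError("decay rate must be positive")
    return float(1.0 / c)


# ---------------------------------------------------------------------------
# WBC fit
# ---------------------------------------------------------------------------

def fit_wbc_decay(times, wbc, t_peak: float, window: float = POST_PEAK_SPAN_DAYS) -> WbcFit:
    """Least-squares fit of a + b*exp(-c*(t - t_peak)) on the post-peak window.

    Multi-start over ``C_STARTS`` with a >= 0, b >= 0, c in [0.01, 5] day^-1;
    the best objective wins. A constant series is unidentifiable: returns
    a = mean, b = 0, c = NaN.
    """
    times = np.asarray(times, dtype=float)
    wbc = np.asarray(wbc, dtype=float)
    sel = (times >= t_peak - 1e-9) & (times <= t_peak + window + 1e-9)
    t = times[sel] - t_peak
    y = wbc[sel]
    if t.size < 4:
        raise ValueError(f"need >= 4 points in the fit window, got {t.size}")
    if np.ptp(y) == 0.0:
        return WbcFit(a=float(y.mean()), b=0.0, c=float("nan"),
                      adj_r2=float("nan"), unidentifiable=True)

    def _model(tt, a, b, c):
        return a + b * np.exp(-c * tt)

    best = None
    amp0 = max(float(np.ptp(y)), 1e-6)
    a0 = max(float(y.min()), 0.0)
    for c0 in C_STARTS:
        try:
            popt, _ = curve_fit(
                _model, t, y, p0=[a0, amp0, c0],
                bounds=([0.0, 0.0, C_BOUNDS[0]], [np.inf, np.inf, C_BOUNDS[1]]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12, maxfev=20000,
            )
        except RuntimeError:
            continue
        ssr = float(np.sum((y - _model(t, *popt)) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt)
    if best is None:
        raise RuntimeError("WBC decay fit failed to converge from every start")
    a, b, c = (float(v) for v in best[1])
    try:
        r2 = adjusted_r2(y, _model(t, a, b, c), 3)
    except ValueError:
        r2 = float("nan")
    return WbcFit(a=a, b=b, c=c, adj_r2=r2)


# ---------------------------------------------------------------------------
# PLT fit
# ---------------------------------------------------------------------------

def fit_plt_growth(times, plt, t_peak: float, tau_grid=None,
                   window: float = POST_PEAK_SPAN_DAYS) -> PltFit:
    """Fit delayed linear PLT growth d + f*(t - t_peak) for t >= t_peak + tau.

    For each candidate lag on ``tau_grid`` (default 0..4 d, step 0.25 d) the
    line is fit by ordinary least squares on points with t >= t_peak + tau
    (window ends at t_peak + 5 d); the lag maximizing adjusted R^2 wins, ties
    to the smallest lag. The winning lag is then refined to the intersection
    of the fitted line with the pre-lag plateau mean, clamped to the interval
    bracketed by the last plateau point and the first growth point — under
    sparse irregular sampling the grid alone only identifies the lag up to the
    sampling gap around the breakpoint.

    A zero-slope (constant) series is flagged unidentifiable with f = 0.
    """
    times = np.asarray(times, dtype=float)
    plt = np.asarray(plt, dtype=float)
    if tau_grid is None:
        tau_grid = DEFAULT_TAU_GRID
    tau_grid = np.sort(np.asarray(tau_grid, dtype=float))

    in_window = (times >= t_peak - 1e-9) & (times <= t_peak + window + 1e-9)
    t_all = times[in_window] - t_peak
    y_all = plt[in_window]
    if np.ptp(y_all) == 0.0 and y_all.size >= 2:
        return PltFit(d=float(y_all.mean()), f=0.0, tau=float(tau_grid[0]),
                      adj_r2=float("nan"), unidentifiable=True)

    best = None  # (adj_r2, tau, d, f)
    for tau in tau_grid:
        sel = t_all >= tau - 1e-9
        t = t_all[sel]
        y = y_all[sel]
        if t.size < 3:
            continue
        f, d = np.polyfit(t, y, 1)
        pred = d + f * t
        try:
            r2 = adjusted_r2(y, pred, 2)
        except ValueError:
            # minimal 3-point candidate: no residual dof for the adjustment;
            # score by plain R^2 so late lags are not silently skipped
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot else float("nan")
        if np.isnan(r2):
            continue
        if best is None or r2 > best[0] + _TIE_TOL:
            best = (r2, float(tau), float(d), float(f))
    if best is None:
        raise ValueError("insufficient points at every candidate lag")
    r2, tau, d, f = best

    tau = _refine_tau(t_all, y_all, tau, d, f)
    return PltFit(d=d, f=f, tau=tau, adj_r2=r2)


def _refine_tau(t_all, y_all, tau_grid_hat, d, f):
    """Refine the grid lag to the plateau/growth-line intersection.

    The breakpoint must lie between the last pre-lag sample and the first
    post-lag sample; the refined estimate is clamped to that interval.
    """
    pre = t_all < tau_grid_hat - 1e-9
    post = t_all >= tau_grid_hat - 1e-9
    if not pre.any() or not post.any() or abs(f) < 1e-12:
        return float(tau_grid_hat)
    plateau = float(y_all[pre].mean())
    tau_star = (plateau - d) / f
    lo = float(t_all[pre].max())
    hi = float(t_all[post].min())
    return float(np.clip(tau_star, max(lo, 0.0), hi))


# ---------------------------------------------------------------------------
# Non-dimensionalization
# ---------------------------------------------------------------------------

def nondimensionalize(fit: RecoveryFit, times, wbc=None, plt=None) -> DimensionlessTrajectory:
    """Map a post-peak trajectory onto the universal (t*, w, p) coordinates.

    w = (WBC - a)/b, p = (PLT - PLT(t_peak + tau)) / (f/c),
    t* = (t - t_peak) * c, defined for t >= t_peak. For exact model data
    w(t*) = exp(-t*) and p(t*) = t* - tau*c (t* >= tau*c).
    """
    times = np.asarray(times, dtype=float)
    sel = times >= fit.t_peak - 1e-9
    c = fit.wbc.c
    if not np.isfinite(c) or c <= 0:
        raise ValueError("non-dimensionalization requires a positive decay rate")
    t_star = (times[sel] - fit.t_peak) * c
    w = p = None
    if wbc is not None:
        if fit.wbc.b == 0:
            raise ValueError("w is undefined for zero decay amplitude (b = 0)")
        w = (np.asarray(wbc, dtype=float)[sel] - fit.wbc.a) / fit.wbc.b
    if plt is not None:
        if fit.plt.f == 0:
            raise ValueError("p is undefined for zero growth slope (f = 0)")
        plt_at_lag = fit.plt.d + fit.plt.f * fit.plt.tau
        p = (np.asarray(plt, dtype=float)[sel] - plt_at_lag) / (fit.plt.f / c)
    return DimensionlessTrajectory(t_star=t_star, w=w, p=p)


# ---------------------------------------------------------------------------
# Cohort-level convenience
# ---------------------------------------------------------------------------

def fit_patient(patient: PatientRecord, cohort_class: str,
                t_peak: float | None = None, tau_grid=None) -> RecoveryFit:
    """Fit both models for one patient, aligning at the (given or found) peak."""
    if t_peak is None:
        t_peak = find_peak_wbc(patient, cohort_class, mode="modeling")
    wbc = patient.get("WBC")
    plt = patient.get("PLT")
    wfit = fit_wbc_decay(wbc.times, wbc.values, t_peak)
    pfit = fit_plt_growth(plt.times, plt.values, t_peak, tau_grid=tau_grid)
    return RecoveryFit(patient_id=patient.patient_id, t_peak=t_peak, wbc=wfit, plt=pfit)


def fit_cohort(cohort: Cohort, tau_grid=None) -> pd.DataFrame:
    """Fit every patient; returns the per-patient fit table.

    Patients whose fit fails preconditions or is unidentifiable are flagged
    (and excluded from parameter summaries by callers); counts are logged.
    """
    rows = []
    n_failed = n_unident = 0
    for p in cohort.patients:
        try:
            fit = fit_patient(p, cohort.cohort_class, tau_grid=tau_grid)
        except (ValueError, KeyError, RuntimeError) as exc:
            n_failed += 1
            rows.append({"patient_id": p.patient_id, "flag": f"failed: {exc}"})
            continue
        flag = ""
        if fit.wbc.unidentifiable or fit.plt.unidentifiable:
            flag = "unidentifiable"
            n_unident += 1
        rows.append({
            "patient_id": p.patient_id, "t_peak": fit.t_peak,
            "a": fit.wbc.a, "b": fit.wbc.b, "c": fit.wbc.c,
            "d": fit.plt.d, "f": fit.plt.f, "tau": fit.plt.tau,
            "adj_r2_wbc": fit.wbc.adj_r2, "adj_r2_plt": fit.plt.adj_r2,
            "flag": flag,
        })
    if n_failed or n_unident:
        logger.info("fit_cohort: %d failed, %d unidentifiable of %d",
                    n_failed, n_unident, len(cohort))
    return pd.DataFrame(rows)
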