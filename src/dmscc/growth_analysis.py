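"""Colony growth mathematics for dMSCC experiments.

Growth is quantified on the pooled colony level: the natural logarithm of the
total segmented cell area per frame is piecewise linear in time, and its
slope is the specific growth rate in 1/h.  The module provides

* ordinary least-squares log-linear fits over closed-open time windows,
* the maximal specific growth rate ``mu_max`` as the steepest slope of any
  3 h window slid frame by frame after the onset of the dynamics,
* the initial growth rate ``mu_ini`` over the first hour after onset,
* the adaptation time as the intersection of the two regression lines,
  gated on ``mu_ini < mu_max`` and ``mu_ini / mu_max < 0.9``,
* normalisation against the constant-excess control, the time-weighted
  constant-condition baseline, and a Monod goodness-of-fit check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .chip_model import OscillationProfile

__all__ = [
    "GrowthSeries",
    "GrowthFit",
    "AdaptationResult",
    "MonodFit",
    "growth_series",
    "fit_log_linear",
    "mu_max_sliding",
    "mu_ini",
    "adaptation_time",
    "normalize_mu",
    "time_weighted_mu",
    "fit_monod",
]

logger = logging.getLogger(__name__)

_TOL = 1e-9


@dataclass
class GrowthSeries:
    """Total colony area and cell count per phase-contrast frame."""

    times: np.ndarray  # h, strictly increasing
    total_area: np.ndarray  # um^2
    cell_count: np.ndarray
    condition: object | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.total_area = np.asarray(self.total_area, dtype=float)
        self.cell_count = np.asarray(self.cell_count)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.total_area <= 0):
            raise ValueError("total_area must be positive at every frame")


@dataclass(frozen=True)
class GrowthFit:
    """A log-linear regression: slope is the specific growth rate (1/h)."""

    slope: float
    intercept: float
    window: tuple[float, float]
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a growth fit needs at least 3 points")


@dataclass(frozen=True)
class AdaptationResult:
    """Two-phase adaptation summary.

    ``t_adapt`` is the duration between the onset of the dynamics and the
    intersection of the mu_ini and mu_max regression lines.  The gate passes
    only when mu_ini < mu_max and mu_ini/mu_max < 0.9; otherwise the colony
    is considered not to show a resolvable adaptation phase and ``t_adapt``
    is reported as 0 with ``gate_passed=False``.
    """

    mu_ini: float
    mu_max: float
    t_adapt: float
    gate_passed: bool
    mu_ratio: float


@dataclass(frozen=True)
class MonodFit:
    mu_m: float
    Ks: float
    r_squared: float
    converged: bool = True


def growth_series(table: pd.DataFrame, condition=None) -> GrowthSeries:
    """Aggregate a pooled cell table into per-frame total area and count.

    Frames with no cells simply do not appear; frames whose total area is
    non-positive are dropped with a warning.
    """
    if "time_h" not in table.columns or "area_um2" not in table.columns:
        raise ValueError("cell table must contain 'time_h' and 'area_um2'")
    grouped = table.groupby("time_h")["area_um2"].agg(["sum", "size"]).sort_index()
    bad = grouped["sum"] <= 0
    if bad.any():
        logger.warning("dropping %d frames with non-positive total area", int(bad.sum()))
        grouped = grouped[~bad]
    if grouped.empty:
        raise ValueError("no usable frames in cell table")
    return GrowthSeries(
        times=grouped.index.to_numpy(dtype=float),
        total_area=grouped["sum"].to_numpy(),
        cell_count=grouped["size"].to_numpy(),
        condition=condition,
    )


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    return (times >= t0 - _TOL) & (times < t1 - _TOL)


def fit_log_linear(
    series: GrowthSeries, window: tuple[float, float], signal: str = "area"
) -> GrowthFit:
    """OLS fit of ln(total area) (or ln(cell count)) versus time over the
    closed-open window [t0, t1)."""
    y_raw = series.total_area if signal == "area" else series.cell_count.astype(float)
    mask = _window_mask(series.times, window)
    if int(mask.sum()) < 3:
        raise ValueError(
            f"insufficient data: {int(mask.sum())} frames in window {window}, need >= 3"
        )
    t = series.times[mask]
    y = np.log(y_raw[mask])
    res = stats.linregress(t, y)
    # a perfectly flat series has zero variance in y: define R^2 = 1 (exact fit)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot < 1e-300:
        r2 = 1.0
    else:
        r2 = float(res.rvalue**2)
    return GrowthFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        window=(float(window[0]), float(window[1])),
        r_squared=min(max(r2, 0.0), 1.0),
        n_points=int(mask.sum()),
    )


def mu_max_sliding(
    series: GrowthSeries,
    t_onset: float,
    window_h: float = 3.0,
    frame_step: int = 1,
    signal: str = "area",
) -> GrowthFit:
    """Maximal specific growth rate after onset.

    A window of ``window_h`` hours is slid frame by frame over all start
    frames at or after ``t_onset`` for which the window is complete; the fit
    with the maximal slope is returned (earliest window on ties).
    """
    t_end = series.times[-1]
    starts = series.times[
        (series.times >= t_onset - _TOL) & (series.times + window_h <= t_end + _TOL)
    ][::frame_step]
    best: GrowthFit | None = None
    for t0 in starts:
        try:
            fit = fit_log_linear(series, (t0, t0 + window_h), signal=signal)
        except ValueError:
            continue
        if best is None or fit.slope > best.slope + _TOL:
            best = fit
    if best is None:
        raise ValueError(
            f"insufficient data: no complete {window_h} h window after t={t_onset} h"
        )
    return best


def mu_ini(
    series: GrowthSeries, t_onset: float, window_h: float = 1.0, signal: str = "area"
) -> GrowthFit:
    """Initial growth rate: single fixed window [t_onset, t_onset + window_h)."""
    return fit_log_linear(series, (t_onset, t_onset + window_h), signal=signal)


def adaptation_time(
    fit_ini: GrowthFit,
    fit_max: GrowthFit,
    t_onset: float,
    ratio_gate: float = 0.9,
    slope_tol: float = 1e-9,
) -> AdaptationResult:
    """Adaptation duration from the intersection of the two regression lines.

    t* = (b_ini - b_max) / (s_max - s_ini); the reported duration is
    t* - t_onset.  The gate fails (duration 0) when the slopes are equal
    within tolerance, when mu_ini/mu_max >= ratio_gate, or when the
    intersection falls before the onset.
    """
    s_i, s_m = fit_ini.slope, fit_max.slope
    mu_ratio = s_i / s_m if abs(s_m) > 0 else np.inf
    gate = s_i < s_m and mu_ratio < ratio_gate and (s_m - s_i) > slope_tol
    if not gate:
        return AdaptationResult(s_i, s_m, 0.0, False, mu_ratio)
    t_star = (fit_ini.intercept - fit_max.intercept) / (s_m - s_i)
    t_adapt = t_star - t_onset
    if t_adapt < 0:
        return AdaptationResult(s_i, s_m, 0.0, False, mu_ratio)
    return AdaptationResult(s_i, s_m, float(t_adapt), True, mu_ratio)


def normalize_mu(mu: float, mu_excess_control: float) -> float:
    """Growth rate relative to the constant-excess control of the same run."""
    if mu_excess_control <= 0:
        raise ValueError("excess-control growth rate must be positive")
    return mu / mu_excess_control


def time_weighted_mu(
    mu_excess_ctrl: float, mu_limitation_ctrl: float, profile: OscillationProfile
) -> float:
    """Duty-cycle-weighted average of the two constant-condition growth
    rates: the naive baseline the dynamic colonies are compared against."""
    f = profile.duty_cycle
    return f * mu_excess_ctrl + (1.0 - f) * mu_limitation_ctrl


def fit_monod(points) -> MonodFit:
    """Nonlinear least squares of mu = mu_m * S / (Ks + S).

    ``points`` is an iterable of (S_eff, mu) pairs; S_eff is the
    duty-cycle-weighted mean glucose concentration of the condition.  The
    reported R^2 measures how well a concentration-only Monod model explains
    the dose-response (the point of this fit is usually that it does not).
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (S_eff, mu) points")
    S, mu = pts[:, 0], pts[:, 1]
    if len(np.unique(S)) < 3:
        raise ValueError("need at least 3 distinct S_eff values")

    def monod(s, mu_m, ks):
        return mu_m * s / (ks + s)

    try:
        popt, _ = optimize.curve_fit(
            monod,
            S,
            mu,
            p0=(float(mu.max()), float(np.median(S))),
            bounds=([0.0, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError:
        logger.warning("Monod fit did not converge")
        return MonodFit(np.nan, np.nan, np.nan, converged=False)
    pred = monod(S, *popt)
    ss_res = float(np.sum((mu - pred) ** 2))
    ss_tot = float(np.sum((mu - mu.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return MonodFit(mu_m=float(popt[0]), Ks=float(popt[1]), r_squared=r2)
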