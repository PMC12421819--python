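"""Growth and uptake parameter estimation from time series.

mu is the slope of a linear regression of ln(OD600) against time over an
automatically selected exponential window (maximal-length sliding window
with r^2 >= 0.99); DT = ln(2)/mu.  Specific uptake rates follow
q_S = (1/X) * (dS/dt) with X the centered-average biomass between
sampling points, and the regression-based aggregate divides mu by the
slope of biomass against substrate concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GrowthFit",
    "RateEstimate",
    "YieldEstimate",
    "fit_growth",
    "estimate_uptake",
    "estimate_yield",
    "DEFAULT_OD_TO_CDW",
]

LN2 = float(np.log(2.0))

# Strain-specific OD600 -> gCDW/L correlation factor; package default,
# must be calibrated per strain for absolute rates.
DEFAULT_OD_TO_CDW = 0.4


@dataclass
class GrowthFit:
    mu: float  # h^-1
    DT: float  # h, always ln(2)/mu
    window: tuple[float, float]
    r_squared: float
    od_to_cdw: float = DEFAULT_OD_TO_CDW
    n_points: int = 0


@dataclass
class RateEstimate:
    q_S: float  # mmol gCDW^-1 h^-1 (aggregate, regression-based)
    per_interval: list[float] = field(default_factory=list)
    X: float = float("nan")  # mean biomass over the window, gCDW/L
    delta_S: float = float("nan")  # total substrate change, mM
    delta_t: float = float("nan")  # h


@dataclass
class YieldEstimate:
    Y_XS: float  # gCDW per mol substrate
    basis: str = ""
    delta_X: float = float("nan")  # gCDW/L
    delta_S: float = float("nan")  # mM


class NoExponentialWindowError(ValueError):
    pass


def _window_fit(t: np.ndarray, ln_od: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(t, ln_od)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def _range_window(od: np.ndarray, lo_factor: float, hi_factor: float) -> np.ndarray:
    """Mask of points inside the exponential range of the curve.

    Lag points sit near the initial OD and stationary points near the
    final OD; keeping only ODs in (lo_factor * OD_start,
    hi_factor * OD_end) isolates the exponential stretch without relying
    on a noise-sensitive r^2 sweep.
    """
    od0 = float(np.median(od[:3]))
    od_end = max(float(np.median(od[-3:])), float(od.max()) * 0.99)
    return (od >= lo_factor * od0) & (od <= hi_factor * od_end)


def fit_growth(time_h, od600,
               window_policy: str = "range",
               r2_threshold: float = 0.99,
               min_points: int = 4,
               detection_limit: float = 0.01,
               od_to_cdw: float = DEFAULT_OD_TO_CDW) -> GrowthFit:
    """Regress ln(OD) on time over the detected exponential window.

    ``window_policy="range"`` (default) trims lag and stationary points
    by OD thresholds relative to the curve's start and end levels;
    ``"max_r2"`` picks the maximal-length sliding window with
    r^2 >= ``r2_threshold``.  The range policy recovers noiseless
    exponentials exactly, which the r^2 sweep does not (it happily
    absorbs a few lag/stationary points into a long window).
    """
    t = np.asarray(time_h, dtype=float)
    od = np.asarray(od600, dtype=float)
    if t.shape != od.shape or t.ndim != 1:
        raise ValueError("time and OD series must be 1-D and aligned")
    keep = od > detection_limit
    t, od = t[keep], od[keep]
    if len(t) < min_points:
        raise NoExponentialWindowError(
            f"only {len(t)} points above the detection limit")
    ln_od = np.log(od)
    n = len(t)

    if window_policy == "range":
        mask = _range_window(od, lo_factor=1.25, hi_factor=0.75)
        if mask.sum() < min_points:
            raise NoExponentialWindowError(
                "no exponential window: fewer than "
                f"{min_points} points between the lag and stationary levels")
        slope, _icpt, r2 = _window_fit(t[mask], ln_od[mask])
        if slope <= 0:
            raise NoExponentialWindowError("selected window has no growth")
        tw = t[mask]
        return GrowthFit(mu=slope, DT=LN2 / slope,
                         window=(float(tw[0]), float(tw[-1])),
                         r_squared=r2, od_to_cdw=od_to_cdw,
                         n_points=int(mask.sum()))

    if window_policy != "max_r2":
        raise ValueError(f"unknown window policy {window_policy!r}")
    best: tuple[int, int] | None = None
    best_fit: tuple[float, float, float] | None = None
    for length in range(n, min_points - 1, -1):
        for start in range(0, n - length + 1):
            sl = slice(start, start + length)
            slope, icpt, r2 = _window_fit(t[sl], ln_od[sl])
            if r2 >= r2_threshold and slope > 0:
                if best is None or (best_fit is not None and slope > best_fit[0]):
                    best = (start, start + length)
                    best_fit = (slope, icpt, r2)
        if best is not None:
            break
    if best is None or best_fit is None:
        raise NoExponentialWindowError(
            f"no window of >= {min_points} points reaches r^2 >= {r2_threshold}")
    slope, _icpt, r2 = best_fit
    return GrowthFit(mu=slope, DT=LN2 / slope,
                     window=(float(t[best[0]]), float(t[best[1] - 1])),
                     r_squared=r2, od_to_cdw=od_to_cdw,
                     n_points=best[1] - best[0])


def estimate_uptake(time_h, biomass_gL, substrate_mM,
                    mu: float | None = None) -> RateEstimate:
    """Specific substrate consumption rate from aligned series.

    ``biomass_gL`` is in gCDW/L (convert OD with the od_to_cdw factor
    first), ``substrate_mM`` in mM.  Returns per-interval rates plus a
    regression aggregate: mu divided by the slope of biomass vs
    substrate when ``mu`` is given, otherwise the biomass-weighted mean
    of the interval rates.
    """
    t = np.asarray(time_h, dtype=float)
    X = np.asarray(biomass_gL, dtype=float)
    S = np.asarray(substrate_mM, dtype=float)
    if not (t.shape == X.shape == S.shape) or t.ndim != 1 or len(t) < 2:
        raise ValueError("series must be 1-D, aligned and have >= 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    if np.any(X <= 0):
        raise ValueError("biomass must be positive throughout")

    per_interval: list[float] = []
    for k in range(len(t) - 1):
        dt = t[k + 1] - t[k]
        dS = S[k] - S[k + 1]  # consumption positive
        Xbar = 0.5 * (X[k] + X[k + 1])
        per_interval.append(float(dS / dt / Xbar))

    dS_tot = float(S[0] - S[-1])
    if mu is not None:
        slope = float(stats.linregress(S, X).slope)  # gCDW/L per mM
        if slope == 0:
            raise ValueError("biomass does not vary with substrate")
        q = mu / (-slope)  # substrate falls as biomass rises
    else:
        w = 0.5 * (X[:-1] + X[1:]) * np.diff(t)
        q = float(np.sum(np.asarray(per_interval) * w) / np.sum(w))
    if q < 0:
        warnings.warn("substrate concentration increases over time; "
                      "q_S reported negative", stacklevel=2)
    return RateEstimate(q_S=q, per_interval=per_interval,
                        X=float(np.mean(X)), delta_S=dS_tot,
                        delta_t=float(t[-1] - t[0]))


def estimate_yield(biomass_gL, substrate_mM, basis: str = "") -> YieldEstimate:
    """Biomass yield Y_X/S = dX / dS (gCDW per mol substrate)."""
    X = np.asarray(biomass_gL, dtype=float)
    S = np.asarray(substrate_mM, dtype=float)
    if X.shape != S.shape or X.ndim != 1 or len(X) < 2:
        raise ValueError("series must be 1-D, aligned and have >= 2 points")
    dX = float(X[-1] - X[0])
    dS = float(S[0] - S[-1])
    if dS <= 0:
        raise ValueError("no substrate was consumed")
    y = dX / (dS / 1000.0)  # mM -> mol/L
    return YieldEstimate(Y_XS=max(0.0, y), basis=basis, delta_X=dX, delta_S=dS)
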