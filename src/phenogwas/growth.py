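"""Growth-curve fitness: smoothing, maximum slope, doubling time, hit calling.

Curves are uniformly sampled OD time series. Smoothing is a median filter of
window 5 followed by a Gaussian filter with sigma = 3 samples (reflective
boundaries, kernel truncated at 4 sigma). The fitness read-out is the maximum
slope over all contiguous ordinary-least-squares line fits of a fixed window
(12 timepoints by default; 24 for 15-min-interval nitrogen screens).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

DEFAULT_WINDOW = 12
MIN_GROWTH = 0.015  # exclusion threshold for the strain-comparison screen
HIT_CUT = 0.75  # |log2(slope_A / slope_T)| above this flags a hit


@dataclass
class SlopeFit:
    """Best-window OLS line over a smoothed growth curve."""

    slope: float  # OD per hour
    intercept: float
    window_start: int  # index of the first point of the winning window
    window: int
    r_squared: float
    interval_h: float  # sampling interval the per-hour slope is based on


def smooth(od: np.ndarray, median_size: int = 5, sigma: float = 3.0) -> np.ndarray:
    """Median filter then Gaussian filter, in that order; length unchanged."""
    od = np.asarray(od, dtype=float)
    if od.size < median_size:
        raise ValueError(f"need at least {median_size} points to smooth")
    med = ndimage.median_filter(od, size=median_size, mode="reflect")
    return ndimage.gaussian_filter1d(med, sigma=sigma, mode="reflect", truncate=4.0)


def _window_ols(y: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slope, intercept and R^2 of the OLS line in every contiguous window.

    x is the sample index 0..window-1; vectorized over windows via sliding
    windows and the closed-form simple-regression formulas.
    """
    x = np.arange(window, dtype=float)
    x_mean = x.mean()
    x_var = ((x - x_mean) ** 2).sum()
    windows = np.lib.stride_tricks.sliding_window_view(y, window)
    y_mean = windows.mean(axis=1)
    cov = ((x - x_mean) * (windows - y_mean[:, None])).sum(axis=1)
    slopes = cov / x_var
    intercepts = y_mean - slopes * x_mean
    ss_res = ((windows - intercepts[:, None] - slopes[:, None] * x) ** 2).sum(axis=1)
    ss_tot = ((windows - y_mean[:, None]) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    return slopes, intercepts, r2


def max_slope(
    od: np.ndarray,
    interval_h: float,
    window: int = DEFAULT_WINDOW,
    presmoothed: bool = False,
) -> SlopeFit:
    """Maximum-slope fitness of one well.

    Fits an OLS line to every contiguous ``window``-point stretch of the
    (smoothed) curve and returns the fit with the largest slope, converted to
    OD per hour.
    """
    od = np.asarray(od, dtype=float)
    if od.size < window:
        raise ValueError(f"curve has {od.size} points, window needs {window}")
    y = od if presmoothed else smooth(od)
    slopes, intercepts, r2 = _window_ols(y, window)
    best = int(np.argmax(slopes))
    return SlopeFit(
        slope=float(slopes[best] / interval_h),
        intercept=float(intercepts[best]),
        window_start=best,
        window=window,
        r_squared=float(r2[best]),
        interval_h=interval_h,
    )


def fit_plate(
    curves: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    time_col: str = "time",
    od_col: str = "od",
    well_col: str = "well",
) -> pd.DataFrame:
    """Max-slope fits for every well of a long-format curve table."""
    records = []
    for well, group in curves.groupby(well_col, sort=True):
        group = group.sort_values(time_col)
        t = group[time_col].to_numpy(float)
        interval = float(np.median(np.diff(t)))
        fit = max_slope(group[od_col].to_numpy(), interval_h=interval, window=window)
        records.append(
            dict(
                well=well,
                slope=fit.slope,
                intercept=fit.intercept,
                window_start=fit.window_start,
                window=fit.window,
                r_squared=fit.r_squared,
                interval_h=fit.interval_h,
            )
        )
    return pd.DataFrame.from_records(records)


def doubling_time(times_h: np.ndarray, od: np.ndarray) -> float:
    """Doubling time in hours from an exponential-phase window.

    OLS on log2(OD) versus time; the doubling time is the inverse of the
    slope. Returns inf (non-growing) when the slope is not positive.
    """
    od = np.asarray(od, dtype=float)
    times_h = np.asarray(times_h, dtype=float)
    if np.any(od <= 0):
        raise ValueError("doubling time needs strictly positive OD values")
    slope = np.polyfit(times_h, np.log2(od), 1)[0]
    if slope <= 0:
        return float("inf")
    return 1.0 / slope


def compare_conditions(
    slopes_a: pd.DataFrame,
    slopes_t: pd.DataFrame,
    min_growth: float = MIN_GROWTH,
    hit_cut: float = HIT_CUT,
    condition_col: str = "condition",
    slope_col: str = "slope",
) -> pd.DataFrame:
    """Differential growth between two strains across conditions.

    Input tables hold replicate max slopes per condition for each strain.
    Conditions where both strains' maximum slope is below ``min_growth``
    (same unit as the slopes) are excluded; otherwise the log2 ratio of mean
    slopes A/T is computed and |log2 ratio| > ``hit_cut`` flags a hit.
    Conditions whose mean slope is non-positive after the exclusion rule are
    excluded too (the ratio is undefined).
    """
    a = slopes_a.groupby(condition_col)[slope_col].agg(["mean", "max"])
    t = slopes_t.groupby(condition_col)[slope_col].agg(["mean", "max"])
    merged = a.join(t, how="inner", lsuffix="_A", rsuffix="_T")
    records = []
    for condition, rec in merged.iterrows():
        excluded = bool(rec["max_A"] < min_growth and rec["max_T"] < min_growth)
        reason = "no-growth-both-strains" if excluded else ""
        log2_ratio = np.nan
        if not excluded and (rec["mean_A"] <= 0 or rec["mean_T"] <= 0):
            excluded, reason = True, "non-positive-mean-slope"
        if not excluded:
            log2_ratio = float(np.log2(rec["mean_A"] / rec["mean_T"]))
        records.append(
            dict(
                condition=condition,
                slope_A=float(rec["mean_A"]),
                slope_T=float(rec["mean_T"]),
                log2_ratio=log2_ratio,
                excluded=excluded,
                reason=reason,
                hit=bool(not excluded and abs(log2_ratio) > hit_cut),
            )
        )
    return pd.DataFrame.from_records(records)
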