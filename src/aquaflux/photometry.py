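"""Photometry detrending: remove the photobleaching tendency by line
fitting and quantify injection-locked level change and oscillation range.

The trend is a least-squares line fitted on pre-injection data only and
extrapolated over the whole recording; residuals carry the biology.  The
"oscillation range" of a window is the 5th-to-95th percentile span of the
mean-removed residuals (robust to isolated spikes); SD and peak-to-peak
variants are selectable.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import TimeSeries

__all__ = ["PhotometryMetrics", "fit_linear_trend", "detrended_metrics"]

RangeMethod = Literal["percentile", "sd", "peak_to_peak"]


@dataclass(frozen=True)
class PhotometryMetrics:
    """Trend fit plus injection-referenced residual summaries."""

    slope_per_s: float
    intercept: float
    level_change_frac: float        # mean post residual / trend level at injection
    oscillation_range_pre: float
    oscillation_range_post: float
    pre_window: tuple[float, float]
    post_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.oscillation_range_pre < 0 or self.oscillation_range_post < 0:
            raise ValueError("oscillation ranges must be >= 0")
        if self.pre_window[1] > self.post_window[0] + 1e-9:
            raise ValueError("pre window must end before the post window begins")


def fit_linear_trend(
    trace: TimeSeries,
    window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Least-squares line over ``window`` (default: whole trace).

    Returns (slope units/s, intercept at t = 0 absolute time).
    """
    if window is None:
        window = (trace.t0, trace.t0 + trace.duration)
    sl = trace.window_slice(*window)
    if sl.stop - sl.start < 10:
        raise ValueError("trend window must contain >= 10 samples")
    t = trace.times[sl]
    if np.ptp(t) == 0:
        raise ValueError("degenerate trend window")
    slope, intercept = np.polyfit(t, trace.values[sl], 1)
    return float(slope), float(intercept)


def _window_range(r: np.ndarray, method: RangeMethod) -> float:
    r = r - r.mean()
    if method == "percentile":
        return float(np.percentile(r, 95) - np.percentile(r, 5))
    if method == "sd":
        return float(r.std(ddof=1))
    if method == "peak_to_peak":
        return float(np.ptp(r))
    raise ValueError(f"unknown range method {method!r}")


def detrended_metrics(
    trace: TimeSeries,
    trend: tuple[float, float],
    t_inject_s: float,
    pre_window_s: float | None = None,
    post_window_s: float | None = None,
    range_method: RangeMethod = "percentile",
    settle_s: float = 0.0,
) -> PhotometryMetrics:
    """Residual-based metrics around an injection.

    ``trend`` is (slope, intercept) from :func:`fit_linear_trend`, fitted on
    pre-injection data.  ``pre_window_s``/``post_window_s`` are window
    durations adjacent to the injection (default: the full pre and post
    segments).  ``settle_s`` delays the start of the post window past the
    injection so that the pharmacokinetic level transition does not leak
    into the oscillation-range estimate; with it the level change also
    reads the settled plateau rather than the ramp average.  The level
    change is the mean post-window residual as a fraction of the trend
    value at the injection time.
    """
    if settle_s < 0:
        raise ValueError("settle_s must be >= 0")
    slope, intercept = trend
    t_end = trace.t0 + trace.duration
    pre = (trace.t0 if pre_window_s is None else t_inject_s - pre_window_s, t_inject_s)
    post_start = t_inject_s + settle_s
    post = (post_start, t_end if post_window_s is None else post_start + post_window_s)
    if post[1] > t_end + 1e-9:
        post = (post[0], t_end)
    residual = trace.values - (intercept + slope * trace.times)
    sl_pre = trace.window_slice(pre[0], pre[1] - trace.dt / 2)  # pre excludes t_inject
    sl_post = trace.window_slice(*post)
    if sl_post.stop - sl_post.start < 2:
        raise ValueError("post window is empty")
    trend_at_inject = intercept + slope * t_inject_s
    if trend_at_inject == 0:
        raise ValueError("trend level at injection is zero; level change undefined")
    return PhotometryMetrics(
        slope_per_s=slope,
        intercept=intercept,
        level_change_frac=float(residual[sl_post].mean() / trend_at_inject),
        oscillation_range_pre=_window_range(residual[sl_pre], range_method),
        oscillation_range_post=_window_range(residual[sl_post], range_method),
        pre_window=pre,
        post_window=post,
    )
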