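"""Ca²⁺ signal-strength statistic and a simplified active-region detector.

The signal strength of a Ca²⁺ trace is the temporal integral of dF/F0 over
an analysis window, normalised per minute (units: dF/F0·s per minute),
with F0 taken as the mean of the lowest 20 samples of the trace.  The
integral is signed by default; rectification is available but off, since
the statistic is defined as a plain temporal integral.

The active-ROI detector here is a deliberately simplified stand-in for
dedicated spatiotemporal event-screening methods: per-pixel dF/F0
thresholding at k·(robust noise) sustained over >= 3 consecutive frames,
followed by 8-connected component grouping.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ImageStack, RoiSpec, TimeSeries
from .fit_imaging import DffTrace

__all__ = [
    "CaSignalStrength",
    "f0_lowest_n",
    "signal_strength_per_minute",
    "detect_active_rois",
]


@dataclass(frozen=True)
class CaSignalStrength:
    """Temporal-integral statistic: dF/F0·s per minute over a window."""

    value: float
    window: tuple[float, float]
    F0: float

    def __post_init__(self) -> None:
        if not self.window[1] > self.window[0]:
            raise ValueError("window length must be > 0")
        if not np.isfinite(self.value):
            raise ValueError("signal strength must be finite")


def f0_lowest_n(trace: TimeSeries, n: int = 20) -> float:
    """Baseline F0 as the mean of the ``n`` smallest samples."""
    if n < 1 or n > len(trace):
        raise ValueError(f"n must be in [1, {len(trace)}]")
    return float(np.sort(trace.values)[:n].mean())


def signal_strength_per_minute(
    dff: DffTrace,
    window: tuple[float, float] | None = None,
    rectify: bool = False,
) -> CaSignalStrength:
    """Trapezoidal integral of dF/F0 over the window, per minute."""
    trace = dff.series
    if window is None:
        window = (trace.t0, trace.t0 + trace.duration)
    sl = trace.window_slice(*window)
    if sl.stop - sl.start < 2:
        raise ValueError("window must contain >= 2 samples")
    v = trace.values[sl]
    if rectify:
        v = np.abs(v)
    integral = float(np.trapezoid(v, dx=trace.dt))  # dF/F0 · s
    minutes = (sl.stop - sl.start - 1) * trace.dt / 60.0
    return CaSignalStrength(value=integral / minutes, window=window, F0=dff.F0)


def detect_active_rois(
    stack: ImageStack,
    min_area_um2: float = 25.0,
    k_sigma: float = 3.0,
    min_consec: int = 3,
    f0_n: int = 20,
) -> list[RoiSpec]:
    """Simplified active-region detector on an event-bearing stack.

    Per pixel: F0 = lowest-``f0_n`` mean over time, dF/F0 computed, robust
    noise = 1.4826·MAD; pixels exceeding ``k_sigma``·noise for at least
    ``min_consec`` consecutive frames are flagged, grouped by
    8-connectivity, and components of at least ``min_area_um2`` become ROIs
    centred at the component centroid with the equivalent-circle diameter.
    An empty list is a valid result.
    """
    if stack.n_frames < 30:
        raise ValueError("need >= 30 frames for baseline estimation")
    data = stack.data.astype(float)
    f0 = np.sort(data, axis=0)[:f0_n].mean(axis=0)
    f0 = np.maximum(f0, 1e-12)
    dff = (data - f0) / f0
    med = np.median(dff, axis=0)
    noise = 1.4826 * np.median(np.abs(dff - med), axis=0)
    noise = np.maximum(noise, 1e-12)
    hot = dff > k_sigma * noise
    # sustained for >= min_consec consecutive frames
    sustained = np.zeros(stack.shape_rc, dtype=bool)
    run = np.zeros(stack.shape_rc, dtype=int)
    for k in range(stack.n_frames):
        run = np.where(hot[k], run + 1, 0)
        sustained |= run >= min_consec
    labels, n_comp = ndimage.label(sustained, structure=np.ones((3, 3), dtype=int))
    rois: list[RoiSpec] = []
    px_area = stack.pixel_size_um**2
    for lab in range(1, n_comp + 1):
        m = labels == lab
        area = m.sum() * px_area
        if area < min_area_um2:
            continue
        r0, c0 = ndimage.center_of_mass(m)
        rois.append(RoiSpec(center_rc=(r0, c0), diameter_um=2.0 * np.sqrt(area / np.pi)))
    return rois
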