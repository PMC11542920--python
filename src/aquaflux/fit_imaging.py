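"""Fluorescence-intensity-translated (FIT) quantification.

From a raw SRB time-lapse stack to background-corrected dF/F0 traces and
evoked-response kinetics.  Because the dye amount per astrocyte is fixed,
fluorescence collected from a fixed field of view tracks 1/volume: swelling
(water inflow) dims the cell, shrinking (water outflow) brightens it.

Conventions taken from the measurement protocol this reimplements:
background is the mean of peripheral cell-free 15x15 µm² subregions; ROIs
are 50 µm discs around astrocyte footprints; F0 is the mean of the 10
samples immediately preceding the detected fluorescence change.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .core import ImageStack, RoiSpec, TimeSeries, round_half_up

__all__ = [
    "DffTrace",
    "ResponseMetrics",
    "SlopePair",
    "estimate_background",
    "extract_roi_trace",
    "detect_onset",
    "compute_f0_pre_onset",
    "to_dff",
    "pre_post_slopes",
    "response_metrics",
]

Direction = Literal["up", "down", "either"]


@dataclass(frozen=True)
class DffTrace:
    """Normalised fluorescence trace dF/F0 = (F − background − F0)/F0."""

    series: TimeSeries
    F0: float
    roi: RoiSpec | None = None
    background: float | np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.F0 > 0:
            raise ValueError("F0 must be > 0")


@dataclass(frozen=True)
class ResponseMetrics:
    """Evoked-response kinetics, all referenced to the stimulus time."""

    start_time_s: float     # delay stimulus → detected change
    time_to_peak_s: float   # stimulus → extremum
    amplitude: float        # |dF/F0| at the extremum
    direction: Literal["up", "down"]

    def __post_init__(self) -> None:
        if not 0 <= self.start_time_s <= self.time_to_peak_s:
            raise ValueError("need 0 <= start_time <= time_to_peak")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class SlopePair:
    """Least-squares slopes before/after an event (units per second)."""

    slope_pre: float
    slope_post: float
    pre_window: tuple[float, float]
    post_window: tuple[float, float]
    delta_pre: float = float("nan")   # net change over the pre window
    delta_post: float = float("nan")  # net change over the post window

    def __post_init__(self) -> None:
        if self.pre_window[1] > self.post_window[0] + 1e-9:
            raise ValueError("pre window must end at or before the post window starts")


def _tile_positions(n: int, tile: int) -> list[int]:
    """Non-overlapping tile start offsets covering [0, n)."""
    return list(range(0, n - tile + 1, tile))


def estimate_background(
    stack: ImageStack,
    regions: Sequence[RoiSpec] | Literal["auto"] = "auto",
    subregion_um: float = 15.0,
    k_tiles: int = 4,
    cell_rois: Sequence[RoiSpec] | None = None,
) -> np.ndarray:
    """Per-frame background from cell-free subregions.

    ``regions="auto"`` selects the ``k_tiles`` darkest (by temporal-mean
    intensity) ``subregion_um``-sided square tiles from the border band of
    the field — one tile deep along each edge — mimicking the manual choice
    of peripheral cell-free subregions.  Explicit ``regions`` override the
    automatic choice and are validated against ``cell_rois`` for overlap.
    """
    n_r, n_c = stack.shape_rc
    tile = max(round_half_up(subregion_um / stack.pixel_size_um), 1)
    if tile > min(n_r, n_c):
        raise ValueError("field smaller than one background subregion")

    if regions == "auto":
        tmean = stack.data.mean(axis=0)
        candidates: list[tuple[float, np.ndarray]] = []
        seen: set[tuple[int, int]] = set()
        row_starts = _tile_positions(n_r, tile)
        col_starts = _tile_positions(n_c, tile)
        border_rows = {row_starts[0], row_starts[-1]}
        border_cols = {col_starts[0], col_starts[-1]}
        for r in row_starts:
            for c in col_starts:
                if r not in border_rows and c not in border_cols:
                    continue  # border band only
                if (r, c) in seen:
                    continue
                seen.add((r, c))
                m = np.zeros((n_r, n_c), dtype=bool)
                m[r : r + tile, c : c + tile] = True
                candidates.append((float(tmean[m].mean()), m))
        candidates.sort(key=lambda x: x[0])
        if not candidates:
            raise ValueError("no candidate background tiles in the border band")
        masks = [m for _, m in candidates[: max(k_tiles, 1)]]
        union = np.any(masks, axis=0)
    else:
        if len(regions) == 0:
            raise ValueError("need at least one background region")
        union = np.zeros((n_r, n_c), dtype=bool)
        for reg in regions:
            union |= reg.mask((n_r, n_c), stack.pixel_size_um)
        if cell_rois:
            for roi in cell_rois:
                if (union & roi.mask((n_r, n_c), stack.pixel_size_um)).any():
                    raise ValueError("background region overlaps a cell ROI")
    return stack.data[:, union].mean(axis=1)


def extract_roi_trace(
    stack: ImageStack,
    roi: RoiSpec,
    background: float | np.ndarray = 0.0,
) -> TimeSeries:
    """Background-subtracted mean-intensity trace of one ROI (floored at 0)."""
    m = roi.mask(stack.shape_rc, stack.pixel_size_um)
    raw = stack.data[:, m].mean(axis=1)
    bg = np.broadcast_to(np.asarray(background, dtype=float), raw.shape)
    return TimeSeries(
        np.clip(raw - bg, 0.0, None),
        dt=stack.frame_interval_s,
        t0=stack.t0,
        unit_label="F (bg-corrected)",
    )


def detect_onset(
    trace: TimeSeries,
    stim_time_s: float,
    direction: Direction = "either",
    k_sigma: float = 3.0,
    m_consec: int = 5,
    baseline_window_s: tuple[float, float] | None = None,
) -> float | None:
    """First time >= stimulus at which the trace leaves the baseline band.

    The baseline band is mean ± k_sigma·SD over ``baseline_window_s``
    (default: everything before the stimulus); the onset is the start of the
    first run of ``m_consec`` consecutive suprathreshold samples.  If the
    baseline SD is exactly zero the threshold falls back to an absolute
    epsilon of ``1e-9 * max(1, |baseline mean|)`` per sigma.
    Returns None when no onset is found; never returns a time before the
    stimulus.
    """
    if m_consec < 1:
        raise ValueError("m_consec must be >= 1")
    if baseline_window_s is None:
        baseline_window_s = (trace.t0, stim_time_s)
    if baseline_window_s[1] > stim_time_s + 1e-9:
        raise ValueError("baseline window must end at or before the stimulus")
    sl = trace.window_slice(*baseline_window_s)
    base = trace.values[sl]
    # exclude the sample at stim itself from the baseline
    t_last = trace.t0 + (sl.stop - 1) * trace.dt
    if t_last >= stim_time_s - 1e-9 and sl.stop - sl.start > 1:
        base = trace.values[sl.start : sl.stop - 1]
    if base.size < 10:
        raise ValueError("baseline window must contain >= 10 samples")
    mu = float(base.mean())
    sd = float(base.std(ddof=1))
    if sd == 0.0:
        sd = 1e-9 * max(1.0, abs(mu))
    thr = k_sigma * sd

    i0 = max(int(np.ceil((stim_time_s - trace.t0) / trace.dt - 1e-9)), 0)
    dev = trace.values[i0:] - mu
    if direction == "up":
        hits = dev >= thr
    elif direction == "down":
        hits = dev <= -thr
    else:
        hits = np.abs(dev) >= thr
    run = 0
    for j, h in enumerate(hits):
        run = run + 1 if h else 0
        if run >= m_consec:
            onset_idx = i0 + j - m_consec + 1
            return trace.t0 + onset_idx * trace.dt
    return None


def compute_f0_pre_onset(trace: TimeSeries, onset_time_s: float, n: int = 10) -> float:
    """F0 = mean of the ``n`` samples immediately preceding the onset sample."""
    if n < 1:
        raise ValueError("n must be >= 1")
    idx = round_half_up((onset_time_s - trace.t0) / trace.dt)
    if idx < n:
        raise ValueError(f"need {n} samples before onset, have {idx}")
    return float(trace.values[idx - n : idx].mean())


def to_dff(
    trace: TimeSeries,
    F0: float,
    roi: RoiSpec | None = None,
    background: float | np.ndarray | None = None,
) -> DffTrace:
    """Normalise a background-corrected trace as dF/F0 = (F − F0)/F0."""
    if not F0 > 0:
        raise ValueError("F0 must be > 0")
    series = trace.with_values((trace.values - F0) / F0, unit_label="dF/F0")
    return DffTrace(series=series, F0=F0, roi=roi, background=background)


def _ols_slope(trace: TimeSeries, window: tuple[float, float]) -> tuple[float, float]:
    sl = trace.window_slice(*window)
    if sl.stop - sl.start < 3:
        raise ValueError("slope window must contain >= 3 samples")
    t = trace.times[sl]
    v = trace.values[sl]
    slope, _ = np.polyfit(t, v, 1)
    return float(slope), float(v[-1] - v[0])


def pre_post_slopes(
    trace: TimeSeries,
    t_event_s: float,
    pre_window_s: tuple[float, float] | None = None,
    post_window_s: tuple[float, float] | None = None,
    guard_s: float = 10.0,
) -> SlopePair:
    """OLS slopes before/after an event (drug application, injection).

    Default windows are the full pre/post segments shrunk by a ``guard_s``
    band on either side of the event.  Net change over each window is also
    reported (delta_pre/delta_post) for analyses that compare ΔF per phase
    rather than slope.
    """
    t_end = trace.t0 + trace.duration
    if pre_window_s is None:
        pre_window_s = (trace.t0, t_event_s - guard_s)
    if post_window_s is None:
        post_window_s = (t_event_s + guard_s, t_end)
    if pre_window_s[1] > t_event_s + 1e-9:
        raise ValueError("pre window must end at or before the event")
    slope_pre, delta_pre = _ols_slope(trace, pre_window_s)
    slope_post, delta_post = _ols_slope(trace, post_window_s)
    return SlopePair(
        slope_pre=slope_pre,
        slope_post=slope_post,
        pre_window=pre_window_s,
        post_window=post_window_s,
        delta_pre=delta_pre,
        delta_post=delta_post,
    )


def response_metrics(
    dff: DffTrace,
    stim_time_s: float,
    direction: Literal["up", "down"],
    search_window_s: float = 120.0,
    k_sigma: float = 3.0,
    m_consec: int = 5,
    baseline_window_s: tuple[float, float] | None = None,
) -> ResponseMetrics | None:
    """Onset delay, time to peak and absolute amplitude of an evoked response.

    Direction convention for osmotic challenges of dye-loaded astrocytes:
    hypertonic (shrinking, dye concentrates) → "up"; hypotonic (swelling,
    dye dilutes) → "down".  Returns None when no onset is detected (metrics
    are absent, not zero).
    """
    trace = dff.series
    onset = detect_onset(
        trace,
        stim_time_s,
        direction=direction,
        k_sigma=k_sigma,
        m_consec=m_consec,
        baseline_window_s=baseline_window_s,
    )
    if onset is None:
        return None
    sl = trace.window_slice(onset, onset + search_window_s)
    seg = trace.values[sl]
    rel = np.argmax(seg) if direction == "up" else np.argmin(seg)
    peak_idx = sl.start + int(rel)
    peak_time = trace.t0 + peak_idx * trace.dt
    return ResponseMetrics(
        start_time_s=onset - stim_time_s,
        time_to_peak_s=peak_time - stim_time_s,
        amplitude=float(abs(trace.values[peak_idx])),
        direction=direction,
    )
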