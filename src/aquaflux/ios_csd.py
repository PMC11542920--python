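"""Intrinsic-optical-signal analysis of cortical spreading depression.

dT/T0 conversion of transmittance stacks, kymographs along a line of
interest, biphasic peak metrics (the fast CSD front and the slower general
swelling), swelling kinetics, and wave-speed estimation from per-position
onset times.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .core import ImageStack, TimeSeries
from .fit_imaging import detect_onset

__all__ = [
    "Kymograph",
    "CSDMetrics",
    "SwellingKinetics",
    "WaveSpeedEstimate",
    "to_dtt",
    "make_kymograph",
    "csd_peak_metrics",
    "swelling_kinetics",
    "estimate_wave_speed",
]


@dataclass(frozen=True)
class Kymograph:
    """Space × time map of dT/T0 sampled along a line of interest."""

    map: np.ndarray                     # (position, frame)
    line: tuple[tuple[float, float], tuple[float, float]]
    width_px: int
    pixel_size_um: float
    frame_interval_s: float
    t0: float = 0.0

    @property
    def positions_um(self) -> np.ndarray:
        (r0, c0), (r1, c1) = self.line
        length = np.hypot(r1 - r0, c1 - c0) * self.pixel_size_um
        return np.linspace(0.0, length, self.map.shape[0])

    def position_trace(self, i: int) -> TimeSeries:
        return TimeSeries(self.map[i], dt=self.frame_interval_s, t0=self.t0, unit_label="dT/T0")


@dataclass(frozen=True)
class CSDMetrics:
    """Onset delay and biphasic peak structure, referenced to stimulation.

    ``peak2_*`` are None for single-peak responses.  Amplitudes are
    baseline-referenced; ``peak2_amp_from_trough`` additionally measures the
    second peak from the inter-peak trough.
    """

    onset_delay_s: float
    peak1_amp: float
    peak1_time_s: float
    peak2_amp: float | None = None
    peak2_time_s: float | None = None
    peak2_amp_from_trough: float | None = None

    def __post_init__(self) -> None:
        if self.onset_delay_s > self.peak1_time_s + 1e-9:
            raise ValueError("onset must not follow peak 1")
        if self.peak2_time_s is not None and self.peak2_time_s < self.peak1_time_s:
            raise ValueError("peak 2 must follow peak 1")
        if self.peak1_amp < 0 or (self.peak2_amp is not None and self.peak2_amp < 0):
            raise ValueError("amplitudes must be >= 0")


@dataclass(frozen=True)
class SwellingKinetics:
    """Kinetics of the prolonged general-swelling component (peak 2)."""

    speed_per_s: float          # max rising slope of dT/T0 toward peak 2
    duration_s: float           # full width at half of the peak-2 amplitude
    recovery_time_s: float | None  # peak 2 → re-entry into the 10% baseline band

    def __post_init__(self) -> None:
        if self.speed_per_s < 0 or self.duration_s < 0:
            raise ValueError("kinetics must be >= 0")
        if self.recovery_time_s is not None and self.recovery_time_s < 0:
            raise ValueError("recovery time must be >= 0")


@dataclass(frozen=True)
class WaveSpeedEstimate:
    """Wave speed from onset-time-vs-distance regression along a kymograph."""

    speed_um_s: float
    direction: int              # +1: away from line start, -1: toward it
    n_onsets: int
    residual_rms_s: float


def to_dtt(stack: ImageStack, baseline_frames: int, epsilon: float = 1e-9) -> ImageStack:
    """Per-pixel relative transmittance change (T − T0)/T0.

    ``T0`` is the per-pixel mean of the first ``baseline_frames`` frames
    (which must precede stimulation); pixels with T0 <= epsilon are NaN.
    """
    if baseline_frames < 5:
        raise ValueError("need >= 5 baseline frames")
    if baseline_frames > stack.n_frames:
        raise ValueError("baseline exceeds stack length")
    t0_img = stack.data[:baseline_frames].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dtt = (stack.data - t0_img) / t0_img
    dtt[:, t0_img <= epsilon] = np.nan
    return ImageStack(
        data=dtt,
        pixel_size_um=stack.pixel_size_um,
        frame_interval_s=stack.frame_interval_s,
        t0=stack.t0,
    )


def make_kymograph(
    dtt: ImageStack,
    line: tuple[tuple[float, float], tuple[float, float]],
    width_px: int = 5,
) -> Kymograph:
    """Sample dT/T0 along a line, averaging across ``width_px`` perpendicular
    pixels, one column per frame."""
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    (r0, c0), (r1, c1) = line
    n_r, n_c = dtt.shape_rc
    for r, c in (line[0], line[1]):
        if not (0 <= r <= n_r - 1 and 0 <= c <= n_c - 1):
            raise ValueError("line endpoints must lie inside the field")
    length_px = float(np.hypot(r1 - r0, c1 - c0))
    if length_px < 2:
        raise ValueError("line must span >= 2 pixels")
    n_pos = int(np.floor(length_px)) + 1
    s = np.linspace(0.0, 1.0, n_pos)
    rr = r0 + s * (r1 - r0)
    cc = c0 + s * (c1 - c0)
    ur, uc = (r1 - r0) / length_px, (c1 - c0) / length_px
    pr, pc = -uc, ur  # perpendicular unit vector
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    coords_r = rr[:, None] + offsets[None, :] * pr   # (n_pos, width)
    coords_c = cc[:, None] + offsets[None, :] * pc
    coords = np.stack([coords_r.ravel(), coords_c.ravel()])
    out = np.empty((n_pos, dtt.n_frames))
    for k in range(dtt.n_frames):
        sampled = ndimage.map_coordinates(dtt.data[k], coords, order=1, mode="nearest")
        out[:, k] = sampled.reshape(n_pos, width_px).mean(axis=1)
    return Kymograph(
        map=out,
        line=line,
        width_px=width_px,
        pixel_size_um=dtt.pixel_size_um,
        frame_interval_s=dtt.frame_interval_s,
        t0=dtt.t0,
    )


def csd_peak_metrics(
    trace: TimeSeries,
    stim_time_s: float,
    min_separation_s: float = 20.0,
    k_sigma: float = 3.0,
    m_consec: int = 5,
    baseline_window_s: tuple[float, float] | None = None,
) -> CSDMetrics | None:
    """Biphasic peak metrics of a dT/T0 trace.

    Onset via the baseline-band detector (direction up); peak 1 is the first
    local maximum after the onset, peak 2 the largest local maximum at least
    ``min_separation_s`` later.  Peak prominence must exceed the baseline
    noise band to ignore ripple.  Returns None when no onset is detected.
    """
    onset = detect_onset(
        trace,
        stim_time_s,
        direction="up",
        k_sigma=k_sigma,
        m_consec=m_consec,
        baseline_window_s=baseline_window_s,
    )
    if onset is None:
        return None
    bl = (trace.t0, stim_time_s) if baseline_window_s is None else baseline_window_s
    sl_base = trace.window_slice(*bl)
    base = trace.values[sl_base]
    baseline_mu = float(base.mean())
    prominence = max(k_sigma * float(base.std(ddof=1)), 1e-12)

    i_on = trace.index_at(onset)
    seg = trace.values[i_on:]
    peaks, _ = signal.find_peaks(seg, prominence=prominence)
    if peaks.size == 0:  # monotone rise to the end: use global max of segment
        peaks = np.array([int(np.argmax(seg))])
    p1 = int(peaks[0])
    t1 = trace.t0 + (i_on + p1) * trace.dt
    amp1 = float(seg[p1] - baseline_mu)

    min_sep_idx = int(np.ceil(min_separation_s / trace.dt - 1e-9))
    later = peaks[peaks >= p1 + min_sep_idx]
    if later.size == 0:
        return CSDMetrics(
            onset_delay_s=onset - stim_time_s,
            peak1_amp=max(amp1, 0.0),
            peak1_time_s=t1 - stim_time_s,
        )
    p2 = int(later[np.argmax(seg[later])])
    t2 = trace.t0 + (i_on + p2) * trace.dt
    trough = float(seg[p1 : p2 + 1].min())
    return CSDMetrics(
        onset_delay_s=onset - stim_time_s,
        peak1_amp=max(amp1, 0.0),
        peak1_time_s=t1 - stim_time_s,
        peak2_amp=max(float(seg[p2] - baseline_mu), 0.0),
        peak2_time_s=t2 - stim_time_s,
        peak2_amp_from_trough=max(float(seg[p2] - trough), 0.0),
    )


def swelling_kinetics(
    trace: TimeSeries,
    metrics: CSDMetrics,
    stim_time_s: float,
    baseline_level: float | None = None,
) -> SwellingKinetics:
    """Speed, duration and recovery of the general-swelling component.

    speed: max forward difference / dt on the rising limb from the
    inter-peak trough (or onset) to peak 2; duration: contiguous time around
    peak 2 spent above baseline + peak2_amp/2; recovery: time from peak 2
    until the trace first re-enters baseline ± 0.1·peak2_amp (None if it
    never does).  Baseline defaults to the pre-stimulation mean.
    """
    if metrics.peak2_time_s is None or metrics.peak2_amp is None:
        raise ValueError("peak 2 absent; swelling kinetics undefined")
    if baseline_level is None:
        sl = trace.window_slice(trace.t0, stim_time_s)
        baseline_level = float(trace.values[sl].mean())
    i_peak2 = trace.index_at(stim_time_s + metrics.peak2_time_s)
    i_onset = trace.index_at(stim_time_s + metrics.onset_delay_s)
    i_peak1 = trace.index_at(stim_time_s + metrics.peak1_time_s)
    # rising limb starts at the inter-peak trough (or the onset if peaks merge)
    if i_peak1 < i_peak2:
        i_start = i_peak1 + int(np.argmin(trace.values[i_peak1 : i_peak2 + 1]))
    else:
        i_start = i_onset
    rising = np.diff(trace.values[i_start : i_peak2 + 1])
    speed = float(rising.max() / trace.dt) if rising.size else 0.0

    half = baseline_level + metrics.peak2_amp / 2.0
    above = trace.values >= half
    lo = i_peak2
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i_peak2
    while hi < len(trace) - 1 and above[hi + 1]:
        hi += 1
    duration = (hi - lo) * trace.dt

    band = 0.1 * metrics.peak2_amp
    post = trace.values[i_peak2:]
    inside = np.abs(post - baseline_level) <= band
    idx = np.flatnonzero(inside)
    recovery = float(idx[0] * trace.dt) if idx.size else None
    return SwellingKinetics(speed_per_s=max(speed, 0.0), duration_s=duration, recovery_time_s=recovery)


def estimate_wave_speed(
    kym: Kymograph,
    onset_k_sigma: float = 3.0,
    stim_time_s: float = 0.0,
    m_consec: int = 3,
    baseline_window_s: tuple[float, float] | None = None,
) -> WaveSpeedEstimate | None:
    """Wave speed from a least-squares fit of onset time against distance.

    Onsets are detected independently on each kymograph row; at least 5
    rows must yield one (ValueError otherwise).  Returns None when the
    fitted slope is below the resolvable epsilon (simultaneous onset —
    e.g. a global change, not a travelling wave).
    """
    pos = kym.positions_um
    onsets, dists = [], []
    for i in range(kym.map.shape[0]):
        tr = kym.position_trace(i)
        try:
            t_on = detect_onset(
                tr,
                stim_time_s,
                direction="up",
                k_sigma=onset_k_sigma,
                m_consec=m_consec,
                baseline_window_s=baseline_window_s,
            )
        except ValueError:
            continue
        if t_on is not None:
            onsets.append(t_on)
            dists.append(pos[i])
    if len(onsets) < 5:
        raise ValueError(f"wave-speed fit needs >= 5 onsets, found {len(onsets)}")
    d = np.asarray(dists)
    t = np.asarray(onsets)
    slope, intercept = np.polyfit(d, t, 1)  # s per µm
    span = float(np.ptp(d))
    eps = kym.frame_interval_s / (2.0 * span) if span > 0 else np.inf
    if abs(slope) <= eps:
        return None
    resid = t - (intercept + slope * d)
    return WaveSpeedEstimate(
        speed_um_s=float(1.0 / abs(slope)),
        direction=int(np.sign(slope)),
        n_onsets=len(onsets),
        residual_rms_s=float(np.sqrt(np.mean(resid**2))),
    )
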