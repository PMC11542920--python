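"""Synthetic intrinsic-optical-signal stack with a propagating CSD wave.

The transmittance change at a pixel is a radially propagating biphasic
response: a fast first component (the spreading-depression front) and a
slower, larger second component (prolonged general swelling), both
normalised double-exponential kernels delayed by distance/speed:

    dT/T0(p, t) = amp1 * k1(t - stim - d(p)/speed) + amp2 * k2(...)

Kernels are causal (zero for negative argument) with unit peak, so ``amp1``
and ``amp2`` are the component peak amplitudes in dT/T0 units.  The stack
is rendered as ``T0_level * (1 + dT/T0)`` plus Gaussian noise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import ImageStack

__all__ = ["CSDWaveParams", "CSDGroundTruth", "render_csd_stack", "csd_kernel"]


def csd_kernel(t: np.ndarray, tau_rise_s: float, tau_decay_s: float) -> np.ndarray:
    """Unit-peak causal double-exponential kernel (clamped to 0 for t<0)."""
    if tau_rise_s <= 0 or tau_decay_s <= 0:
        raise ValueError("time constants must be > 0")
    t = np.asarray(t, dtype=float)
    tt = np.maximum(t, 0.0)  # clamp before exp: negative times would overflow
    raw = np.where(t >= 0, np.exp(-tt / tau_decay_s) - np.exp(-tt / tau_rise_s), 0.0)
    t_pk = tau_rise_s * tau_decay_s / (tau_decay_s - tau_rise_s) * np.log(tau_decay_s / tau_rise_s)
    peak = np.exp(-t_pk / tau_decay_s) - np.exp(-t_pk / tau_rise_s)
    return raw / peak


@dataclass(frozen=True)
class CSDWaveParams:
    """Wave geometry/kinetics. Second component must decay slower than the
    first (``tau_decay2 > tau_decay1``), mirroring CSD-then-swelling."""

    origin_px: tuple[float, float] = (0.0, 0.0)
    speed_um_s: float = 50.0
    amp1: float = 0.08
    amp2: float = 0.06
    tau_rise1_s: float = 1.0
    tau_decay1_s: float = 5.0
    tau_rise2_s: float = 30.0
    tau_decay2_s: float = 90.0
    stim_time_s: float = 10.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.speed_um_s <= 0:
            raise ValueError("speed_um_s must be > 0")
        if self.amp1 < 0 or self.amp2 < 0:
            raise ValueError("amplitudes must be >= 0")
        for tau in (self.tau_rise1_s, self.tau_decay1_s, self.tau_rise2_s, self.tau_decay2_s):
            if tau <= 0:
                raise ValueError("time constants must be > 0")
        if self.tau_decay2_s <= self.tau_decay1_s:
            raise ValueError("second component must be slower (tau_decay2 > tau_decay1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CSDGroundTruth:
    """Noiseless dT/T0 field and per-pixel wave arrival times."""

    dtt: np.ndarray            # (frame, row, col)
    arrival_time_s: np.ndarray  # (row, col): stim + d/speed
    params: CSDWaveParams


def render_csd_stack(
    wave: CSDWaveParams,
    field_shape_rc: tuple[int, int] = (64, 128),
    pixel_size_um: float = 4.0,
    frame_interval_s: float = 1.0,
    duration_s: float = 120.0,
    seed: int | None = None,
    T0_level: float = 1000.0,
) -> tuple[ImageStack, CSDGroundTruth]:
    """Render a transmittance stack carrying one propagating CSD wave."""
    r0, c0 = wave.origin_px
    if not (0 <= r0 < field_shape_rc[0] and 0 <= c0 < field_shape_rc[1]):
        raise ValueError("wave origin must lie inside the field")
    rows = np.arange(field_shape_rc[0])[:, None]
    cols = np.arange(field_shape_rc[1])[None, :]
    dist_um = np.hypot(rows - r0, cols - c0) * pixel_size_um
    arrival = wave.stim_time_s + dist_um / wave.speed_um_s

    n_frames = int(np.floor(duration_s / frame_interval_s + 1e-9)) + 1
    t = frame_interval_s * np.arange(n_frames)
    tt = t[:, None, None] - arrival[None, :, :]
    dtt = wave.amp1 * csd_kernel(tt, wave.tau_rise1_s, wave.tau_decay1_s)
    dtt += wave.amp2 * csd_kernel(tt, wave.tau_rise2_s, wave.tau_decay2_s)

    data = T0_level * (1.0 + dtt)
    if wave.noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + T0_level * rng.normal(0.0, wave.noise_sd, size=data.shape)
    stack = ImageStack(data=data, pixel_size_um=pixel_size_um, frame_interval_s=frame_interval_s)
    return stack, CSDGroundTruth(dtt=dtt, arrival_time_s=arrival, params=wave)
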