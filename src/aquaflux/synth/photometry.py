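"""Synthetic fiber-photometry traces: bleaching line, injection drop,
amplitude-switched slow oscillation.

The trace is the sum of
  * a photobleaching trend ``intercept + slope_per_s * t``;
  * a smooth level term ramping (mono-exponentially, time constant
    ``drop_tau_s``) to ``−level_drop_frac * intercept`` after the injection;
  * an Ornstein–Uhlenbeck oscillation with correlation time ``osc_tau_s``
    whose stationary SD is ``osc_amp_pre`` before and ``osc_amp_post``
    after the injection;
  * white measurement noise.

Detrending against the fitted line should recover ``level_drop_frac`` and
the oscillation-amplitude ratio — the generator parameters are the oracle.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import TimeSeries

__all__ = ["PhotometryGroundTruth", "simulate_photometry_trace"]


@dataclass(frozen=True)
class PhotometryGroundTruth:
    slope_per_s: float
    intercept: float
    t_inject_s: float
    level_drop_frac: float
    osc_amp_pre: float
    osc_amp_post: float


def simulate_photometry_trace(
    slope_per_s: float = -0.002,
    intercept: float = 100.0,
    t_inject_s: float = 600.0,
    level_drop_frac: float = 0.05,
    osc_amp_pre: float = 1.0,
    osc_amp_post: float = 0.5,
    osc_tau_s: float = 20.0,
    duration_s: float = 1800.0,
    dt: float = 1.0,
    seed: int | None = None,
    drop_tau_s: float = 60.0,
    noise_sd: float = 0.05,
) -> tuple[TimeSeries, PhotometryGroundTruth]:
    """Simulate one photometry recording (1 Hz default)."""
    if dt <= 0 or duration_s <= 0:
        raise ValueError("dt and duration must be > 0")
    if duration_s <= t_inject_s:
        raise ValueError("duration must exceed t_inject")
    if osc_tau_s <= 0:
        raise ValueError("osc_tau_s must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + dt / 2, dt)
    trend = intercept + slope_per_s * t
    post = t >= t_inject_s
    level = np.zeros_like(t)
    level[post] = -level_drop_frac * intercept * (1.0 - np.exp(-(t[post] - t_inject_s) / drop_tau_s))

    # Ornstein–Uhlenbeck: exact discretisation with time-varying stationary SD
    sd = np.where(post, osc_amp_post, osc_amp_pre)
    rho = np.exp(-dt / osc_tau_s)
    osc = np.empty_like(t)
    osc[0] = rng.normal(0.0, sd[0]) if sd[0] > 0 else 0.0
    innov = rng.normal(0.0, 1.0, size=t.size)
    for k in range(1, t.size):
        osc[k] = rho * osc[k - 1] + np.sqrt(max(1.0 - rho**2, 0.0)) * sd[k] * innov[k]

    v = trend + level + osc
    if noise_sd > 0:
        v += rng.normal(0.0, noise_sd, size=t.size)
    truth = PhotometryGroundTruth(
        slope_per_s=slope_per_s,
        intercept=intercept,
        t_inject_s=t_inject_s,
        level_drop_frac=level_drop_frac,
        osc_amp_pre=osc_amp_pre,
        osc_amp_post=osc_amp_post,
    )
    return TimeSeries(v, dt=dt, unit_label="F (a.u.)"), truth
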