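"""Synthetic Ca²⁺ event traces with a pre/post rate change.

Each trace is a unit baseline plus double-exponential transients at Poisson
event times — rate ``rate_pre`` before ``t_switch_s`` and ``rate_post``
after — with exponentially distributed amplitudes, plus white noise.  The
expected temporal-integral "signal strength" of a window is
rate × mean transient area, which makes the post/pre strength ratio a known
function of the rate ratio and gives the statistic an exact calibration
target.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import TimeSeries

__all__ = ["CalciumGroundTruth", "simulate_calcium_traces", "transient_kernel"]


def transient_kernel(t: np.ndarray, tau_rise_s: float, tau_decay_s: float) -> np.ndarray:
    """Double-exponential transient, normalised to unit peak; 0 for t < 0."""
    if tau_decay_s <= tau_rise_s:
        raise ValueError("tau_decay must exceed tau_rise")
    t = np.asarray(t, dtype=float)
    tt = np.maximum(t, 0.0)  # clamp before exp: negative times would overflow
    raw = np.where(t >= 0, np.exp(-tt / tau_decay_s) - np.exp(-tt / tau_rise_s), 0.0)
    t_peak = (
        tau_rise_s * tau_decay_s / (tau_decay_s - tau_rise_s) * np.log(tau_decay_s / tau_rise_s)
    )
    peak = np.exp(-t_peak / tau_decay_s) - np.exp(-t_peak / tau_rise_s)
    return raw / peak


def kernel_area(tau_rise_s: float, tau_decay_s: float) -> float:
    """Integral of the unit-peak transient kernel (dimensionless · s)."""
    t_peak = (
        tau_rise_s * tau_decay_s / (tau_decay_s - tau_rise_s) * np.log(tau_decay_s / tau_rise_s)
    )
    peak = np.exp(-t_peak / tau_decay_s) - np.exp(-t_peak / tau_rise_s)
    return (tau_decay_s - tau_rise_s) / peak


@dataclass(frozen=True)
class CalciumGroundTruth:
    """Per-trace generating record: event times (s) and amplitudes."""

    event_times_s: tuple[np.ndarray, ...]
    event_amps: tuple[np.ndarray, ...]
    rate_pre_per_min: float
    rate_post_per_min: float
    t_switch_s: float
    mean_event_area: float   # amp_mean * kernel area, dF/F0 · s

    def expected_strength_per_min(self, pre: bool) -> float:
        """Expected temporal-integral statistic (dF/F0·s per minute)."""
        rate = self.rate_pre_per_min if pre else self.rate_post_per_min
        return rate * self.mean_event_area


def simulate_calcium_traces(
    rate_pre_per_min: float = 2.0,
    rate_post_per_min: float = 6.0,
    amp_mean: float = 0.5,
    tau_rise_s: float = 1.0,
    tau_decay_s: float = 4.0,
    t_switch_s: float = 300.0,
    duration_s: float = 600.0,
    dt: float = 1.0,
    n: int = 20,
    seed: int | None = None,
    noise_sd: float = 0.01,
) -> tuple[list[TimeSeries], CalciumGroundTruth]:
    """Simulate ``n`` event traces (1 Hz default, matching slice imaging).

    Baseline fluorescence is 1.0, so the lowest-20-sample baseline estimate
    recovers F0 ≈ 1 and transient amplitudes are directly in dF/F0 units.
    """
    if rate_pre_per_min < 0 or rate_post_per_min < 0:
        raise ValueError("event rates must be >= 0")
    if duration_s < t_switch_s:
        raise ValueError("duration must cover t_switch")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + dt / 2, dt)
    traces: list[TimeSeries] = []
    all_times, all_amps = [], []
    for _ in range(n):
        n_pre = rng.poisson(rate_pre_per_min / 60.0 * t_switch_s)
        n_post = rng.poisson(rate_post_per_min / 60.0 * (duration_s - t_switch_s))
        times = np.sort(
            np.concatenate(
                [
                    rng.uniform(0.0, t_switch_s, size=n_pre),
                    rng.uniform(t_switch_s, duration_s, size=n_post),
                ]
            )
        )
        amps = rng.exponential(amp_mean, size=times.size)
        v = np.ones_like(t)
        for ti, ai in zip(times, amps):
            v += ai * transient_kernel(t - ti, tau_rise_s, tau_decay_s)
        if noise_sd > 0:
            v += rng.normal(0.0, noise_sd, size=t.size)
        traces.append(TimeSeries(v, dt=dt, unit_label="F (a.u.)"))
        all_times.append(times)
        all_amps.append(amps)
    truth = CalciumGroundTruth(
        event_times_s=tuple(all_times),
        event_amps=tuple(all_amps),
        rate_pre_per_min=rate_pre_per_min,
        rate_post_per_min=rate_post_per_min,
        t_switch_s=t_switch_s,
        mean_event_area=amp_mean * kernel_area(tau_rise_s, tau_decay_s),
    )
    return traces, truth
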