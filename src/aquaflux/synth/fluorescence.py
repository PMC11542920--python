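"""Dye-dilution renderer: volume traces → SRB-like fluorescence stacks.

A labelled cell holds a fixed amount of dye, so its cytosolic concentration
— and the fluorescence collected from a fixed field of view — scales as
1/V.  Each simulated cell is drawn as a disc (footprint geometry fixed; the
volume signal is carried entirely by intensity), with optional mono-
exponential photobleaching, a flat background offset, and white Gaussian
read noise:

    I(pixel in cell i, frame k) = F0_scale * V0_i / V_i(t_k) * exp(-t_k/bleach_tau)
                                  + background_offset + noise

Swelling (V up) therefore dims the cell; shrinking brightens it, and the
true dF/F0 relative to the resting volume is ``V0/V − 1``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ..core import ImageStack, RoiSpec
from .osmotic import VolumeTrace

__all__ = ["ImagingParams", "render_fit_stack"]


@dataclass(frozen=True)
class ImagingParams:
    """Optics/camera model for the rendered stack.

    ``bleach_tau_s=None`` disables photobleaching; ``noise_sd`` is the
    per-pixel Gaussian noise SD in raw intensity units.
    """

    F0_scale: float = 1000.0
    background_offset: float = 100.0
    bleach_tau_s: float | None = None
    noise_sd: float = 0.0
    pixel_size_um: float = 2.0
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        if self.F0_scale <= 0:
            raise ValueError("F0_scale must be > 0")
        if self.background_offset < 0 or self.noise_sd < 0:
            raise ValueError("imaging parameters must be non-negative")
        if self.bleach_tau_s is not None and self.bleach_tau_s <= 0:
            raise ValueError("bleach_tau_s must be > 0 (or None)")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be > 0")


def render_fit_stack(
    traces: Sequence[VolumeTrace],
    centers_rc: Sequence[tuple[float, float]],
    imaging: ImagingParams,
    field_shape_rc: tuple[int, int] = (64, 64),
    cell_diameter_um: float = 50.0,
    seed: int | None = None,
    allow_overlap: bool = False,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render one fluorescence stack from per-cell volume traces.

    Returns the stack and a long-format ground-truth table with one row per
    (cell, frame): true volume, true dF/F0 = V0/V − 1, and the noiseless
    bleach-free cell intensity.
    """
    if len(traces) != len(centers_rc):
        raise ValueError("need one centre per volume trace")
    if len(traces) == 0:
        raise ValueError("need at least one cell")
    durations = {round(tr.series.duration, 9) for tr in traces}
    if len(durations) > 1:
        raise ValueError("all volume traces must share the same duration")

    radius_px = cell_diameter_um / 2.0 / imaging.pixel_size_um
    rr = np.arange(field_shape_rc[0])[:, None]
    cc = np.arange(field_shape_rc[1])[None, :]
    masks = []
    for r0, c0 in centers_rc:
        if (
            r0 - radius_px < -0.5
            or c0 - radius_px < -0.5
            or r0 + radius_px > field_shape_rc[0] - 0.5
            or c0 + radius_px > field_shape_rc[1] - 0.5
        ):
            raise ValueError(f"cell footprint at {(r0, c0)} exceeds the field")
        masks.append((rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2)
    if not allow_overlap:
        overlap = np.zeros(field_shape_rc, dtype=int)
        for m in masks:
            overlap += m
        if np.any(overlap > 1):
            raise ValueError("cell footprints overlap (pass allow_overlap=True to permit)")

    duration = traces[0].series.duration
    n_frames = int(np.floor(duration / imaging.frame_interval_s + 1e-9)) + 1
    t_frames = imaging.frame_interval_s * np.arange(n_frames)
    bleach = (
        np.ones(n_frames)
        if imaging.bleach_tau_s is None
        else np.exp(-t_frames / imaging.bleach_tau_s)
    )

    rng = np.random.default_rng(seed)
    data = np.full((n_frames,) + tuple(field_shape_rc), imaging.background_offset, dtype=float)
    if imaging.noise_sd > 0:
        data += rng.normal(0.0, imaging.noise_sd, size=data.shape)

    records = []
    for i, (tr, m) in enumerate(zip(traces, masks)):
        V = np.interp(t_frames, tr.series.times, tr.series.values)
        cell_int = imaging.F0_scale * tr.params.V0 / V * bleach
        data[:, m] += cell_int[:, None]
        for k in range(n_frames):
            records.append(
                {
                    "cell": i,
                    "frame": k,
                    "time_s": t_frames[k],
                    "row": centers_rc[i][0],
                    "col": centers_rc[i][1],
                    "V_um3": V[k],
                    "dff_true": tr.params.V0 / V[k] - 1.0,
                    "intensity_true": imaging.F0_scale * tr.params.V0 / V[k],
                }
            )

    stack = ImageStack(
        data=data,
        pixel_size_um=imaging.pixel_size_um,
        frame_interval_s=imaging.frame_interval_s,
    )
    return stack, pd.DataFrame.from_records(records)
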