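"""Core data containers shared by every analysis stage.

All trace quantities (raw fluorescence F, dF/F0, transmittance dT/T0, ADC
time courses) travel as :class:`TimeSeries`; single-plane time-lapse
acquisitions travel as :class:`ImageStack`; diffusion-weighted series as
:class:`DWISeries`.  Conventions, used everywhere:

* frame/sample indices are 0-based; sample ``i`` sits at time ``t0 + i*dt``;
* spatial arrays are (row, col) with origin top-left;
* physical parameters are given in seconds / micrometres and converted to
  frames / pixels by rounding half-up.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "ImageStack",
    "RoiSpec",
    "DWISeries",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round a scalar to the nearest integer, ties away from zero-half up."""
    return int(np.floor(float(x) + 0.5))


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled scalar signal.

    Parameters
    ----------
    values : 1-D array of samples.
    dt : sampling interval in seconds (> 0).
    t0 : time of sample 0 in seconds.
    unit_label : free-text unit of the samples (e.g. ``"dF/F0"``).
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0
    unit_label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("TimeSeries requires a 1-D array with >= 1 sample")
        if not self.dt > 0:
            raise ValueError(f"dt must be strictly positive, got {self.dt}")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.dt * (self.values.size - 1)

    def index_at(self, t_s: float) -> int:
        """Sample index nearest to time ``t_s`` (half-up rounding)."""
        i = round_half_up((t_s - self.t0) / self.dt)
        return min(max(i, 0), len(self) - 1)

    def window_slice(self, t_start: float, t_end: float) -> slice:
        """Half-open index range covering samples with t_start <= t <= t_end."""
        i0 = int(np.ceil((t_start - self.t0) / self.dt - 1e-9))
        i1 = int(np.floor((t_end - self.t0) / self.dt + 1e-9)) + 1
        i0 = max(i0, 0)
        i1 = min(i1, len(self))
        if i1 <= i0:
            raise ValueError(f"window [{t_start}, {t_end}] s contains no samples")
        return slice(i0, i1)

    def crop(self, t_start: float, t_end: float) -> "TimeSeries":
        sl = self.window_slice(t_start, t_end)
        return TimeSeries(
            self.values[sl],
            dt=self.dt,
            t0=self.t0 + sl.start * self.dt,
            unit_label=self.unit_label,
        )

    def with_values(self, values: np.ndarray, unit_label: str | None = None) -> "TimeSeries":
        return TimeSeries(
            values,
            dt=self.dt,
            t0=self.t0,
            unit_label=self.unit_label if unit_label is None else unit_label,
        )


@dataclass(frozen=True)
class ImageStack:
    """Single-channel time-lapse stack, shape (frame, row, col)."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3 or data.shape[0] < 1:
            raise ValueError("ImageStack requires a (frame, row, col) array with >= 1 frame")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be > 0")
        object.__setattr__(self, "data", data)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape_rc(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.frame_interval_s * np.arange(self.n_frames)

    def frame_at(self, t_s: float) -> int:
        i = round_half_up((t_s - self.t0) / self.frame_interval_s)
        return min(max(i, 0), self.n_frames - 1)


@dataclass(frozen=True)
class RoiSpec:
    """Circular region of interest (default diameter 50 µm, matching the
    footprint of a single astrocyte plus its extended processes)."""

    center_rc: tuple[float, float]
    diameter_um: float = 50.0

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError("diameter_um must be > 0")

    def mask(self, shape_rc: tuple[int, int], pixel_size_um: float) -> np.ndarray:
        """Boolean disc: pixels whose centre lies within diameter/2 of the
        ROI centre (distances converted through ``pixel_size_um``)."""
        if not pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        rows, cols = np.ogrid[0 : shape_rc[0], 0 : shape_rc[1]]
        r0, c0 = self.center_rc
        d2 = ((rows - r0) ** 2 + (cols - c0) ** 2) * pixel_size_um**2
        m = d2 <= (self.diameter_um / 2.0) ** 2
        if not m.any():
            raise ValueError("ROI mask is empty for this field/pixel size")
        return m


@dataclass(frozen=True)
class DWISeries:
    """Direction-averaged diffusion-weighted series.

    ``signals`` has shape (time, bvalue, x, y, z), b-values ascending;
    ``roi_labels`` is an integer volume on the same grid (0 = background).
    """

    signals: np.ndarray
    bvalues: np.ndarray
    roi_labels: np.ndarray
    time_spacing_s: float = 300.0
    region_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sig = np.asarray(self.signals, dtype=float)
        bvals = np.asarray(self.bvalues, dtype=float)
        labels = np.asarray(self.roi_labels)
        if sig.ndim != 5:
            raise ValueError("signals must be (time, bvalue, x, y, z)")
        if bvals.ndim != 1 or bvals.size != sig.shape[1]:
            raise ValueError("bvalues must match signals axis 1")
        if np.unique(bvals).size < 2:
            raise ValueError("ADC fitting requires >= 2 distinct b-values")
        if np.any(np.diff(bvals) <= 0):
            raise ValueError("bvalues must be strictly ascending")
        if labels.shape != sig.shape[2:]:
            raise ValueError("roi_labels grid does not match signal volumes")
        if np.any(labels < 0):
            raise ValueError("roi_labels must be non-negative integers")
        object.__setattr__(self, "signals", sig)
        object.__setattr__(self, "bvalues", bvals)
        object.__setattr__(self, "roi_labels", labels.astype(int))

    @property
    def n_time(self) -> int:
        return self.signals.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return self.time_spacing_s * np.arange(self.n_time)

    def region_labels(self) -> list[int]:
        labs = np.unique(self.roi_labels)
        return [int(l) for l in labs if l != 0]

    def region_name(self, label: int) -> str:
        return self.region_names.get(label, f"region_{label}")
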