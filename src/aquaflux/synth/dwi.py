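"""Synthetic diffusion-weighted series: mono-exponential decay + Rician noise.

The noiseless direction-averaged voxel signal is ``S0 * exp(-b * ADC)``
with a region-dependent, time-varying true ADC.  Magnitude-image noise is
Rician: the modulus of the complex signal perturbed by i.i.d. Gaussian noise
of SD ``sigma = S0 / SNR_b0`` in both quadratures.  The defaults mirror a
repeated-scan protocol: 14 scans, 5 min apart, b = 0/250/1800 s/mm².
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import DWISeries

__all__ = ["DWIGroundTruth", "simulate_dwi_series", "phantom_truth", "make_phantom_labels"]

DEFAULT_BVALUES = (0.0, 250.0, 1800.0)  # s/mm²


@dataclass(frozen=True)
class DWIGroundTruth:
    """Per-region true ADC time courses (mm²/s) and the noise model."""

    region_adc: dict[int, np.ndarray]
    S0: float = 1000.0
    SNR_b0: float = 50.0
    bvalues: tuple[float, ...] = DEFAULT_BVALUES
    region_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.SNR_b0 <= 0:
            raise ValueError("SNR_b0 must be > 0 (use np.inf for noiseless)")
        if self.S0 <= 0:
            raise ValueError("S0 must be > 0")
        clean = {}
        for lab, tc in self.region_adc.items():
            tc = np.asarray(tc, dtype=float)
            if np.any(tc <= 0):
                raise ValueError(f"region {lab}: true ADC must be > 0")
            clean[int(lab)] = tc
        object.__setattr__(self, "region_adc", clean)
        b = np.asarray(self.bvalues, dtype=float)
        if np.unique(b).size != b.size or 0.0 not in b:
            raise ValueError("b-values must be distinct and include 0")


def phantom_truth(
    adc: float = 1.0e-3,
    n_time: int = 14,
    S0: float = 1000.0,
    SNR_b0: float = 50.0,
    bvalues: tuple[float, ...] = DEFAULT_BVALUES,
) -> DWIGroundTruth:
    """Homogeneous stable phantom: one region, constant true ADC."""
    return DWIGroundTruth(
        region_adc={1: np.full(n_time, adc)},
        S0=S0,
        SNR_b0=SNR_b0,
        bvalues=bvalues,
        region_names={1: "phantom"},
    )


def make_phantom_labels(n_voxels: int = 500, shape: tuple[int, int, int] | None = None) -> np.ndarray:
    """Label volume with ``n_voxels`` voxels of label 1 in a compact block."""
    if shape is None:
        side = int(np.ceil(n_voxels ** (1 / 3)))
        shape = (side, side, side)
    labels = np.zeros(shape, dtype=int)
    flat = labels.reshape(-1)
    if n_voxels > flat.size:
        raise ValueError("n_voxels exceeds grid size")
    flat[:n_voxels] = 1
    return labels


def simulate_dwi_series(
    truth: DWIGroundTruth,
    region_label_volume: np.ndarray,
    n_time: int | None = None,
    seed: int | None = None,
    time_spacing_s: float = 300.0,
) -> tuple[DWISeries, DWIGroundTruth]:
    """Simulate a repeated-scan DWI series over a labelled volume.

    Every nonzero label present in the volume must have a truth time course
    of length ``n_time``; background (label 0) carries zero true signal and
    is pure noise floor.  ``SNR_b0 = np.inf`` disables noise.
    """
    labels = np.asarray(region_label_volume).astype(int)
    present = {int(l) for l in np.unique(labels) if l != 0}
    missing = present - set(truth.region_adc)
    if missing:
        raise ValueError(f"labelled regions without a truth time course: {sorted(missing)}")
    lengths = {tc.size for tc in truth.region_adc.values()}
    if n_time is None:
        if len(lengths) != 1:
            raise ValueError("ambiguous n_time: truth time courses differ in length")
        n_time = lengths.pop()
    elif lengths and lengths != {n_time}:
        raise ValueError(f"truth time courses must all have length n_time={n_time}")

    bvalues = np.sort(np.asarray(truth.bvalues, dtype=float))
    signals = np.zeros((n_time, bvalues.size) + labels.shape)
    adc_map = np.zeros(labels.shape)
    for ti in range(n_time):
        for lab in present:
            adc_map[labels == lab] = truth.region_adc[lab][ti]
        clean = np.where(
            labels[None, :, :, :] > 0,
            truth.S0 * np.exp(-bvalues[:, None, None, None] * adc_map[None, :, :, :]),
            0.0,
        )
        signals[ti] = clean
    if np.isfinite(truth.SNR_b0):
        rng = np.random.default_rng(seed)
        sigma = truth.S0 / truth.SNR_b0
        n1 = rng.normal(0.0, sigma, size=signals.shape)
        n2 = rng.normal(0.0, sigma, size=signals.shape)
        signals = np.hypot(signals + n1, n2)
    series = DWISeries(
        signals=signals,
        bvalues=bvalues,
        roi_labels=labels,
        time_spacing_s=time_spacing_s,
        region_names=dict(truth.region_names),
    )
    return series, truth
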