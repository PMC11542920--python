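"""Voxelwise ADC fitting, ROI time courses, ΔADC, and phantom QC.

The apparent diffusion coefficient is fitted per voxel by an unweighted
least-squares line through ln(S) versus b over all b-values (default
acquisition 0/250/1800 s/mm²): ADC = −slope, S0 = exp(intercept).  Voxels
with any non-positive signal are flagged as failed and excluded from region
means (and counted).  ΔADC is the percentage change of a region's mean ADC
from the basal-period mean — by default the average of the first two scans,
acquired before the injection:

    ΔADC_i = (ADC_i / baseline − 1) × 100  (%)

A ``baseline="scan2"`` compatibility option divides by the second scan's
ADC alone instead of the two-scan average.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core import DWISeries

__all__ = [
    "ADCTimecourse",
    "DeltaADCSeries",
    "fit_adc_voxel",
    "fit_adc_volume",
    "adc_timecourse",
    "delta_adc",
    "summarize_post_window",
    "phantom_stability",
]


@dataclass(frozen=True)
class ADCTimecourse:
    """Per-region mean ADC (mm²/s) at each scan.

    ``table`` columns: region, time_index, time_s, adc_mean, n_voxels,
    n_failed.  Failed voxels are excluded from the means; regions with zero
    successful fits carry NaN.
    """

    table: pd.DataFrame
    time_spacing_s: float

    @property
    def regions(self) -> list[str]:
        return list(pd.unique(self.table["region"]))

    def region_series(self, region: str) -> np.ndarray:
        sub = self.table[self.table["region"] == region].sort_values("time_index")
        return sub["adc_mean"].to_numpy()


@dataclass(frozen=True)
class DeltaADCSeries:
    """Per-region percentage ADC change from the basal-period mean."""

    table: pd.DataFrame          # region, time_index, time_s, delta_adc_pct
    baseline_indices: tuple[int, ...]

    def region_series(self, region: str) -> np.ndarray:
        sub = self.table[self.table["region"] == region].sort_values("time_index")
        return sub["delta_adc_pct"].to_numpy()

    @property
    def regions(self) -> list[str]:
        return list(pd.unique(self.table["region"]))


def fit_adc_voxel(signals: Sequence[float], bvalues: Sequence[float]) -> tuple[float, float]:
    """Log-linear fit of one voxel: returns (S0, ADC in mm²/s).

    Non-positive signals invalidate their b-point; fewer than two valid
    points flags failure as (nan, nan) rather than raising, so volume-scale
    fitting can proceed.
    """
    s = np.asarray(signals, dtype=float)
    b = np.asarray(bvalues, dtype=float)
    valid = s > 0
    if valid.sum() < 2 or np.unique(b[valid]).size < 2:
        return float("nan"), float("nan")
    slope, intercept = np.polyfit(b[valid], np.log(s[valid]), 1)
    return float(np.exp(intercept)), float(-slope)


def fit_adc_volume(signals: np.ndarray, bvalues: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised log-linear fit over a (bvalue, x, y, z) block.

    Returns (S0, ADC) volumes; voxels with any non-positive signal are NaN.
    The closed-form OLS slope is used (all voxels share the b design).
    """
    b = np.asarray(bvalues, dtype=float)
    ok = np.all(signals > 0, axis=0)
    lnS = np.full_like(signals, np.nan)
    np.log(signals, out=lnS, where=signals > 0)
    bc = b - b.mean()
    sxx = float((bc**2).sum())
    slope = np.einsum("b,bxyz->xyz", bc, lnS) / sxx
    intercept = lnS.mean(axis=0) - slope * b.mean()
    S0 = np.exp(intercept)
    adc = -slope
    S0[~ok] = np.nan
    adc[~ok] = np.nan
    return S0, adc


def adc_timecourse(series: DWISeries) -> ADCTimecourse:
    """Fit every voxel at every scan and average ADC maps within each ROI."""
    rows = []
    for ti in range(series.n_time):
        _, adc = fit_adc_volume(series.signals[ti], series.bvalues)
        for lab in series.region_labels():
            m = series.roi_labels == lab
            vals = adc[m]
            good = np.isfinite(vals)
            rows.append(
                {
                    "region": series.region_name(lab),
                    "time_index": ti,
                    "time_s": ti * series.time_spacing_s,
                    "adc_mean": float(vals[good].mean()) if good.any() else float("nan"),
                    "n_voxels": int(m.sum()),
                    "n_failed": int((~good).sum()),
                }
            )
    return ADCTimecourse(table=pd.DataFrame(rows), time_spacing_s=series.time_spacing_s)


def delta_adc(
    tc: ADCTimecourse,
    baseline_indices: Sequence[int] = (0, 1),
    baseline: Literal["mean", "scan2"] = "mean",
) -> DeltaADCSeries:
    """Percentage ADC change from the basal period, per region.

    ``baseline="mean"`` (default) divides by the mean ADC over
    ``baseline_indices``; ``baseline="scan2"`` divides by the ADC of the
    scan at the last baseline index only.
    """
    baseline_indices = tuple(int(i) for i in baseline_indices)
    if len(baseline_indices) == 0:
        raise ValueError("need at least one baseline scan")
    rows = []
    for region in tc.regions:
        sub = tc.table[tc.table["region"] == region].sort_values("time_index")
        adc = sub["adc_mean"].to_numpy()
        if max(baseline_indices) >= adc.size:
            raise ValueError("baseline index beyond the time course")
        if baseline == "mean":
            ref = float(np.mean(adc[list(baseline_indices)]))
        elif baseline == "scan2":
            ref = float(adc[baseline_indices[-1]])
        else:
            raise ValueError(f"unknown baseline mode {baseline!r}")
        if not ref > 0:
            raise ValueError(f"region {region}: baseline ADC must be > 0")
        for ti, a in zip(sub["time_index"], adc):
            rows.append(
                {
                    "region": region,
                    "time_index": int(ti),
                    "time_s": int(ti) * tc.time_spacing_s,
                    "delta_adc_pct": (a / ref - 1.0) * 100.0,
                }
            )
    return DeltaADCSeries(table=pd.DataFrame(rows), baseline_indices=baseline_indices)


def summarize_post_window(
    ds: DeltaADCSeries | ADCTimecourse,
    window_indices: Sequence[int] | None = None,
    injection_index: int = 2,
    window_post_injection_s: tuple[float, float] = (1800.0, 3000.0),
) -> pd.DataFrame:
    """Per-region mean over a post-injection window of scans.

    Default window: scans falling 30–50 min after the injection (which
    follows the second scan in the repeated-scan protocol).  Feeds the group
    statistics stage.
    """
    tc = ds.table
    value_col = "delta_adc_pct" if "delta_adc_pct" in tc.columns else "adc_mean"
    if window_indices is None:
        spacing = ds.time_spacing_s if isinstance(ds, ADCTimecourse) else None
        if spacing is None:
            times = tc.sort_values("time_index")["time_s"].unique()
            spacing = float(np.median(np.diff(times))) if times.size > 1 else 300.0
        t_inject = injection_index * spacing
        lo, hi = (t_inject + w for w in window_post_injection_s)
        window_indices = sorted(
            int(i)
            for i, t in zip(tc["time_index"], tc["time_s"])
            if lo - 1e-9 <= t <= hi + 1e-9
        )
    window_indices = sorted(set(int(i) for i in window_indices))
    if not window_indices:
        raise ValueError("post-injection window contains no scans")
    sub = tc[tc["time_index"].isin(window_indices)]
    if sub.empty:
        raise ValueError("post-injection window indices not present in the time course")
    out = (
        sub.groupby("region", sort=False)[value_col]
        .mean()
        .rename("window_mean")
        .reset_index()
    )
    out["window_indices"] = [tuple(window_indices)] * len(out)
    return out


def phantom_stability(
    tc: ADCTimecourse,
    basal_indices: Sequence[int] = (0, 1),
) -> float:
    """Max |ΔADC| (%) of a single-region phantom from its basal-period mean.

    The quality bound for a stable scanner/phantom is 2%.
    """
    if len(tc.regions) != 1:
        raise ValueError("phantom stability is defined for a single-region time course")
    ds = delta_adc(tc, baseline_indices=basal_indices)
    return float(np.max(np.abs(ds.region_series(tc.regions[0]))))
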