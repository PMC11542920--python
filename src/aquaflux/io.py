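"""Readers and writers for the formats the pipeline exchanges.

TIFF (single-channel grayscale stacks, 8/16/32-bit), NIfTI-1 (DWI volumes
and ROI label maps), and CSV (traces, b-value tables, metrics).  Acquisition
metadata embedded in image files is ignored in favour of explicit arguments:
pixel size and frame interval are experiment-book quantities, not something
to trust a re-saved TIFF about.
"""
from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .core import DWISeries, ImageStack, TimeSeries

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "read_trace_csv",
    "write_trace_csv",
    "read_dwi_series",
    "write_dwi_series",
]


def read_image_stack(
    path: str | os.PathLike,
    pixel_size_um: float,
    frame_interval_s: float,
    t0: float = 0.0,
) -> ImageStack:
    """Read a single-channel multi-page TIFF as an :class:`ImageStack`.

    Frames keep file order; integer pixel data is preserved bit-exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel stack (frame, row, col); got shape {data.shape}"
        )
    return ImageStack(
        data=data,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        t0=t0,
    )


def write_image_stack(path: str | os.PathLike, stack: ImageStack) -> None:
    """Write an :class:`ImageStack` as a multi-page grayscale TIFF."""
    tifffile.imwrite(Path(path), stack.data, photometric="minisblack")


def read_trace_csv(path: str | os.PathLike, unit_label: str = "") -> TimeSeries:
    """Read a single-ROI trace CSV with columns ``time_s, value``.

    The time column must be uniformly sampled; dt and t0 are inferred.
    """
    df = pd.read_csv(path)
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: trace CSV needs columns time_s,value")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: trace needs >= 2 samples to infer dt")
    dts = np.diff(t)
    dt = float(np.median(dts))
    if not np.allclose(dts, dt, rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    return TimeSeries(df["value"].to_numpy(dtype=float), dt=dt, t0=float(t[0]), unit_label=unit_label)


def write_trace_csv(path: str | os.PathLike, trace: TimeSeries) -> None:
    pd.DataFrame({"time_s": trace.times, "value": trace.values}).to_csv(path, index=False)


def _read_nifti(path: Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float)


def read_dwi_series(
    volume_paths_table: str | os.PathLike,
    bvalue_table: str | os.PathLike,
    roi_label_path: str | os.PathLike,
    time_spacing_s: float = 300.0,
) -> DWISeries:
    """Assemble a :class:`DWISeries` from per-(time, b-value) NIfTI volumes.

    Parameters
    ----------
    volume_paths_table : CSV with columns ``time_index, bvalue, path`` —
        one direction-averaged volume per (time point, b-value).
    bvalue_table : CSV with a ``bvalue`` column listing the acquisition's
        b-values (s/mm²), each exactly once.
    roi_label_path : NIfTI integer label volume on the same grid,
        0 = background.

    Rows may appear in any order; the output is canonically ordered with
    time points ascending and b-values ascending.
    """
    table = pd.read_csv(volume_paths_table)
    for col in ("time_index", "bvalue", "path"):
        if col not in table.columns:
            raise ValueError("volume table needs columns time_index,bvalue,path")
    bdf = pd.read_csv(bvalue_table)
    if "bvalue" not in bdf.columns:
        raise ValueError("b-value table needs a bvalue column")
    bvalues = np.sort(bdf["bvalue"].to_numpy(dtype=float))
    if np.unique(bvalues).size != bvalues.size:
        raise ValueError("duplicate rows in b-value table")

    labels = nib.load(str(roi_label_path))
    label_vol = np.rint(np.asarray(labels.dataobj)).astype(int)

    time_indices = np.sort(table["time_index"].unique())
    base = Path(volume_paths_table).parent
    signals = None
    for ti, t_idx in enumerate(time_indices):
        sub = table[table["time_index"] == t_idx]
        if sub.duplicated("bvalue").any():
            raise ValueError(f"time point {t_idx}: duplicate b-value rows")
        for bi, b in enumerate(bvalues):
            rows = sub[np.isclose(sub["bvalue"].to_numpy(dtype=float), b)]
            if len(rows) != 1:
                raise ValueError(f"missing volume for time {t_idx}, b={b:g}")
            p = Path(rows.iloc[0]["path"])
            if not p.is_absolute():
                p = base / p
            vol = _read_nifti(p)
            if signals is None:
                signals = np.empty((time_indices.size, bvalues.size) + vol.shape)
            if vol.shape != signals.shape[2:]:
                raise ValueError(f"{p}: grid {vol.shape} != {signals.shape[2:]}")
            signals[ti, bi] = vol
    if label_vol.shape != signals.shape[2:]:
        raise ValueError("ROI label grid does not match DWI volumes")
    return DWISeries(
        signals=signals,
        bvalues=bvalues,
        roi_labels=label_vol,
        time_spacing_s=time_spacing_s,
    )


def write_dwi_series(out_dir: str | os.PathLike, series: DWISeries) -> tuple[Path, Path, Path]:
    """Write a DWISeries as NIfTI volumes + volume/b-value CSV tables.

    Returns the paths of (volume table, b-value table, ROI labels), in the
    layout :func:`read_dwi_series` consumes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    affine = np.eye(4)
    for ti in range(series.n_time):
        for bi, b in enumerate(series.bvalues):
            name = f"dwi_t{ti:02d}_b{int(round(b)):04d}.nii"
            nib.save(nib.Nifti1Image(series.signals[ti, bi].astype(np.float32), affine), str(out / name))
            rows.append({"time_index": ti, "bvalue": b, "path": name})
    vol_table = out / "volumes.csv"
    pd.DataFrame(rows).to_csv(vol_table, index=False)
    b_table = out / "bvalues.csv"
    pd.DataFrame({"bvalue": series.bvalues}).to_csv(b_table, index=False)
    roi_path = out / "roi_labels.nii"
    nib.save(nib.Nifti1Image(series.roi_labels.astype(np.int16), affine), str(roi_path))
    return vol_table, b_table, roi_path
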