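"""Stage registry and reproducible runs.

Each stage is a pure function of (inputs, parameters, seed) that writes
tables (CSV) and derived images (TIFF/NIfTI) into the run directory and
returns the list of files it produced.  ``run_pipeline`` wraps a stage call
with a manifest (inputs, parameters, seed, software version, outputs) so
any output can be regenerated; the same config and seed give byte-identical
tables.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .core import RoiSpec
from . import calcium as ca
from . import dwi_adc as da
from . import fit_imaging as fi
from . import ios_csd as ic
from . import photometry as ph
from . import stats as st
from . import synth
from .io import (
    read_dwi_series,
    read_image_stack,
    read_trace_csv,
    write_dwi_series,
    write_image_stack,
    write_trace_csv,
)

__all__ = ["STAGES", "run_pipeline", "register_stage"]

STAGES: dict[str, Callable[[RunConfig, Path], list[str]]] = {}


def register_stage(name: str):
    def deco(fn):
        STAGES[name] = fn
        return fn

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run one registered stage and write a manifest; returns the manifest."""
    if config.stage not in STAGES:
        raise ValueError(f"unknown stage {config.stage!r}; registered: {sorted(STAGES)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = STAGES[config.stage](config, out)
    manifest = {
        "stage": config.stage,
        "inputs": dict(config.inputs),
        "params": {k: v for k, v in sorted(config.params.items())},
        "seed": config.seed,
        "version": __version__,
        "outputs": sorted(outputs),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _load_rois(path: Path) -> list[RoiSpec]:
    df = pd.read_csv(path)
    for col in ("row", "col"):
        if col not in df.columns:
            raise ValueError(f"{path}: ROI table needs columns row,col[,diameter_um]")
    diam = df["diameter_um"] if "diameter_um" in df.columns else [50.0] * len(df)
    return [
        RoiSpec(center_rc=(float(r), float(c)), diameter_um=float(d))
        for r, c, d in zip(df["row"], df["col"], diam)
    ]


# ----------------------------------------------------------------- simulate

@register_stage("simulate")
def _stage_simulate(cfg: RunConfig, out: Path) -> list[str]:
    scenario = cfg.param("scenario")
    if scenario is None:
        raise KeyError("config is missing required parameter 'scenario'")
    seed = cfg.seed
    outputs: list[str] = []
    if scenario == "osmotic":
        params = synth.OsmoticParams(
            g_aqp=float(cfg.param("g_aqp", 2.0)),
            g_leak=float(cfg.param("g_leak", 0.5)),
            J_met=float(cfg.param("J_met", 0.0)),
        )
        proto = synth.ChallengeProtocol(
            c_out=(300.0, float(cfg.param("c_out_challenge", 400.0)), 300.0),
            breakpoints=(0.0, float(cfg.param("t_on_s", 60.0)), float(cfg.param("t_off_s", 120.0))),
            duration=float(cfg.param("duration_s", 300.0)),
        )
        trace = synth.simulate_osmotic_volume(params, proto, dt=float(cfg.param("dt", 0.1)))
        imaging = synth.ImagingParams(
            noise_sd=float(cfg.param("noise_sd", 5.0)),
            pixel_size_um=float(cfg.param("pixel_size_um", 2.0)),
            frame_interval_s=float(cfg.param("frame_interval_s", 1.0)),
        )
        stack, truth = synth.render_fit_stack([trace], [(32.0, 32.0)], imaging, seed=seed)
        write_image_stack(out / "stack.tif", stack)
        truth.to_csv(out / "ground_truth.csv", index=False)
        pd.DataFrame({"row": [32.0], "col": [32.0], "diameter_um": [50.0]}).to_csv(
            out / "rois.csv", index=False
        )
        outputs += ["stack.tif", "ground_truth.csv", "rois.csv"]
    elif scenario == "calcium":
        traces, truth = synth.simulate_calcium_traces(
            n=int(cfg.param("n", 20)), seed=seed
        )
        for i, tr in enumerate(traces):
            write_trace_csv(out / f"trace_{i:03d}.csv", tr)
            outputs.append(f"trace_{i:03d}.csv")
        pd.DataFrame(
            {
                "trace": range(len(traces)),
                "n_events_pre": [t[t < truth.t_switch_s].size for t in truth.event_times_s],
                "n_events_post": [t[t >= truth.t_switch_s].size for t in truth.event_times_s],
            }
        ).to_csv(out / "ground_truth.csv", index=False)
        outputs.append("ground_truth.csv")
    elif scenario == "photometry":
        trace, truth = synth.simulate_photometry_trace(seed=seed)
        write_trace_csv(out / "trace.csv", trace)
        pd.DataFrame([truth.__dict__]).to_csv(out / "ground_truth.csv", index=False)
        outputs += ["trace.csv", "ground_truth.csv"]
    elif scenario == "csd":
        field = (int(cfg.param("field_rows", 64)), int(cfg.param("field_cols", 128)))
        wave = synth.CSDWaveParams(
            origin_px=(field[0] / 2.0, 0.0),  # on the default kymograph line
            speed_um_s=float(cfg.param("speed_um_s", 50.0)),
            noise_sd=float(cfg.param("noise_sd", 0.002)),
        )
        stack, truth = synth.render_csd_stack(
            wave, field_shape_rc=field, duration_s=float(cfg.param("duration_s", 200.0)), seed=seed
        )
        write_image_stack(out / "stack.tif", stack)
        pd.DataFrame([{"speed_um_s": wave.speed_um_s, "stim_time_s": wave.stim_time_s,
                       "amp1": wave.amp1, "amp2": wave.amp2}]).to_csv(
            out / "ground_truth.csv", index=False
        )
        outputs += ["stack.tif", "ground_truth.csv"]
    elif scenario in ("dwi", "phantom"):
        n_time = int(cfg.param("n_time", 14))
        if scenario == "phantom":
            truth = synth.phantom_truth(n_time=n_time, SNR_b0=float(cfg.param("snr_b0", 50.0)))
            labels = synth.make_phantom_labels(int(cfg.param("n_voxels", 500)))
        else:
            base = float(cfg.param("adc_base", 1.0e-3))
            step = 1.0 + float(cfg.param("step_pct", 6.0)) / 100.0
            course = np.full(n_time, base)
            course[int(cfg.param("step_scan", 3)) :] *= step
            truth = synth.DWIGroundTruth(
                region_adc={1: np.full(n_time, base), 2: course},
                SNR_b0=float(cfg.param("snr_b0", 50.0)),
                region_names={1: "cortex", 2: "striatum"},
            )
            labels = np.zeros((12, 12, 8), dtype=int)
            labels[:6] = 1
            labels[6:] = 2
        series, _ = synth.simulate_dwi_series(truth, labels, seed=seed)
        write_dwi_series(out, series)
        outputs += ["volumes.csv", "bvalues.csv", "roi_labels.nii"]
        pd.DataFrame(
            [
                {"region": truth.region_names.get(lab, f"region_{lab}"), "time_index": ti,
                 "adc_true": tc[ti]}
                for lab, tc in truth.region_adc.items()
                for ti in range(len(tc))
            ]
        ).to_csv(out / "ground_truth.csv", index=False)
        outputs.append("ground_truth.csv")
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return outputs


# -------------------------------------------------------------- fit-imaging

@register_stage("fit-imaging")
def _stage_fit_imaging(cfg: RunConfig, out: Path) -> list[str]:
    stack = read_image_stack(
        cfg.require_input("stack"),
        pixel_size_um=float(cfg.param("pixel_size_um", 2.0)),
        frame_interval_s=float(cfg.param("frame_interval_s", 1.0)),
    )
    rois = _load_rois(cfg.require_input("rois"))
    stim = float(cfg.param("stim_time_s", 60.0))
    direction = str(cfg.param("direction", "either"))
    bg = fi.estimate_background(stack, "auto", subregion_um=float(cfg.param("subregion_um", 15.0)))
    trace_rows, metric_rows = [], []
    for i, roi in enumerate(rois):
        raw = fi.extract_roi_trace(stack, roi, bg)
        onset = fi.detect_onset(raw, stim, direction=direction)
        f0 = fi.compute_f0_pre_onset(raw, onset if onset is not None else stim)
        dff = fi.to_dff(raw, f0, roi=roi)
        for t, v in zip(dff.series.times, dff.series.values):
            trace_rows.append({"roi": i, "time_s": t, "dff": v})
        slopes = fi.pre_post_slopes(dff.series, stim)
        row = {"roi": i, "onset_s": onset, "F0": f0,
               "slope_pre": slopes.slope_pre, "slope_post": slopes.slope_post}
        if direction in ("up", "down"):
            rm = fi.response_metrics(dff, stim, direction,
                                     search_window_s=float(cfg.param("search_window_s", 120.0)))
            if rm is not None:
                row.update(start_time_s=rm.start_time_s, time_to_peak_s=rm.time_to_peak_s,
                           amplitude=rm.amplitude)
        metric_rows.append(row)
    pd.DataFrame(trace_rows).to_csv(out / "traces.csv", index=False)
    pd.DataFrame(metric_rows).to_csv(out / "metrics.csv", index=False)
    return ["traces.csv", "metrics.csv"]


# ------------------------------------------------------------------ calcium

@register_stage("calcium")
def _stage_calcium(cfg: RunConfig, out: Path) -> list[str]:
    t_switch = float(cfg.param("t_switch_s", 300.0))
    guard = float(cfg.param("guard_s", 30.0))
    rows = []
    trace_paths = sorted(Path(cfg.require_input("traces")).glob("trace_*.csv"))
    if not trace_paths:
        raise FileNotFoundError("no trace_*.csv files under input.traces")
    for i, p in enumerate(trace_paths):
        tr = read_trace_csv(p)
        f0 = ca.f0_lowest_n(tr)
        dff = fi.to_dff(tr, f0)
        t_end = tr.t0 + tr.duration
        half = min(t_switch - guard - tr.t0, t_end - t_switch - guard)
        pre = ca.signal_strength_per_minute(dff, (t_switch - guard - half, t_switch - guard))
        post = ca.signal_strength_per_minute(dff, (t_switch + guard, t_switch + guard + half))
        rows.append(
            {"trace": i, "F0": f0, "strength_pre": pre.value, "strength_post": post.value,
             "ratio": post.value / pre.value if pre.value != 0 else float("nan")}
        )
    pd.DataFrame(rows).to_csv(out / "strengths.csv", index=False)
    return ["strengths.csv"]


# --------------------------------------------------------------- photometry

@register_stage("photometry")
def _stage_photometry(cfg: RunConfig, out: Path) -> list[str]:
    tr = read_trace_csv(cfg.require_input("trace"))
    t_inject = float(cfg.param("t_inject_s", 600.0))
    fit_start = float(cfg.param("fit_start_s", tr.t0))
    trend = ph.fit_linear_trend(tr, (fit_start, t_inject))
    metrics = ph.detrended_metrics(tr, trend, t_inject,
                                   range_method=str(cfg.param("range_method", "percentile")))
    pd.DataFrame([metrics.__dict__]).to_csv(out / "metrics.csv", index=False)
    outputs = ["metrics.csv"]
    if bool(cfg.param("qc_plot", False)):
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(8, 3))
            ax.plot(tr.times, tr.values, lw=0.5, label="trace")
            ax.plot(tr.times, trend[1] + trend[0] * tr.times, "k--", label="bleaching trend")
            ax.axvline(t_inject, color="r", lw=0.8, label="injection")
            ax.set_xlabel("time (s)")
            ax.legend(frameon=False)
            fig.savefig(out / "qc_trend.png", dpi=120, bbox_inches="tight")
            plt.close(fig)
            outputs.append("qc_trend.png")
        except ImportError:
            pass
    return outputs


# ------------------------------------------------------------------ ios-csd

@register_stage("ios-csd")
def _stage_ios_csd(cfg: RunConfig, out: Path) -> list[str]:
    stack = read_image_stack(
        cfg.require_input("stack"),
        pixel_size_um=float(cfg.param("pixel_size_um", 4.0)),
        frame_interval_s=float(cfg.param("frame_interval_s", 1.0)),
    )
    stim = float(cfg.param("stim_time_s", 10.0))
    baseline_frames = int(cfg.param("baseline_frames", max(int(stim / stack.frame_interval_s), 5)))
    dtt = ic.to_dtt(stack, baseline_frames)
    n_r, n_c = dtt.shape_rc
    line = (
        (float(cfg.param("line_r0", n_r / 2)), float(cfg.param("line_c0", 0.0))),
        (float(cfg.param("line_r1", n_r / 2)), float(cfg.param("line_c1", n_c - 1.0))),
    )
    kym = ic.make_kymograph(dtt, line, width_px=int(cfg.param("width_px", 5)))
    pd.DataFrame(kym.map).to_csv(out / "kymograph.csv", index=False)
    mid = kym.map.shape[0] // 2
    trace = kym.position_trace(mid)
    metrics = ic.csd_peak_metrics(trace, stim)
    rows = {}
    if metrics is not None:
        rows.update(onset_delay_s=metrics.onset_delay_s, peak1_amp=metrics.peak1_amp,
                    peak1_time_s=metrics.peak1_time_s, peak2_amp=metrics.peak2_amp,
                    peak2_time_s=metrics.peak2_time_s)
        if metrics.peak2_time_s is not None:
            kin = ic.swelling_kinetics(trace, metrics, stim)
            rows.update(swell_speed_per_s=kin.speed_per_s, swell_duration_s=kin.duration_s,
                        recovery_time_s=kin.recovery_time_s)
    try:
        ws = ic.estimate_wave_speed(kym, stim_time_s=stim)
        if ws is not None:
            rows.update(wave_speed_um_s=ws.speed_um_s, wave_direction=ws.direction)
    except ValueError:
        pass
    pd.DataFrame([rows] if rows else []).to_csv(out / "metrics.csv", index=False)
    return ["kymograph.csv", "metrics.csv"]


# ------------------------------------------------------------------ dwi-adc

@register_stage("dwi-adc")
def _stage_dwi_adc(cfg: RunConfig, out: Path) -> list[str]:
    series = read_dwi_series(
        cfg.require_input("volumes"),
        cfg.require_input("bvalues"),
        cfg.require_input("roi_labels"),
        time_spacing_s=float(cfg.param("time_spacing_s", 300.0)),
    )
    tc = da.adc_timecourse(series)
    tc.table.to_csv(out / "adc_timecourse.csv", index=False)
    ds = da.delta_adc(tc, baseline_indices=tuple(cfg.param("baseline_indices", (0, 1))))
    ds.table.to_csv(out / "delta_adc.csv", index=False)
    outputs = ["adc_timecourse.csv", "delta_adc.csv"]
    try:
        summary = da.summarize_post_window(ds, injection_index=int(cfg.param("injection_index", 2)))
    except ValueError:
        pass  # series too short for the default 30-50 min post-injection window
    else:
        summary.to_csv(out / "post_window_summary.csv", index=False)
        outputs.append("post_window_summary.csv")
    return outputs


# -------------------------------------------------------------------- stats

@register_stage("stats")
def _stage_stats(cfg: RunConfig, out: Path) -> list[str]:
    df = pd.read_csv(cfg.require_input("table"))
    res = st.group_compare(
        df,
        test=str(cfg.param("test", "t")),
        paired=bool(cfg.param("paired", False)),
    )
    res.to_csv(out / "stats.csv", index=False)
    return ["stats.csv"]
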