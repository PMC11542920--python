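"""Containers, file round-trips and pipeline reproducibility."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aquaflux import synth
from aquaflux.config import RunConfig, load_config
from aquaflux.core import DWISeries, ImageStack, RoiSpec, TimeSeries
from aquaflux.fit_imaging import estimate_background, extract_roi_trace
from aquaflux.io import (
    read_dwi_series,
    read_image_stack,
    read_trace_csv,
    write_dwi_series,
    write_image_stack,
    write_trace_csv,
)
from aquaflux.pipeline import run_pipeline


class TestTimeSeries:
    def test_sample_i_at_t0_plus_i_dt(self):
        ts = TimeSeries(np.arange(5.0), dt=1.0, t0=0.0)
        assert np.array_equal(ts.times, [0, 1, 2, 3, 4])
        assert ts.index_at(2.4) == 2 and ts.index_at(2.5) == 3  # half-up

    def test_rejects_bad_dt_and_empty(self):
        with pytest.raises(ValueError):
            TimeSeries(np.arange(3.0), dt=0.0)
        with pytest.raises(ValueError):
            TimeSeries(np.array([]), dt=1.0)

    def test_crop_preserves_time_origin(self):
        ts = TimeSeries(np.arange(10.0), dt=0.5, t0=1.0)
        sub = ts.crop(2.0, 4.0)
        assert sub.t0 == pytest.approx(2.0)
        assert sub.values[0] == ts.values[ts.index_at(2.0)]


class TestRoiSpec:
    def test_disc_mask_radius_in_um(self):
        roi = RoiSpec(center_rc=(16, 16), diameter_um=50.0)
        m = roi.mask((32, 32), pixel_size_um=2.0)
        # 25 px diameter disc: pixel centres within 12.5 px of the centre
        rr, cc = np.nonzero(m)
        assert np.hypot(rr - 16, cc - 16).max() <= 12.5 + 1e-9
        assert m.sum() == pytest.approx(np.pi * 12.5**2, rel=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            RoiSpec(center_rc=(500, 500), diameter_um=1.0).mask((32, 32), 2.0)


class TestTiffRoundTrip:
    def test_uint16_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        data = rng.integers(0, 2**16, size=(5, 12, 10), dtype=np.uint16)
        stack = ImageStack(data=data, pixel_size_um=1.5, frame_interval_s=2.0)
        p = tmp_path / "s.tif"
        write_image_stack(p, stack)
        back = read_image_stack(p, pixel_size_um=1.5, frame_interval_s=2.0)
        assert back.data.dtype == np.uint16
        assert np.array_equal(back.data, data)
        assert back.times[3] == pytest.approx(6.0)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_image_stack(tmp_path / "nope.tif", 1.0, 1.0)

    def test_rendered_stack_roundtrip_preserves_pipeline_output(
        self, tmp_path, noiseless_fit_scene
    ):
        stack, _, _ = noiseless_fit_scene
        p = tmp_path / "scene.tif"
        write_image_stack(p, stack)
        back = read_image_stack(p, stack.pixel_size_um, stack.frame_interval_s)
        roi = RoiSpec(center_rc=(32, 32))
        bg = estimate_background(stack)
        tr1 = extract_roi_trace(stack, roi, bg)
        tr2 = extract_roi_trace(back, roi, estimate_background(back))
        assert np.allclose(tr1.values, tr2.values, rtol=0, atol=1e-9)


class TestTraceCsv:
    def test_roundtrip_full_precision(self, tmp_path):
        ts = TimeSeries(np.random.default_rng(1).normal(size=50), dt=0.5, t0=3.0)
        p = tmp_path / "t.csv"
        write_trace_csv(p, ts)
        back = read_trace_csv(p)
        assert back.dt == pytest.approx(0.5)
        assert back.t0 == pytest.approx(3.0)
        assert np.allclose(back.values, ts.values, rtol=0, atol=1e-12)


@pytest.fixture()
def small_series():
    truth = synth.phantom_truth(n_time=14, SNR_b0=np.inf)
    labels = synth.make_phantom_labels(64, shape=(8, 8, 4))
    series, _ = synth.simulate_dwi_series(truth, labels, seed=0)
    return series


class TestDwiSeriesIO:
    def test_fourteen_timepoints_roundtrip(self, tmp_path, small_series):
        vt, bt, rt = write_dwi_series(tmp_path, small_series)
        back = read_dwi_series(vt, bt, rt)
        assert back.n_time == 14
        assert np.array_equal(back.bvalues, [0.0, 250.0, 1800.0])
        assert np.allclose(back.signals, small_series.signals, rtol=1e-6)
        assert np.array_equal(back.roi_labels, small_series.roi_labels)

    def test_shuffled_rows_reach_canonical_order(self, tmp_path, small_series):
        vt, bt, rt = write_dwi_series(tmp_path, small_series)
        df = pd.read_csv(vt).sample(frac=1.0, random_state=7)
        df.to_csv(vt, index=False)
        back = read_dwi_series(vt, bt, rt)
        assert np.allclose(back.signals, small_series.signals, rtol=1e-6)

    def test_missing_combination_rejected(self, tmp_path, small_series):
        vt, bt, rt = write_dwi_series(tmp_path, small_series)
        df = pd.read_csv(vt)
        df.drop(df.index[5], inplace=True)
        df.to_csv(vt, index=False)
        with pytest.raises(ValueError, match="missing volume"):
            read_dwi_series(vt, bt, rt)

    def test_single_bvalue_rejected(self):
        with pytest.raises(ValueError, match="2 distinct b-values"):
            DWISeries(
                signals=np.ones((2, 1, 2, 2, 2)),
                bvalues=np.array([0.0]),
                roi_labels=np.zeros((2, 2, 2), dtype=int),
            )


class TestPipeline:
    def test_same_config_same_bytes(self, tmp_path):
        cfgs = [
            RunConfig(stage="simulate", params={"scenario": "phantom", "n_voxels": 50},
                      seed=9, out_dir=str(tmp_path / f"r{i}"))
            for i in range(2)
        ]
        for c in cfgs:
            run_pipeline(c)
        a = (tmp_path / "r0" / "volumes.csv").read_bytes()
        b = (tmp_path / "r1" / "volumes.csv").read_bytes()
        assert a == b
        ga = (tmp_path / "r0" / "ground_truth.csv").read_bytes()
        gb = (tmp_path / "r1" / "ground_truth.csv").read_bytes()
        assert ga == gb

    def test_dwi_stage_schema_one_row_per_region_time(self, tmp_path):
        sim = RunConfig(stage="simulate", params={"scenario": "dwi", "n_time": 6},
                        seed=1, out_dir=str(tmp_path / "sim"))
        run_pipeline(sim)
        fit = RunConfig(
            stage="dwi-adc",
            inputs={"volumes": str(tmp_path / "sim" / "volumes.csv"),
                    "bvalues": str(tmp_path / "sim" / "bvalues.csv"),
                    "roi_labels": str(tmp_path / "sim" / "roi_labels.nii")},
            seed=1,
            out_dir=str(tmp_path / "fit"),
        )
        manifest = run_pipeline(fit)
        assert manifest["seed"] == 1
        tc = pd.read_csv(tmp_path / "fit" / "adc_timecourse.csv")
        assert len(tc) == 2 * 6  # two regions x six scans
        assert set(tc.columns) >= {"region", "time_index", "adc_mean", "n_failed"}

    def test_missing_input_names_the_key(self, tmp_path):
        cfg = RunConfig(stage="dwi-adc", out_dir=str(tmp_path / "x"))
        with pytest.raises(KeyError, match="input.volumes"):
            run_pipeline(cfg)

    def test_unknown_stage_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown stage"):
            run_pipeline(RunConfig(stage="frobnicate", out_dir=str(tmp_path)))


class TestConfig:
    def test_flat_keys_partition(self, tmp_path):
        p = tmp_path / "cfg.yml"
        p.write_text(
            "stage: dwi-adc\nseed: 7\nout_dir: out\n"
            "input.volumes: v.csv\ntime_spacing_s: 300\n"
        )
        cfg = load_config(p)
        assert cfg.stage == "dwi-adc"
        assert cfg.seed == 7
        assert cfg.inputs == {"volumes": "v.csv"}
        assert cfg.params == {"time_spacing_s": 300}

    def test_missing_stage_key(self, tmp_path):
        p = tmp_path / "cfg.yml"
        p.write_text("seed: 1\n")
        with pytest.raises(ValueError, match="stage"):
            load_config(p)


class TestCli:
    def test_simulate_phantom_command(self, tmp_path):
        from click.testing import CliRunner

        from aquaflux.cli import main

        res = CliRunner().invoke(
            main,
            ["simulate", "--scenario", "phantom", "--seed", "4",
             "--out", str(tmp_path / "run")],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "run" / "manifest.json").exists()
        assert (tmp_path / "run" / "volumes.csv").exists()
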