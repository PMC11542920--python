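"""FIT stage: background, ROI traces, onset, F0, dF/F0, slopes, kinetics."""
from __future__ import annotations

import numpy as np
import pytest

from aquaflux import synth
from aquaflux.core import ImageStack, RoiSpec, TimeSeries
from aquaflux.fit_imaging import (
    compute_f0_pre_onset,
    detect_onset,
    estimate_background,
    extract_roi_trace,
    pre_post_slopes,
    response_metrics,
    to_dff,
)


class TestBackground:
    def test_uniform_stack_gives_its_value(self, uniform_stack):
        bg = estimate_background(uniform_stack)
        assert np.allclose(bg, 7.0)

    def test_recovers_generator_offset(self, noiseless_fit_scene):
        stack, _, imaging = noiseless_fit_scene
        bg = estimate_background(stack)  # auto border tiles; cell is central
        assert np.allclose(bg, imaging.background_offset, atol=1e-9)

    def test_explicit_region_overlapping_cell_roi_rejected(self, uniform_stack):
        roi = RoiSpec((16, 16), 30.0)
        with pytest.raises(ValueError, match="overlaps"):
            estimate_background(uniform_stack, regions=[roi], cell_rois=[roi])

    def test_field_smaller_than_subregion_rejected(self):
        tiny = ImageStack(np.ones((3, 4, 4)), pixel_size_um=1.0, frame_interval_s=1.0)
        with pytest.raises(ValueError, match="smaller"):
            estimate_background(tiny, subregion_um=15.0)


class TestRoiTrace:
    def test_disc_over_uniform_minus_background(self, uniform_stack):
        stack = ImageStack(
            np.full((5, 32, 32), 100.0), pixel_size_um=2.0, frame_interval_s=1.0
        )
        tr = extract_roi_trace(stack, RoiSpec((16, 16), 20.0), background=10.0)
        assert np.allclose(tr.values, 90.0)

    def test_noiseless_cell_equals_dilution_formula(self, noiseless_fit_scene):
        stack, truth, imaging = noiseless_fit_scene
        bg = estimate_background(stack)
        tr = extract_roi_trace(stack, RoiSpec((32, 32), 50.0), bg)
        assert np.allclose(tr.values, truth["intensity_true"], rtol=1e-10)


class TestOnsetDetection:
    def test_flat_noisy_trace_has_no_onset(self):
        rng = np.random.default_rng(0)
        tr = TimeSeries(100 + rng.normal(0, 1, 400), dt=1.0)
        assert detect_onset(tr, stim_time_s=200.0, direction="either") is None

    def test_step_onset_located_within_one_sample(self):
        rng = np.random.default_rng(1)
        v = 100 + rng.normal(0, 1.0, 300)
        v[100:] += 5.0  # 5 sigma step at frame 100, stim at frame 90
        tr = TimeSeries(v, dt=1.0)
        onset = detect_onset(tr, stim_time_s=90.0, direction="up")
        assert onset is not None and 100.0 <= onset <= 101.0

    def test_never_fires_before_stimulus(self):
        v = np.concatenate([np.zeros(50), np.linspace(0, 10, 100)])
        tr = TimeSeries(v, dt=1.0)
        onset = detect_onset(tr, stim_time_s=49.0, direction="up",
                             baseline_window_s=(0.0, 40.0))
        assert onset is not None and onset >= 49.0

    def test_zero_variance_baseline_uses_epsilon_fallback(self):
        v = np.concatenate([np.full(20, 10.0), np.full(20, 11.0)])
        tr = TimeSeries(v, dt=1.0)
        onset = detect_onset(tr, stim_time_s=19.0, direction="up")
        assert onset == pytest.approx(20.0)


class TestF0AndDff:
    def test_mean_of_ten_points_before_onset(self):
        tr = TimeSeries(np.arange(100.0), dt=1.0)
        # onset at index 50: mean of samples 40..49 = 44.5
        assert compute_f0_pre_onset(tr, onset_time_s=50.0, n=10) == pytest.approx(44.5)

    def test_insufficient_pre_onset_samples(self):
        tr = TimeSeries(np.arange(20.0), dt=1.0)
        with pytest.raises(ValueError, match="before onset"):
            compute_f0_pre_onset(tr, onset_time_s=5.0, n=10)

    def test_dff_of_constant_and_doubled(self):
        tr = TimeSeries(np.full(10, 50.0), dt=1.0)
        assert np.allclose(to_dff(tr, 50.0).series.values, 0.0)
        assert np.allclose(to_dff(tr, 25.0).series.values, 1.0)
        with pytest.raises(ValueError):
            to_dff(tr, 0.0)


class TestSlopes:
    def test_flat_trace_zero_slopes(self):
        tr = TimeSeries(np.full(200, 3.0), dt=1.0)
        sp = pre_post_slopes(tr, t_event_s=100.0)
        assert sp.slope_pre == pytest.approx(0.0, abs=1e-12)
        assert sp.slope_post == pytest.approx(0.0, abs=1e-12)

    def test_piecewise_linear_recovered_exactly(self):
        t = np.arange(200.0)
        v = np.where(t < 100, 0.0, -0.001 * (t - 100))
        sp = pre_post_slopes(TimeSeries(v, dt=1.0), 100.0, (0.0, 99.0), (100.0, 199.0))
        assert sp.slope_pre == pytest.approx(0.0, abs=1e-12)
        assert sp.slope_post == pytest.approx(-0.001, rel=1e-9)

    def test_aquaporin_block_scenario_steepens_decline(self):
        # tonic source balanced pre-block; block at t=300 s -> swelling ->
        # dye dilution -> fluorescence decline steepens (slope_post < slope_pre)
        p = synth.OsmoticParams(g_aqp=2.0, g_leak=0.5, J_met=1.0)
        proto = synth.ChallengeProtocol(
            c_out=(300.0, 300.0), breakpoints=(0.0, 300.0), duration=600.0,
            block=(0.0, 1.0),
        )
        vt = synth.simulate_osmotic_volume(p, proto, dt=0.2)
        dff = TimeSeries(vt.params.V0 / vt.series.values - 1.0, dt=0.2)
        sp = pre_post_slopes(dff, 300.0)
        assert sp.slope_post < sp.slope_pre


class TestResponseMetrics:
    @staticmethod
    def _dff_from(values, dt=1.0):
        tr = TimeSeries(np.asarray(values, dtype=float) + 100.0, dt=dt)
        return to_dff(tr, 100.0)

    def test_flat_trace_metrics_absent(self):
        rng = np.random.default_rng(2)
        dff = self._dff_from(rng.normal(0, 0.01, 300))
        assert response_metrics(dff, 150.0, "up") is None

    def test_constructed_peak_time_and_amplitude(self):
        # rise begins at stim (t=100 s), peaks at +0.2 dF/F0 40 s later
        t = np.arange(300.0)
        v = np.zeros_like(t)
        ramp = (t >= 100) & (t <= 140)
        v[ramp] = 0.2 * (t[ramp] - 100) / 40.0
        v[t > 140] = np.maximum(0.2 - 0.004 * (t[t > 140] - 140), 0.0)
        m = response_metrics(self._dff_from(100 * v), 100.0, "up", search_window_s=120.0)
        assert m is not None
        assert m.time_to_peak_s == pytest.approx(40.0, abs=1.0)
        assert m.amplitude == pytest.approx(0.2, rel=1e-6)
        assert m.start_time_s <= m.time_to_peak_s


class TestEndToEndRecovery:
    @pytest.mark.parametrize("c_challenge,direction", [(400.0, "up"), (100.0, "down")])
    def test_rendered_scenario_recovery(self, c_challenge, direction):
        params = synth.OsmoticParams()
        proto = synth.ChallengeProtocol(
            c_out=(300.0, c_challenge, 300.0), breakpoints=(0.0, 60.0, 120.0),
            duration=240.0,
        )
        vt = synth.simulate_osmotic_volume(params, proto, dt=0.2)
        imaging = synth.ImagingParams(noise_sd=10.0)  # 1% of F0_scale
        stack, truth = synth.render_fit_stack([vt], [(32.0, 32.0)], imaging, seed=8)
        bg = estimate_background(stack)
        raw = extract_roi_trace(stack, RoiSpec((32, 32), 50.0), bg)
        onset = detect_onset(raw, 60.0, direction=direction)
        assert onset is not None and abs(onset - 60.0) <= 2.0
        f0 = compute_f0_pre_onset(raw, onset)
        dff = to_dff(raw, f0)
        m = response_metrics(dff, 60.0, direction, search_window_s=90.0)
        assert m is not None
        true_amp = np.abs(truth["dff_true"]).max()
        assert m.amplitude == pytest.approx(true_amp, rel=0.05)

    def test_dff_invariant_to_affine_intensity_scaling(self, osmotic_challenge_trace):
        imaging = synth.ImagingParams(noise_sd=0.0)
        stack, _ = synth.render_fit_stack(
            [osmotic_challenge_trace], [(32.0, 32.0)], imaging
        )
        scaled = ImageStack(
            2.5 * stack.data + 40.0, stack.pixel_size_um, stack.frame_interval_s
        )
        dffs = []
        for s in (stack, scaled):
            bg = estimate_background(s)
            raw = extract_roi_trace(s, RoiSpec((32, 32), 50.0), bg)
            onset = detect_onset(raw, 60.0, direction="up")
            dffs.append(to_dff(raw, compute_f0_pre_onset(raw, onset)).series.values)
        assert np.allclose(dffs[0], dffs[1], atol=1e-9)

    def test_amplitude_monotone_in_challenge_magnitude(self):
        # hypotonic 300→250 vs 300→100: stronger challenge, larger swelling amplitude
        amps = []
        for c in (250.0, 100.0):
            proto = synth.ChallengeProtocol(
                c_out=(300.0, c, 300.0), breakpoints=(0.0, 60.0, 140.0), duration=260.0
            )
            vt = synth.simulate_osmotic_volume(synth.OsmoticParams(), proto, dt=0.2)
            stack, _ = synth.render_fit_stack(
                [vt], [(32.0, 32.0)], synth.ImagingParams(noise_sd=5.0), seed=3
            )
            bg = estimate_background(stack)
            raw = extract_roi_trace(stack, RoiSpec((32, 32), 50.0), bg)
            onset = detect_onset(raw, 60.0, direction="down")
            dff = to_dff(raw, compute_f0_pre_onset(raw, onset))
            amps.append(response_metrics(dff, 60.0, "down", 120.0).amplitude)
        assert amps[1] > amps[0]
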