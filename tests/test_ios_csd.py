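"""Intrinsic-optical-signal CSD analysis: dT/T0, kymographs, peaks, speed."""
from __future__ import annotations

import numpy as np
import pytest

from aquaflux import synth
from aquaflux.core import ImageStack, TimeSeries
from aquaflux.ios_csd import (
    CSDMetrics,
    csd_peak_metrics,
    estimate_wave_speed,
    make_kymograph,
    swelling_kinetics,
    to_dtt,
)


@pytest.fixture(scope="module")
def rendered_wave():
    wave = synth.CSDWaveParams(origin_px=(24.0, 0.0), speed_um_s=50.0, noise_sd=0.0)
    stack, truth = synth.render_csd_stack(
        wave, field_shape_rc=(48, 100), pixel_size_um=4.0, duration_s=120.0
    )
    return stack, truth


class TestToDtt:
    def test_constant_stack_all_zero(self, uniform_stack):
        dtt = to_dtt(uniform_stack, baseline_frames=5)
        assert np.allclose(dtt.data, 0.0)

    def test_doubled_frame_gives_unity(self):
        data = np.ones((10, 8, 8))
        data[7] = 2.0
        stack = ImageStack(data, pixel_size_um=1.0, frame_interval_s=1.0)
        dtt = to_dtt(stack, baseline_frames=5)
        assert np.allclose(dtt.data[7], 1.0)

    def test_matches_generator_field(self, rendered_wave):
        stack, truth = rendered_wave
        dtt = to_dtt(stack, baseline_frames=9)  # pre-stim frames, noiseless
        assert np.allclose(dtt.data, truth.dtt, atol=1e-12)

    def test_gain_invariance(self, rendered_wave):
        stack, _ = rendered_wave
        gained = ImageStack(3.0 * stack.data, stack.pixel_size_um, stack.frame_interval_s)
        assert np.allclose(
            to_dtt(stack, 9).data, to_dtt(gained, 9).data, atol=1e-12
        )

    def test_baseline_too_short_rejected(self, uniform_stack):
        with pytest.raises(ValueError):
            to_dtt(uniform_stack, baseline_frames=3)


class TestKymograph:
    def test_constant_input_constant_map(self, uniform_stack):
        dtt = to_dtt(uniform_stack, 5)
        kym = make_kymograph(dtt, ((16.0, 2.0), (16.0, 30.0)))
        assert np.allclose(kym.map, 0.0)
        assert kym.map.shape == (29, uniform_stack.n_frames)

    def test_averaging_commutes_with_dtt_noiseless(self, rendered_wave):
        stack, _ = rendered_wave
        line = ((24.0, 0.0), (24.0, 99.0))
        kym_of_dtt = make_kymograph(to_dtt(stack, 9), line)
        kym_raw = make_kymograph(stack_as_is(stack), line)
        t0 = kym_raw.map[:, :9].mean(axis=1, keepdims=True)
        assert np.allclose(kym_of_dtt.map, (kym_raw.map - t0) / t0, atol=1e-12)

    def test_endpoints_validated(self, uniform_stack):
        dtt = to_dtt(uniform_stack, 5)
        with pytest.raises(ValueError):
            make_kymograph(dtt, ((0.0, 0.0), (200.0, 0.0)))


def stack_as_is(stack):
    # raw transmittance reinterpreted as a map-able stack (same container)
    return ImageStack(stack.data.astype(float), stack.pixel_size_um, stack.frame_interval_s)


class TestPeakMetrics:
    def test_flat_trace_absent(self):
        rng = np.random.default_rng(0)
        tr = TimeSeries(rng.normal(0, 0.001, 200), dt=1.0)
        assert csd_peak_metrics(tr, stim_time_s=20.0) is None

    def test_constructed_two_bump_trace(self):
        t = np.arange(200.0)
        bump = lambda mu, sig, amp: amp * np.exp(-0.5 * ((t - mu) / sig) ** 2)
        v = bump(40.0, 5.0, 0.05) + bump(100.0, 12.0, 0.08)  # peaks 20/80 s post stim
        m = csd_peak_metrics(TimeSeries(v, dt=1.0), stim_time_s=20.0)
        assert m is not None
        assert m.peak1_time_s == pytest.approx(20.0, abs=1.0)
        assert m.peak1_amp == pytest.approx(0.05, abs=0.005)
        assert m.peak2_time_s == pytest.approx(80.0, abs=1.0)
        assert m.peak2_amp == pytest.approx(0.08, abs=0.005)
        assert m.onset_delay_s <= m.peak1_time_s

    def test_rendered_trace_peaks_near_kernel_truth(self, rendered_wave):
        stack, truth = rendered_wave
        dtt = to_dtt(stack, 9)
        r, c = 24, 25  # 100 µm from origin -> arrival at stim + 2 s
        tr = TimeSeries(dtt.data[:, r, c], dt=1.0)
        stim = truth.params.stim_time_s
        m = csd_peak_metrics(tr, stim_time_s=stim)
        assert m is not None and m.peak2_time_s is not None
        # brute-force extrema of the noiseless generator field: peak 1 is the
        # global maximum (amp1 > amp2); peak 2 the late-segment maximum
        g = truth.dtt[:, r, c]
        t1_true = float(np.argmax(g))
        late = int(t1_true) + 20
        t2_true = late + float(np.argmax(g[late:]))
        assert abs((m.peak1_time_s + stim) - t1_true) <= 2.0
        assert abs((m.peak2_time_s + stim) - t2_true) <= 2.0


class TestSwellingKinetics:
    @staticmethod
    def _triangle(h=0.1, w=30.0, dt=0.1, pre=60.0, post=200.0):
        t = np.arange(0.0, pre + 2 * w + post, dt)
        v = np.zeros_like(t)
        up = (t >= pre) & (t < pre + w)
        down = (t >= pre + w) & (t <= pre + 2 * w)
        v[up] = h * (t[up] - pre) / w
        v[down] = h * (1.0 - (t[down] - pre - w) / w)
        return TimeSeries(v, dt=dt), pre + w

    def test_triangle_closed_form(self):
        h, w = 0.1, 30.0
        tr, t_peak = self._triangle(h, w)
        # ramp starts at t=60 s (onset delay 10 s after the t=50 s stimulus)
        m = CSDMetrics(
            onset_delay_s=10.0, peak1_amp=h,
            peak1_time_s=t_peak - 50.0, peak2_amp=h, peak2_time_s=t_peak - 50.0,
        )
        kin = swelling_kinetics(tr, m, stim_time_s=50.0, baseline_level=0.0)
        assert kin.speed_per_s == pytest.approx(h / w, rel=1e-6)
        assert kin.duration_s == pytest.approx(w, abs=2 * tr.dt)
        # re-entry into baseline ± 0.1 h happens 0.9 w after the peak
        assert kin.recovery_time_s == pytest.approx(0.9 * w, abs=2 * tr.dt)

    def test_plateau_never_recovers(self):
        t = np.arange(0.0, 300.0)
        v = np.where(t < 50, 0.0, np.minimum((t - 50) / 20.0, 1.0)) * 0.1
        tr = TimeSeries(v, dt=1.0)
        m = CSDMetrics(onset_delay_s=0.0, peak1_amp=0.1, peak1_time_s=30.0,
                       peak2_amp=0.1, peak2_time_s=30.0)
        kin = swelling_kinetics(tr, m, stim_time_s=40.0, baseline_level=0.0)
        assert kin.recovery_time_s is None

    def test_peak2_absent_rejected(self):
        tr = TimeSeries(np.zeros(100), dt=1.0)
        m = CSDMetrics(onset_delay_s=1.0, peak1_amp=0.1, peak1_time_s=5.0)
        with pytest.raises(ValueError, match="peak 2"):
            swelling_kinetics(tr, m, stim_time_s=10.0)

    def test_slower_decay_prolongs_recovery(self):
        recoveries = []
        for tau2 in (40.0, 120.0):
            wave = synth.CSDWaveParams(
                origin_px=(2.0, 2.0), tau_decay2_s=tau2, noise_sd=0.0
            )
            stack, _ = synth.render_csd_stack(
                wave, field_shape_rc=(5, 5), pixel_size_um=4.0, duration_s=600.0
            )
            dtt = to_dtt(stack, 9)
            tr = TimeSeries(dtt.data[:, 2, 2], dt=1.0)
            m = csd_peak_metrics(tr, stim_time_s=10.0)
            kin = swelling_kinetics(tr, m, stim_time_s=10.0)
            recoveries.append(kin.recovery_time_s)
        assert recoveries[1] > recoveries[0]


class TestWaveSpeed:
    def _kym(self, speed, noise_sd, seed=0, reverse=False):
        origin = (24.0, 99.0) if reverse else (24.0, 0.0)
        wave = synth.CSDWaveParams(origin_px=origin, speed_um_s=speed, noise_sd=noise_sd)
        stack, _ = synth.render_csd_stack(
            wave, field_shape_rc=(48, 100), pixel_size_um=4.0, duration_s=60.0, seed=seed
        )
        dtt = to_dtt(stack, 9)
        return make_kymograph(dtt, ((24.0, 0.0), (24.0, 99.0)))

    def test_recovery_within_ten_percent_at_moderate_noise(self):
        kym = self._kym(50.0, noise_sd=0.05 * 0.08, seed=5)
        est = estimate_wave_speed(kym, stim_time_s=10.0)
        assert est is not None
        assert est.speed_um_s == pytest.approx(50.0, rel=0.10)
        assert est.direction == 1

    def test_reversed_wave_same_magnitude_flipped_direction(self):
        est = estimate_wave_speed(self._kym(50.0, 0.0, reverse=True), stim_time_s=10.0)
        assert est is not None
        assert est.speed_um_s == pytest.approx(50.0, rel=0.05)
        assert est.direction == -1

    def test_simultaneous_onset_returns_none(self):
        # a global (non-propagating) transient: same time course everywhere
        t = np.arange(60.0)
        k = synth.csd_kernel(t - 15.0, 1.0, 5.0)
        data = 1000.0 * (1.0 + 0.08 * k)[:, None, None] * np.ones((1, 8, 40))
        stack = ImageStack(data, pixel_size_um=4.0, frame_interval_s=1.0)
        kym = make_kymograph(to_dtt(stack, 9), ((4.0, 0.0), (4.0, 39.0)))
        assert estimate_wave_speed(kym, stim_time_s=10.0) is None

    def test_fewer_than_five_onsets_raises(self):
        rng = np.random.default_rng(1)
        data = 1000.0 + rng.normal(0, 1.0, (60, 8, 40))
        stack = ImageStack(data, pixel_size_um=4.0, frame_interval_s=1.0)
        kym = make_kymograph(to_dtt(stack, 9), ((4.0, 0.0), (4.0, 39.0)))
        with pytest.raises(ValueError, match=">= 5 onsets"):
            estimate_wave_speed(kym, stim_time_s=10.0)
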