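"""Intracellular analytics: thresholds, Vm distributions, RMR, FV-curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import regimescope as rs
from regimescope.intracellular import FVCurve, VmTrace
from regimescope.synthetic import _ou_current
from conftest import fluct_params, mean_params

FS = 20000.0


class TestPeakDetection:
    def test_flat_trace_has_no_peaks(self):
        tr = VmTrace(np.full(1000, -60.0), FS)
        assert rs.detect_spike_peaks(tr).size == 0

    def test_peaks_match_ground_truth(self, fluct_recording):
        tr = VmTrace(fluct_recording.vm, fluct_recording.sampling_rate)
        peaks = rs.detect_spike_peaks(tr)
        truth = fluct_recording.true_spike_times
        assert peaks.size == truth.size
        assert np.max(np.abs(peaks - truth)) <= 1.0 / tr.sampling_rate

    def test_close_peaks_keep_larger(self):
        v = np.full(200, -60.0)
        v[100] = 5.0
        v[110] = 10.0          # 0.5 ms later, larger
        tr = VmTrace(v, FS)
        peaks = rs.detect_spike_peaks(tr, min_separation_ms=1.0)
        assert peaks.size == 1
        assert np.isclose(peaks[0], 110 / FS)


class TestPhasePlaneThreshold:
    def test_recovers_programmed_threshold(self, fluct_spikes):
        _, spikes = fluct_spikes
        assert spikes.n >= 100
        assert abs(spikes.mean_threshold - (-45.0)) < 1.0

    def test_kink_trace_threshold_at_junction(self):
        # slow depolarizing ramp joined to a steep rise: the acceleration
        # (second phase-plane derivative) is concentrated at the junction
        fs = 10000.0
        slow = -60.0 + 0.5 * np.arange(0, 100) * 0.1      # 0.5 mV/ms, 10 ms
        steep_n = int(np.ceil((20.0 - slow[-1]) / 2.0))
        steep = slow[-1] + 2.0 * np.arange(1, steep_n + 1)  # 20 mV/ms
        v = np.concatenate([np.full(300, -60.0), slow, steep,
                            np.full(100, -60.0)])
        tr = VmTrace(v, fs)
        peak_t = (300 + 100 + steep_n - 1) / fs
        spikes = rs.estimate_thresholds_phase_plane(tr, np.array([peak_t]))
        assert abs(spikes.threshold_mV[0] - slow[-1]) < 1.0

    def test_adaptation_raises_threshold_with_rate(self):
        p = fluct_params(mean_input_current=0.12,
                         threshold_adaptation_increment=1.0,
                         threshold_recovery_tau=80.0)
        rec = rs.simulate_two_regime_neuron(p, 40.0, dt=0.05, seed=3)
        tr = VmTrace(rec.vm, rec.sampling_rate)
        spikes = rs.estimate_thresholds_phase_plane(
            tr, rs.detect_spike_peaks(tr))
        rate = 1.0 / np.diff(spikes.peak_times)
        shift = spikes.threshold_mV[1:] - spikes.threshold_q5
        r, _, _ = rs.correlate(rate, shift)
        assert r > 0.3

    def test_quantile_threshold_below_mean(self, fluct_spikes):
        _, spikes = fluct_spikes
        assert spikes.threshold_q5 <= spikes.mean_threshold


class TestVmDistributions:
    def test_constant_pre_spike_samples_degenerate(self):
        v = np.full(int(FS), -50.0)
        peaks = np.arange(0.1, 0.95, 0.1)
        spikes = rs.SpikeEvents(peaks, peaks - 0.001,
                                np.full(peaks.size, -45.0))
        d = rs.spike_triggered_distribution(VmTrace(v, FS), spikes)
        assert d.sd == 0.0
        assert d.skewness == 0.0
        assert d.degenerate

    def test_fluctuation_regime_sigma_skewness_bounded(self, fluct_spikes):
        tr, spikes = fluct_spikes
        d = rs.spike_triggered_distribution(tr, spikes)
        assert abs(d.skewness) < 0.5
        assert d.n >= 10

    def test_temporal_and_triggered_means_agree(self, fluct_spikes):
        tr, spikes = fluct_spikes
        td = rs.temporal_distribution(tr, spikes)
        sd = rs.spike_triggered_distribution(tr, spikes)
        assert abs(td.mean - sd.mean) < 1.0

    def test_sine_between_spikes_symmetric(self):
        t = np.arange(int(2 * FS)) / FS
        v = -55.0 + 3.0 * np.sin(2 * np.pi * 10 * t)
        peaks = np.array([0.5, 0.6, 0.7, 0.8])
        spikes = rs.SpikeEvents(peaks, peaks - 0.001,
                                np.full(4, -45.0))
        d = rs.temporal_distribution(VmTrace(v, FS), spikes)
        assert abs(d.skewness) < 0.3

    def test_no_retained_samples_is_error(self):
        v = np.full(int(FS), -60.0)
        peaks = np.array([0.1, 0.104])     # 4 ms ISI: below the 6 ms filter
        spikes = rs.SpikeEvents(peaks, peaks - 0.001, np.full(2, -45.0))
        with pytest.raises(ValueError):
            rs.temporal_distribution(VmTrace(v, FS), spikes)


class TestReturnMapRatio:
    def _sawtooth(self, n_teeth=30, tooth_ms=100.0):
        n = int(tooth_ms * 1e-3 * FS)
        ramp = np.linspace(-60.0, -45.0, n)
        v = np.tile(ramp, n_teeth)
        peaks = (np.arange(1, n_teeth) * n - 1) / FS
        return VmTrace(v, FS), peaks

    def test_monotone_ramps_give_exactly_one(self):
        tr, peaks = self._sawtooth()
        assert rs.return_map_ratio(tr, peaks) == 1.0

    def test_decreasing_segments_give_zero(self):
        tr, peaks = self._sawtooth()
        flipped = VmTrace(-tr.samples, FS)
        assert rs.return_map_ratio(flipped, peaks) == 0.0

    def test_zero_drift_noise_near_half(self):
        rng = np.random.default_rng(2)
        v = -60.0 + _ou_current(200000, 3.0, 10.0, 1e3 / FS, rng)
        ratio = rs.return_map_ratio(VmTrace(v, FS))
        assert abs(ratio - 0.5) < 0.02

    def test_time_reversal_complements(self):
        rng = np.random.default_rng(5)
        v = -60.0 + np.cumsum(rng.standard_normal(50000)) * 0.01
        fwd = rs.return_map_ratio(VmTrace(v, FS))
        rev = rs.return_map_ratio(VmTrace(v[::-1].copy(), FS))
        assert np.isclose(fwd + rev, 1.0)

    def test_interburst_segments_excluded(self):
        # ramps separated by a 400 ms decreasing gap: the gap ISI exceeds
        # the 300 ms interburst limit and is removed, so the ratio stays 1
        n = int(0.1 * FS)
        ramp = np.linspace(-60, -45, n)
        gap = np.linspace(-45, -60, int(0.4 * FS))
        v = np.concatenate([ramp, ramp, gap, ramp, ramp])
        ends = np.array([n, 2 * n, 2 * n + gap.size + n,
                         2 * n + gap.size + 2 * n])
        peaks = (ends - 1) / FS
        tr = VmTrace(v, FS)
        assert rs.return_map_ratio(tr, peaks) == 1.0


class TestTimeBelowThreshold:
    def test_always_below_and_above(self):
        tr = VmTrace(np.full(1000, -55.0), FS)
        assert rs.time_below_threshold(tr, -45.0) == 1.0
        assert rs.time_below_threshold(tr, -65.0) == 0.0

    def test_regime_ordering(self, fluct_recording, mean_recording):
        thr = -45.0
        f = rs.time_below_threshold(
            VmTrace(fluct_recording.vm, fluct_recording.sampling_rate), thr)
        m = rs.time_below_threshold(
            VmTrace(mean_recording.vm, mean_recording.sampling_rate), thr)
        assert f > 0.5 > m


class TestFVCurve:
    def test_rate_definition(self):
        # 10 s of residence in one bin with 5 pre-spike samples -> 0.5 Hz
        v = np.full(int(10 * FS), -50.2)
        peaks = np.arange(1.0, 6.0)
        curve = rs.estimate_fv_curve(VmTrace(v, FS), peaks)
        assert curve.vm_bin_centers.size == 1
        assert np.isclose(curve.rate_hz[0], 0.5)

    def test_exponential_fit_identity(self):
        v = np.linspace(-60, -45, 20)
        curve = FVCurve(v, np.ones_like(v), np.zeros_like(v),
                        2.0 * np.exp(0.5 * v), 5e-5)
        fit = rs.fit_fv_exponential(curve)
        assert fit["converged"]
        assert abs(fit["c"] - 2.0) < 1e-6
        assert abs(fit["beta"] - 0.5) < 1e-6

    def test_powerlaw_fit_identity(self):
        v = np.linspace(-60, -45, 20)
        curve = FVCurve(v, np.ones_like(v), np.zeros_like(v),
                        0.3 * (v + 62.0) ** 3, 5e-5)
        fit = rs.fit_fv_powerlaw(curve)
        assert fit["converged"]
        assert abs(fit["alpha"] - 3.0) < 1e-4
        assert abs(fit["Ea"] - (-62.0)) < 1e-4

    def test_hazard_recovery_binwise(self, hazard_recording):
        rec = hazard_recording
        tr = VmTrace(rec.vm, rec.sampling_rate)
        curve = rs.estimate_fv_curve(tr, rec.true_spike_times)
        true = 6.2e12 * np.exp(0.5 * curve.vm_bin_centers)
        well = curve.residence_time_s > 5.0
        rel = np.abs(curve.rate_hz[well] - true[well]) \
            / np.maximum(true[well], 1e-12)
        # attenuation from the 1.7 ms pre-spike lag plus counting noise
        assert np.median(rel) < 0.35

    def test_hazard_beta_recovery(self, hazard_recording):
        rec = hazard_recording
        assert rec.true_spike_times.size >= 500
        tr = VmTrace(rec.vm, rec.sampling_rate)
        curve = rs.estimate_fv_curve(tr, rec.true_spike_times)
        fit = rs.fit_fv_exponential(curve, log_domain=True)
        assert fit["converged"]
        assert abs(fit["beta"] - 0.5) / 0.5 < 0.2

    def test_mean_driven_noiseless_has_empty_subthreshold_bins(self):
        p = mean_params(current_noise_sd=0.0)
        rec = rs.simulate_two_regime_neuron(p, 5.0, dt=0.05, seed=0)
        tr = VmTrace(rec.vm, rec.sampling_rate)
        curve = rs.estimate_fv_curve(tr, rec.true_spike_times)
        deep = curve.vm_bin_centers < -48.0
        assert np.all(curve.pre_spike_counts[deep] == 0)

    def test_too_few_bins_skips_fit(self):
        v = np.array([-50.0, -49.5])
        curve = FVCurve(v, np.ones(2), np.zeros(2), np.ones(2), 5e-5)
        assert not rs.fit_fv_exponential(curve)["converged"]


class TestThresholdDistance:
    def test_arithmetic(self):
        d = rs.VmDistribution(np.empty(0), np.empty(0), -60.0, 5.0, 0.0,
                              "temporal", 100)
        peaks = np.array([0.1])
        spikes = rs.SpikeEvents(peaks, peaks - 0.001, np.array([-45.0]))
        assert np.isclose(rs.normalized_threshold_distance(d, spikes), -3.0)
        d_at = rs.VmDistribution(np.empty(0), np.empty(0), -45.0, 5.0, 0.0,
                                 "temporal", 100)
        assert rs.normalized_threshold_distance(d_at, spikes) == 0.0

    def test_zero_sigma_is_error(self):
        d = rs.VmDistribution(np.empty(0), np.empty(0), -60.0, 0.0, 0.0,
                              "temporal", 100)
        peaks = np.array([0.1])
        spikes = rs.SpikeEvents(peaks, peaks - 0.001, np.array([-45.0]))
        with pytest.raises(ValueError):
            rs.normalized_threshold_distance(d, spikes)

    def test_programmed_three_sigma_distance_recovered(self):
        # drive set so the free mean sits ~3 sigma_V below threshold
        p = fluct_params(mean_input_current=0.06)
        rec = rs.simulate_two_regime_neuron(p, 120.0, dt=0.05, seed=13)
        tr = VmTrace(rec.vm, rec.sampling_rate)
        spikes = rs.estimate_thresholds_phase_plane(
            tr, rs.detect_spike_peaks(tr))
        td = rs.temporal_distribution(tr, spikes)
        dist = rs.normalized_threshold_distance(td, spikes)
        assert -4.0 < dist < -2.0


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(-80, -20), min_size=40, max_size=200))
def test_rmr_is_bounded(vals):
    v = np.asarray(vals)
    tr = VmTrace(v, 1000.0)
    try:
        ratio = rs.return_map_ratio(tr, lag_ms=2.0)
    except ValueError:
        return
    assert 0.0 <= ratio <= 1.0
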