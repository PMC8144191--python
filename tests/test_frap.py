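import math

import numpy as np
import pytest

from azquant import frap
from azquant.synth import FRAPTraceSpec, render_frap_trace


def make_trace(values, dt=1.0, bleach_frames=None, n_baseline=2):
    return frap.FRAPTrace(
        times_s=np.arange(len(values)) * dt,
        intensities=np.asarray(values, dtype=float),
        bleach_frames=bleach_frames,
        n_baseline_frames=n_baseline,
    )


class TestNormalization:
    def test_divides_by_baseline(self):
        trace = make_trace([200, 200, 100, 150], bleach_frames=(2,))
        norm = frap.normalize_trace(trace)
        assert norm.intensities[2] == 0.5
        assert norm.baseline_mean == 200

    def test_two_baseline_frames_averaged(self):
        trace = make_trace([190, 210, 100, 150], bleach_frames=(2,))
        norm = frap.normalize_trace(trace)
        assert norm.baseline_mean == 200

    def test_single_baseline_frame(self):
        trace = make_trace([190, 210, 100, 150], bleach_frames=(2,), n_baseline=1)
        assert frap.normalize_trace(trace).baseline_mean == 190

    def test_constant_trace_normalises_to_ones(self):
        norm = frap.normalize_trace(make_trace([50.0] * 6))
        np.testing.assert_array_equal(norm.intensities, np.ones(6))

    def test_idempotent_within_roundoff(self):
        trace = make_trace([200, 200, 100, 150, 180], bleach_frames=(2,))
        once = frap.normalize_trace(trace)
        twice = frap.normalize_trace(once)
        np.testing.assert_allclose(twice.intensities, once.intensities, rtol=1e-12)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            frap.normalize_trace(make_trace([0, 0, 10, 20]))


class TestBleachSegmentation:
    def test_declared_indices_define_segments(self):
        spec = FRAPTraceSpec(bleach_frames=(5, 60), noise_sd=0.0)
        trace, _ = render_frap_trace(spec, n_frames=120)
        segments = frap.segment_bleaches(frap.normalize_trace(trace))
        assert [(s.start, s.stop) for s in segments] == [(5, 60), (60, 120)]

    def test_auto_detection_matches_declared(self):
        spec = FRAPTraceSpec(bleach_frames=(5, 60), noise_sd=0.4)
        trace, _ = render_frap_trace(spec, n_frames=120, seed=3)
        norm = frap.normalize_trace(trace)
        declared = frap.segment_bleaches(norm)
        blind = frap.FRAPTrace(trace.times_s, norm.intensities)
        auto = frap.segment_bleaches(blind)
        assert [(s.start, s.stop) for s in auto] == [(s.start, s.stop) for s in declared]

    def test_monotone_trace_without_bleach_errors(self):
        trace = make_trace(np.linspace(100, 110, 30))
        with pytest.raises(ValueError, match="no bleach"):
            frap.segment_bleaches(frap.normalize_trace(trace))


class TestRecoveryMetrics:
    def test_half_time_matches_closed_form(self):
        k = math.log(2) / 16.1
        t = np.arange(0, 200.0)
        seg = frap.Segment(0, t.size, 1.0, t, 0.2 + 0.2 * (1 - np.exp(-k * t)))
        res = frap.recovery_metrics(seg)
        assert res.t_half_s == pytest.approx(16.1, abs=1.0)

    def test_immobile_trace_has_no_half_time(self):
        t = np.arange(0, 30.0)
        seg = frap.Segment(0, t.size, 1.0, t, np.full(t.size, 0.2))
        res = frap.recovery_metrics(seg)
        assert res.t_half_s is None
        assert res.recovered_amplitude == 0
        assert any("amplitude" in f for f in res.flags)

    def test_double_bleach_fraction_recovery(self):
        """A 40%-mobile condensate recovers to ~40% after the first bleach
        and nearly completely (of its own pre-bleach level) after the second."""
        spec = FRAPTraceSpec(
            bleach_frames=(5, 305), mobile_fraction=0.4, bleach_floor_fraction=0.02, noise_sd=0.0
        )
        trace, _ = render_frap_trace(spec, n_frames=650)
        first, second = frap.analyze_frap_trace(trace)
        assert first.max_recovered_fraction == pytest.approx(0.4, abs=0.03)
        assert second.max_recovered_fraction > 0.97
        assert first.mobile_fraction == pytest.approx(0.4, abs=0.01)
        assert second.mobile_fraction == pytest.approx(1.0, abs=0.01)


class TestExponentialFit:
    def test_noiseless_rate_recovered(self):
        t = np.arange(0, 120.0)
        seg = frap.Segment(0, t.size, 1.0, t, 0.1 + 0.5 * (1 - np.exp(-0.05 * t)))
        fit = frap.fit_recovery_exponential(seg)
        assert fit.k_per_s == pytest.approx(0.05, rel=0.01)

    def test_fit_half_time_consistent_with_measured(self):
        k = 0.08
        t = np.arange(0, 150.0)
        seg = frap.Segment(0, t.size, 1.0, t, 0.15 + 0.4 * (1 - np.exp(-k * t)))
        res = frap.recovery_metrics(seg)
        fit = frap.fit_recovery_exponential(seg)
        assert abs(fit.t_half_s - res.t_half_s) <= 1.0  # within one frame

    def test_noisy_rate_median_error_under_10_percent(self):
        k = 0.05
        t = np.arange(0, 120.0)
        clean = 0.1 + 0.5 * (1 - np.exp(-k * t))
        errors = []
        for seed in range(50):
            noisy = clean + np.random.default_rng(seed).normal(0, 0.02, t.size)
            fit = frap.fit_recovery_exponential(frap.Segment(0, t.size, 1.0, t, noisy))
            errors.append(abs(fit.k_per_s - k) / k)
        assert np.median(errors) < 0.10


class TestGeneratorContracts:
    def test_immobile_spec_gives_flat_post_bleach_trace(self):
        spec = FRAPTraceSpec(bleach_frames=(5,), mobile_fraction=0.0, noise_sd=0.0)
        trace, _ = render_frap_trace(spec, n_frames=40)
        floor = trace.intensities[5]
        np.testing.assert_allclose(trace.intensities[5:], floor)

    def test_half_time_of_generated_trace_matches_rate(self):
        k = math.log(2) / 16.1
        spec = FRAPTraceSpec(bleach_frames=(5,), recovery_rate_per_s=k, noise_sd=0.0)
        trace, truth = render_frap_trace(spec, n_frames=305)
        (res,) = frap.analyze_frap_trace(trace)
        assert res.t_half_s == pytest.approx(truth.params["t_half_s"], abs=1.0)

    def test_invalid_mobile_fraction_rejected(self):
        with pytest.raises(ValueError):
            FRAPTraceSpec(mobile_fraction=1.5)
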