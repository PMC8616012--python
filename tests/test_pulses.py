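"""Baseline estimation, transit-pulse detection and feature extraction."""

import numpy as np
import pytest

from polarcyte.psa import InstrumentMatrix, theoretical_instrument_matrix
from polarcyte.pulses import (
    SCATTER_CHANNELS,
    TRACE_CHANNELS,
    PulseEvent,
    TraceSet,
    detect_pulses,
    estimate_baseline,
    extract_features,
    features_from_pulse,
)
from polarcyte.simulator import (
    ExperimentDesign,
    ParticleClass,
    render_traces,
    sample_particles,
)


def make_traces(total, fs=100_000.0, split=None):
    """Five-channel TraceSet whose scattering channels sum to ``total``."""
    split = split or {c: 0.25 for c in SCATTER_CHANNELS}
    channels = {c: split[c] * np.asarray(total, dtype=float) for c in SCATTER_CHANNELS}
    channels["FL"] = np.zeros_like(np.asarray(total, dtype=float))
    return TraceSet(sampling_rate=fs, channels=channels)


def gaussian_pulse(n, center, amp, sd):
    x = np.arange(n)
    return amp * np.exp(-0.5 * ((x - center) / sd) ** 2)


class TestTraceSet:
    def test_unequal_lengths_rejected(self):
        channels = {c: np.zeros(10) for c in TRACE_CHANNELS}
        channels["FL"] = np.zeros(9)
        with pytest.raises(ValueError, match="lengths"):
            TraceSet(sampling_rate=1e5, channels=channels)

    def test_nan_rejected(self):
        channels = {c: np.zeros(10) for c in TRACE_CHANNELS}
        channels["I0"][3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            TraceSet(sampling_rate=1e5, channels=channels)

    def test_missing_channel_rejected(self):
        channels = {c: np.zeros(10) for c in SCATTER_CHANNELS}
        with pytest.raises(ValueError, match="channels"):
            TraceSet(sampling_rate=1e5, channels=channels)


class TestBaseline:
    def test_constant_trace(self):
        baseline, noise_sd = estimate_baseline(np.full(1000, 3.7), window=51)
        np.testing.assert_allclose(baseline, 3.7)
        assert noise_sd == 0.0

    def test_white_noise_sd_recovered(self, rng):
        trace = rng.normal(0.0, 0.01, size=100_000)
        _, noise_sd = estimate_baseline(trace, window=101)
        assert noise_sd == pytest.approx(0.01, rel=0.10)

    def test_median_baseline_ignores_sparse_pulses(self, rng):
        n = 50_000
        trace = rng.normal(1.0, 0.01, size=n)
        # 1% duty cycle of strong pulses must not drag the baseline up
        for c in range(500, n, 5000):
            trace += gaussian_pulse(n, c, amp=1.0, sd=8)
        baseline, _ = estimate_baseline(trace, window=1001)
        assert np.median(baseline) == pytest.approx(1.0, abs=0.005)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError, match="longer than trace"):
            estimate_baseline(np.zeros(10), window=11)

    def test_tiny_window_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            estimate_baseline(np.zeros(10), window=2)


class TestDetectPulses:
    def test_single_pulse_detected_with_expected_snr(self, rng):
        n = 20_000
        total = gaussian_pulse(n, 10_000, amp=0.5, sd=10) + rng.normal(0, 0.01, n)
        events = detect_pulses(make_traces(total), k_threshold=5, min_width=8)
        assert len(events) == 1
        assert events[0].snr == pytest.approx(50, rel=0.2)
        assert events[0].start_index < 10_000 < events[0].end_index

    def test_pure_noise_yields_no_events(self):
        # eight consecutive 5-sigma samples from white noise: never at n=1e5
        for seed in range(5):
            rng = np.random.default_rng(seed)
            total = rng.normal(0, 0.01, 100_000)
            assert detect_pulses(make_traces(total), k_threshold=5, min_width=8) == []

    def test_separation_controls_merging(self, rng):
        n = 20_000
        noise = rng.normal(0, 0.005, n)
        far = noise + gaussian_pulse(n, 5_000, 0.5, 10) + gaussian_pulse(n, 15_000, 0.5, 10)
        near = noise + gaussian_pulse(n, 9_970, 0.5, 10) + gaussian_pulse(n, 10_030, 0.5, 10)
        assert len(detect_pulses(make_traces(far), min_separation=200)) == 2
        assert len(detect_pulses(make_traces(near), min_separation=200)) == 1

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_pulses(make_traces(np.array([])))

    def test_integrals_additive_under_trace_split(self, rng):
        n = 40_000
        total = rng.normal(0.2, 0.005, n)
        total += gaussian_pulse(n, 8_000, 0.5, 10) + gaussian_pulse(n, 30_000, 0.7, 10)
        whole = detect_pulses(make_traces(total), k_threshold=5, min_width=8)
        left = detect_pulses(make_traces(total[:n // 2]), k_threshold=5, min_width=8)
        right = detect_pulses(make_traces(total[n // 2:]), k_threshold=5, min_width=8)
        assert len(whole) == len(left) + len(right) == 2
        whole_i = sorted(e.ipsa.sum() for e in whole)
        split_i = sorted(e.ipsa.sum() for e in left + right)
        np.testing.assert_allclose(whole_i, split_i, rtol=0.02)


class TestFeaturesFromPulse:
    def test_identity_instrument_trivial_features(self):
        p = PulseEvent(start_index=0, end_index=10,
                       ipsa=np.array([1.0, 1.0, 0.0, 0.0]), fm=0.5,
                       peak_voltage=1.0, snr=10.0)
        rec = features_from_pulse(p, InstrumentMatrix(np.eye(4)))
        assert (rec.q, rec.u, rec.v, rec.dop) == pytest.approx((1, 0, 0, 1))
        assert rec.F == pytest.approx(0.5)

    def test_joint_scaling_leaves_ratio_features_unchanged(self, default_matrix):
        ipsa = default_matrix.forward([2, 0.5, 0.8, 0.1])
        base = features_from_pulse(
            PulseEvent(0, 10, ipsa, fm=0.3, peak_voltage=1, snr=5), default_matrix)
        scaled = features_from_pulse(
            PulseEvent(0, 10, 3 * ipsa, fm=0.9, peak_voltage=3, snr=5), default_matrix)
        for attr in ("q", "u", "v", "dop", "F"):
            assert getattr(scaled, attr) == pytest.approx(getattr(base, attr))
        assert scaled.I == pytest.approx(3 * base.I)

    def test_low_intensity_pulse_rejected_not_raised(self, default_matrix):
        p = PulseEvent(0, 10, ipsa=1e-12 * np.ones(4), fm=0.0,
                       peak_voltage=1e-12, snr=0.0)
        assert features_from_pulse(p, default_matrix, intensity_floor=1e-6) is None


class TestEndToEnd:
    def test_noiseless_single_particle_recovered_exactly(self, default_matrix):
        cls = ParticleClass("x", f_mean=0.4, f_sd=0.0, amplitude_sigma=0.0)
        design = ExperimentDesign(classes=[cls], seed=7, arrival_rate=0.0,
                                  duration=0.01, noise_sd=0.0)
        rng = np.random.default_rng(7)
        particles = sample_particles(design, rng)[:0]  # force exactly one below
        m = cls.sample_mueller(rng)
        from polarcyte.simulator import Particle
        sout = m @ design.incident_stokes
        particles = [Particle("x", 0.005, sout, f_ratio=0.4, amplitude=1.0)]
        traces, _ = render_traces(particles, design, rng=rng)
        records, rejections = extract_features(traces, default_matrix)
        assert len(records) == 1 and not sum(rejections.values())
        rec = records[0]
        from polarcyte.polarization import polarization_components
        truth = polarization_components(sout)
        assert rec.q == pytest.approx(truth.q, abs=1e-6)
        assert rec.u == pytest.approx(truth.u, abs=1e-6)
        assert rec.v == pytest.approx(truth.v, abs=1e-6)
        assert rec.dop == pytest.approx(truth.dop, abs=1e-6)
        assert rec.F == pytest.approx(0.4, abs=1e-6)

    def test_detection_recall_precision_at_moderate_snr(self):
        # small version of the seeded-runs property (full sweep in acceptance)
        cls = ParticleClass("x", amplitude_sigma=0.0)
        planted = matched = detected = matched_det = 0
        for seed in range(10):
            design = ExperimentDesign(classes=[cls], seed=seed, arrival_rate=100,
                                      duration=0.05, noise_sd=0.02)
            rng = np.random.default_rng(seed)
            parts = sample_particles(design, rng)
            traces, _ = render_traces(parts, design, rng=rng)
            events = detect_pulses(traces, k_threshold=5, min_width=8)
            centers = [p.arrival_time * design.sampling_rate for p in parts]
            planted += len(parts)
            detected += len(events)
            matched += sum(any(e.start_index - 2 <= c <= e.end_index + 2
                               for e in events) for c in centers)
            matched_det += sum(any(e.start_index - 2 <= c <= e.end_index + 2
                                   for c in centers) for e in events)
        assert matched / planted >= 0.95
        assert matched_det / detected >= 0.95
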