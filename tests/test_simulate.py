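"""Rhythm, pulse and trace generator behaviour."""

import dataclasses

import numpy as np
import pytest
import scipy.signal

import rppg_afib as ra
from rppg_afib.simulate import subject_seed


def lag1_autocorr(x):
    x = x - x.mean()
    return float(np.dot(x[:-1], x[1:]) / np.dot(x, x))


class TestSimulateRR:
    def test_nsr_mean_and_low_variability(self, nsr_label):
        """Ensemble over 100 seeds: NSR at 60 bpm gives ~1-s intervals
        with coefficient of variation well under 0.06."""
        means, cvs, counts = [], [], []
        for seed in range(100):
            rr = ra.simulate_rr(nsr_label, 60.0, 60.0, seed)
            counts.append(rr.n_beats)
            means.append(rr.intervals.mean())
            cvs.append(rr.intervals.std() / rr.intervals.mean())
        assert 55 <= np.mean(counts) <= 62
        assert 0.97 <= np.mean(means) <= 1.03
        assert np.max(cvs) < 0.06

    def test_af_heavy_variability_no_serial_correlation(self, af_label):
        cvs, acs = [], []
        for seed in range(100):
            rr = ra.simulate_rr(af_label, 75.0, 300.0, seed)
            cvs.append(rr.intervals.std() / rr.intervals.mean())
            acs.append(lag1_autocorr(rr.intervals))
        assert 0.18 <= np.mean(cvs) <= 0.30
        assert all(-0.15 < a < 0.15 for a in acs)

    def test_too_short_duration_gives_empty_series(self, nsr_label):
        rr = ra.simulate_rr(nsr_label, 60.0, 0.5, 0)
        assert rr.n_beats == 0

    def test_duration_and_bounds_invariants(self):
        for key in ("AF", "NSR", "APC", "VPC", "SINUS_ARRHYTHMIA",
                    "SINUS_TACHY", "SINUS_BRADY", "FLUTTER"):
            rr = ra.simulate_rr(ra.RhythmLabel.from_key(key), 70.0, 120.0, 3)
            assert rr.intervals.sum() <= 120.0
            assert rr.intervals.min() >= 0.25
            assert rr.intervals.max() <= 3.0

    def test_variability_ordering_af_sa_nsr(self):
        """At matched mean rate, interval CV orders AF > sinus arrhythmia
        > NSR with >= 2x separation (100-seed ensembles)."""
        cv = {}
        for key in ("AF", "SINUS_ARRHYTHMIA", "NSR"):
            label = ra.RhythmLabel.from_key(key)
            cv[key] = np.mean([
                (lambda rr: rr.intervals.std() / rr.intervals.mean())(
                    ra.simulate_rr(label, 70.0, 300.0, seed))
                for seed in range(100)])
        assert cv["AF"] >= 2.0 * cv["SINUS_ARRHYTHMIA"]
        assert cv["SINUS_ARRHYTHMIA"] >= 2.0 * cv["NSR"]

    def test_nsr_tachogram_shows_respiratory_peak(self, nsr_label):
        """The RR tachogram, resampled evenly, peaks at the configured
        respiratory frequency."""
        rr = ra.simulate_rr(nsr_label, 60.0, 300.0, 5)
        t = np.cumsum(rr.intervals)
        grid = np.arange(t[0], t[-1], 0.5)
        tach = np.interp(grid, t, rr.intervals)
        freqs, power = scipy.signal.periodogram(tach - tach.mean(), fs=2.0)
        mask = (freqs > 0.05) & (freqs < 0.5)
        peak = freqs[mask][np.argmax(power[mask])]
        assert abs(peak - ra.RRParams().resp_freq_hz) < 0.03

    def test_errors(self, nsr_label):
        with pytest.raises(ValueError):
            ra.simulate_rr(nsr_label, 60.0, -1.0, 0)
        with pytest.raises(ValueError):
            ra.simulate_rr(nsr_label, 10.0, 60.0, 0)
        with pytest.raises(ValueError):
            ra.RhythmLabel(ra.RhythmGroup.NSR, ra.RhythmSubtype.APC)
        with pytest.raises(ValueError):
            ra.RhythmLabel(ra.RhythmGroup.OTHER)


class TestRenderPulse:
    def test_regular_rhythm_dominant_frequency(self, nsr_label):
        rr = ra.RRIntervalSeries(np.ones(10), nsr_label, 0, 10.0)
        pulse = ra.render_pulse(rr, 84.0)
        freqs, power = scipy.signal.periodogram(pulse.samples - pulse.samples.mean(),
                                                fs=84.0)
        assert abs(freqs[np.argmax(power)] - 1.0) <= 0.05

    def test_empty_rr_gives_zero_wave(self, nsr_label):
        rr = ra.RRIntervalSeries(np.array([]), nsr_label, 0, 5.0)
        pulse = ra.render_pulse(rr, 84.0)
        assert pulse.samples.size == 420
        assert not pulse.samples.any()

    def test_amplitude_normalized(self, af_label):
        rr = ra.simulate_rr(af_label, 80.0, 60.0, 2)
        pulse = ra.render_pulse(rr, 84.0)
        assert np.abs(pulse.samples).max() <= 1.0 + 1e-12
        assert pulse.beat_onsets.size == rr.n_beats

    def test_pulse_rate_matches_configured_hr(self, nsr_label):
        """Noise-free pulse dominant frequency equals mean_hr/60 within
        0.05 Hz for a regular rhythm."""
        for hr in (48.0, 72.0, 96.0):
            rr = ra.simulate_rr(nsr_label, hr, 120.0, 1)
            pulse = ra.render_pulse(rr, 84.0)
            freqs, power = scipy.signal.periodogram(
                pulse.samples - pulse.samples.mean(), fs=84.0)
            band = freqs > 0.2
            assert abs(freqs[band][np.argmax(power[band])] - hr / 60.0) <= 0.05


class TestRenderRGB:
    def test_zero_pulse_zero_noise_constant_baseline(self, nsr_label):
        rr = ra.RRIntervalSeries(np.array([]), nsr_label, 0, 10.0)
        pulse = ra.render_pulse(rr, 84.0)
        trace = ra.render_rgb_trace(pulse, noise=ra.NoiseParams.silent(), seed=0)
        for ch, b0 in zip((trace.r, trace.g, trace.b), (140.0, 110.0, 95.0)):
            assert np.allclose(ch, b0)

    def test_green_channel_carries_strongest_pulse(self, nsr_label):
        rr = ra.simulate_rr(nsr_label, 70.0, 60.0, 1)
        pulse = ra.render_pulse(rr, 84.0)
        trace = ra.render_rgb_trace(pulse, noise=ra.NoiseParams.silent(), seed=0)
        rel = [np.var(ch / ch.mean()) for ch in (trace.r, trace.g, trace.b)]
        assert rel[1] > rel[0] and rel[1] > rel[2]

    def test_shape_and_fs_preserved(self, nsr_label):
        rr = ra.simulate_rr(nsr_label, 70.0, 45.0, 1)
        pulse = ra.render_pulse(rr, 84.0)
        trace = ra.render_rgb_trace(pulse, seed=0)
        assert len(trace) == pulse.samples.size
        assert trace.fs == pulse.fs

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            ra.NoiseParams(white_noise_sd=-1.0)


class TestRenderFrames:
    def test_constant_fill_without_noise(self, nsr_label):
        rr = ra.RRIntervalSeries(np.array([]), nsr_label, 0, 1.0)
        pulse = ra.render_pulse(rr, 84.0)
        trace = dataclasses.replace(
            ra.render_rgb_trace(pulse, baseline=(100.0, 150.0, 200.0),
                                noise=ra.NoiseParams.silent(), seed=0))
        frames = ra.render_frames(trace, frame_size=(16, 16),
                                  skin_rect=(4, 12, 4, 12), pixel_noise_sd=0.0)
        assert frames.shape[0] == len(trace)
        assert np.allclose(frames[10, 5, 5], [100.0, 150.0, 200.0])

    def test_roi_mean_recovers_trace_within_noise(self, nsr_label):
        rr = ra.simulate_rr(nsr_label, 70.0, 20.0, 1)
        pulse = ra.render_pulse(rr, 84.0)
        trace = ra.render_rgb_trace(pulse, noise=ra.NoiseParams.silent(), seed=0)
        sd = 3.0
        rect = (8, 40, 16, 48)
        frames = ra.render_frames(trace, skin_rect=rect, pixel_noise_sd=sd,
                                  seed=7)
        rec = ra.roi_mean_rgb(frames, rect, fs=84.0)
        n_pix = (rect[1] - rect[0]) * (rect[3] - rect[2])
        tol = 6.0 * sd / np.sqrt(n_pix)
        assert np.abs(rec.g - trace.g).max() < tol

    def test_empty_rect_rejected(self, nsr_label):
        rr = ra.RRIntervalSeries(np.array([]), nsr_label, 0, 1.0)
        trace = ra.render_rgb_trace(ra.render_pulse(rr, 84.0),
                                    noise=ra.NoiseParams.silent(), seed=0)
        with pytest.raises(ValueError):
            ra.render_frames(trace, frame_size=(16, 16), skin_rect=(4, 4, 0, 8))


class TestSubjectAndCohort:
    def test_subject_trace_length_and_determinism(self, nsr_label):
        a = ra.simulate_subject(nsr_label, 600.0, seed=3)
        b = ra.simulate_subject(nsr_label, 600.0, seed=3)
        assert len(a.trace) == 50400
        assert a.label == nsr_label
        np.testing.assert_array_equal(a.trace.g, b.trace.g)
        np.testing.assert_array_equal(a.rr.intervals, b.rr.intervals)

    def test_subject_duration_bounds(self, nsr_label):
        with pytest.raises(ValueError):
            ra.simulate_subject(nsr_label, 10.0, seed=0)

    def test_cohort_counts_match_reference_composition(self):
        spec = ra.default_cohort_spec()
        assert spec.total == 453
        assert spec.n_per_class["AF"] == 105
        assert spec.n_per_class["NSR"] == 116
        other = sum(v for k, v in spec.n_per_class.items()
                    if k not in ("AF", "NSR"))
        assert other == 232

    def test_small_cohort_counts_and_determinism(self):
        spec = ra.CohortSpec(n_per_class={"NSR": 1, "AF": 1},
                             duration_range=(30.0, 60.0), master_seed=9)
        a = ra.simulate_cohort(spec)
        b = ra.simulate_cohort(spec)
        assert len(a) == 2
        assert [r.label.group for r in a] == [ra.RhythmGroup.NSR,
                                              ra.RhythmGroup.AF]
        for ra_, rb in zip(a, b):
            np.testing.assert_array_equal(ra_.trace.r, rb.trace.r)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            ra.simulate_cohort(ra.CohortSpec(n_per_class={"AF": 0},
                                             master_seed=0))

    def test_subject_seed_stable(self):
        assert subject_seed(123, 4) == subject_seed(123, 4)
        assert subject_seed(123, 4) != subject_seed(123, 5)
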