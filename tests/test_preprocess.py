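import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fnirspipe.io_events import RawRecording
from fnirspipe.preprocess import (ArtifactDetectionParams, BandpassParams, ODSeries,
                                  bandpass, detect_motion, intensity_to_od, spline_correct)
from fnirspipe.synth import ArtifactSpec, simulate_recording


def od_from(x, fs=10.0):
    x = np.asarray(x, float).reshape(len(x), -1)
    return ODSeries(np.arange(x.shape[0]) / fs, x, [660.0] * x.shape[1], np.ones(x.shape[1]), fs)


def flat_od(n=600, fs=10.0, noise_sd=0.005, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, noise_sd, (n, 1))
    return ODSeries(np.arange(n) / fs, x, [660.0], np.ones(1), fs)


class TestIntensityToOD:
    def test_constant_intensity_gives_zero_od(self):
        rec = RawRecording(np.arange(20) / 10.0, np.full((20, 2), 1500.0),
                           [660.0, 880.0], sampling_rate=10.0)
        od = intensity_to_od(rec)
        np.testing.assert_allclose(od.od, 0.0, atol=1e-15)

    def test_tenth_of_reference_gives_od_one(self):
        inten = np.full((20, 1), 1000.0)
        inten[10, 0] = 100.0
        # mean_window over the flat start so I0 = 1000 exactly
        rec = RawRecording(np.arange(20) / 10.0, inten, [660.0], sampling_rate=10.0)
        od = intensity_to_od(rec, reference="mean_window", reference_window_s=(0.0, 0.5))
        assert od.od[10, 0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_log_ratio(self, rng):
        inten = rng.uniform(500.0, 3000.0, (100, 2))
        rec = RawRecording(np.arange(100) / 10.0, inten, [660.0, 880.0], sampling_rate=10.0)
        od = intensity_to_od(rec)
        expected = -np.log10(inten / inten.mean(axis=0))
        np.testing.assert_allclose(od.od, expected, rtol=1e-12)

    @given(scale=st.floats(0.1, 100.0))
    @settings(deadline=None, max_examples=25)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(3)
        inten = rng.uniform(500.0, 3000.0, (50, 1))
        rec1 = RawRecording(np.arange(50) / 10.0, inten, [660.0], sampling_rate=10.0)
        rec2 = RawRecording(np.arange(50) / 10.0, inten * scale, [660.0], sampling_rate=10.0)
        np.testing.assert_allclose(intensity_to_od(rec1).od, intensity_to_od(rec2).od,
                                   atol=1e-12)


class TestDetectMotion:
    def test_clean_series_empty_mask(self):
        od = flat_od()
        mask = detect_motion(od)
        assert mask.n_flagged == 0 and mask.segments == []

    def test_step_flagged_within_mask_tolerance_only(self):
        od = flat_od(noise_sd=0.005)
        x = od.od.copy()
        x[300:, 0] += 0.5
        od = od.replace_od(x)
        mask = detect_motion(od)
        assert mask.mask[300]
        # flags confined to the step neighborhood: window + t_mask dilation
        fs = od.sampling_rate
        params = mask.params
        halo = int(round((params.t_motion_s + params.t_mask_s) * fs)) + 1
        flagged = np.flatnonzero(mask.mask)
        assert flagged.min() >= 300 - halo and flagged.max() <= 300 + halo

    def test_small_step_below_both_thresholds_not_flagged(self):
        # noise tuned so that 10x the robust diff scale is ~0.2 OD
        rng = np.random.default_rng(5)
        x = rng.normal(0.0, 0.02 / 1.349, (600, 1))  # MAD of diffs ~ 0.02
        x[300:, 0] += 0.05  # below 0.2 (robust criterion) and 0.3 (amplitude)
        od = ODSeries(np.arange(600) / 10.0, x, [660.0], np.ones(1), 10.0)
        assert not detect_motion(od).mask[295:305].any()

    def test_translation_invariance(self):
        od = flat_od(seed=8)
        x = od.od.copy()
        x[200:203, 0] += 0.6
        m1 = detect_motion(od.replace_od(x))
        m2 = detect_motion(od.replace_od(x + 5.0))
        np.testing.assert_array_equal(m1.mask, m2.mask)

    def test_monotone_in_amp_threshold(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0.0, 0.03, (800, 1))
        x[400:403, 0] += 0.45
        od = ODSeries(np.arange(800) / 10.0, x, [660.0], np.ones(1), 10.0)
        # larger amplitude threshold can only flag a subset
        loose = detect_motion(od, ArtifactDetectionParams(amp_thresh=0.3, stdev_thresh=1e9))
        strict = detect_motion(od, ArtifactDetectionParams(amp_thresh=0.6, stdev_thresh=1e9))
        assert np.all(loose.mask | ~strict.mask)

    def test_window_shorter_than_two_samples_rejected(self):
        od = flat_od(fs=1.0)
        with pytest.raises(ValueError, match="at least 2"):
            detect_motion(od, ArtifactDetectionParams(t_motion_s=0.2))


class TestSplineCorrect:
    def test_empty_mask_identity(self):
        od = flat_od()
        mask = detect_motion(od)
        out = spline_correct(od, mask)
        np.testing.assert_array_equal(out.od, od.od)

    def test_spike_rmse_halved_against_clean_signal(self):
        fs = 10.0
        n = 1200
        t = np.arange(n) / fs
        clean = 0.05 * np.sin(2 * np.pi * 0.03 * t)
        spike = 0.5 * np.exp(-0.5 * ((t - 60.0) / 0.1) ** 2)
        od = ODSeries(t, (clean + spike)[:, None], [660.0], np.ones(1), fs)
        mask = detect_motion(od)
        assert mask.n_flagged > 0
        out = spline_correct(od, mask)
        a, b = mask.segments[0]
        rmse_before = np.sqrt(np.mean((od.od[a:b, 0] - clean[a:b]) ** 2))
        rmse_after = np.sqrt(np.mean((out.od[a:b, 0] - clean[a:b]) ** 2))
        assert rmse_after < 0.5 * rmse_before

    def test_step_level_difference_under_ten_percent(self):
        od = flat_od(n=1200, noise_sd=0.003, seed=2)
        x = od.od.copy()
        x[600:, 0] += 0.5
        od = od.replace_od(x)
        mask = detect_motion(od)
        out = spline_correct(od, mask)
        a, b = mask.segments[0]
        w = 20  # 2 s
        level_jump = out.od[b:b + w, 0].mean() - out.od[a - w:a, 0].mean()
        assert abs(level_jump) < 0.1 * 0.5

    def test_rerun_detection_flags_fewer_samples(self, finger_config):
        cfg = dataclasses.replace(
            finger_config, seed=13,
            artifacts=[ArtifactSpec(50.0, "spike", 0.5), ArtifactSpec(110.0, "step", 0.5)])
        rec, _ = simulate_recording(cfg)
        od = intensity_to_od(rec)
        mask = detect_motion(od)
        corrected = spline_correct(od, mask)
        assert detect_motion(corrected).n_flagged < mask.n_flagged

    def test_bad_tension_rejected(self):
        od = flat_od()
        mask = detect_motion(od)
        with pytest.raises(ValueError, match="tension"):
            spline_correct(od, mask, tension=1.0)


class TestBandpass:
    def test_zero_in_zero_out(self):
        od = od_from(np.zeros((2000, 1)))
        np.testing.assert_allclose(bandpass(od).od, 0.0, atol=1e-15)

    def test_linearity(self, rng):
        a = rng.normal(0, 1, (3000, 1))
        b = rng.normal(0, 1, (3000, 1))
        fa = bandpass(od_from(a)).od
        fb = bandpass(od_from(b)).od
        fab = bandpass(od_from(a + b)).od
        np.testing.assert_allclose(fab, fa + fb, atol=1e-9)

    def test_double_filter_squares_magnitude_response(self):
        from fnirspipe.validation import filter_gain
        fs, dur = 10.0, 2000.0
        t = np.arange(0.0, dur, 1 / fs)
        x = np.sin(2 * np.pi * 0.03 * t)
        once = bandpass(od_from(x[:, None]))
        twice = bandpass(once)
        g1, _ = filter_gain(0.03, fs, dur)
        sel = slice(2000, -2000)
        amp_once = np.ptp(once.od[sel, 0]) / 2
        amp_twice = np.ptp(twice.od[sel, 0]) / 2
        assert amp_twice / amp_once == pytest.approx(g1, rel=0.02)

    def test_invalid_cutoffs_rejected(self):
        od = od_from(np.zeros((3000, 1)))
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(od, BandpassParams(high_cutoff_hz=6.0))
        with pytest.raises(ValueError, match="low_cutoff"):
            bandpass(od, BandpassParams(low_cutoff_hz=0.2, high_cutoff_hz=0.1))

    def test_short_recording_rejected_not_truncated(self):
        od = od_from(np.zeros((500, 1)))  # 50 s < 1/low_cutoff = 100 s
        with pytest.raises(ValueError, match="pad length"):
            bandpass(od)
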