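import dataclasses

import numpy as np
import pytest
from scipy.signal import periodogram

import fnirspipe as fp
from fnirspipe.synth import PARADIGMS, hrf_kernel


class TestBlockDesign:
    def test_finger_tapping_onsets(self, finger_config, finger_markers):
        np.testing.assert_array_equal(finger_markers.onsets("finger_tapping"),
                                      [15.0, 45.0, 75.0, 105.0, 135.0])

    def test_single_block_nback(self):
        cfg = fp.SimulationConfig.for_paradigm("nback1", n_blocks=1)
        mk = fp.generate_block_design(cfg)
        task = [m for m in mk if m.label == "nback1"]
        assert len(task) == 1
        assert task[0].onset_s == pytest.approx(16.0)
        assert task[0].duration_s == pytest.approx(20.0)

    @pytest.mark.parametrize("paradigm", sorted(PARADIGMS))
    def test_matches_brute_force_enumeration(self, paradigm):
        cfg = fp.SimulationConfig.for_paradigm(paradigm)
        mk = fp.generate_block_design(cfg)
        rest, task, n = cfg.rest_duration_s, cfg.task_duration_s, cfg.n_blocks
        expected = [rest + k * (rest + task) for k in range(n)]
        np.testing.assert_allclose(mk.onsets(paradigm), expected)
        # alternating structure with a trailing rest
        labels = [m.label for m in mk]
        assert labels == ["rest", paradigm] * n + ["rest"]

    def test_nonpositive_block_count_rejected(self):
        with pytest.raises(ValueError, match="n_blocks"):
            fp.SimulationConfig.for_paradigm("finger_tapping", n_blocks=0)


class TestHRFKernel:
    def test_peak_location_and_normalization(self):
        fs = 10.0
        k = hrf_kernel(fs)
        t = np.arange(k.size) / fs
        assert 4.5 <= t[np.argmax(k)] <= 6.5
        assert k.max() == pytest.approx(1.0)
        assert abs(k[int(25 * fs)]) < 0.05

    def test_boxcar_convolution_reaches_plateau(self):
        fs = 10.0
        k = hrf_kernel(fs)
        box = np.ones(int(15 * fs))
        conv = np.convolve(box, k)
        assert conv.max() >= 0.9 * k.sum()

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            hrf_kernel(-1.0)
        with pytest.raises(ValueError):
            hrf_kernel(10.0, duration_s=10.0)


class TestSimulateRecording:
    def test_determinism_bit_identical(self, finger_config):
        cfg = dataclasses.replace(finger_config, seed=42)
        rec1, truth1 = fp.simulate_recording(cfg)
        rec2, truth2 = fp.simulate_recording(cfg)
        np.testing.assert_array_equal(rec1.intensity, rec2.intensity)
        np.testing.assert_array_equal(truth1.true_hbo, truth2.true_hbo)

    def test_different_seeds_differ(self, finger_config):
        rec1, _ = fp.simulate_recording(dataclasses.replace(finger_config, seed=1))
        rec2, _ = fp.simulate_recording(dataclasses.replace(finger_config, seed=2))
        assert not np.array_equal(rec1.intensity, rec2.intensity)

    def test_ground_truth_aligned_and_in_bounds(self, noisy_recording):
        cfg, rec, truth = noisy_recording
        assert truth.timestamps.size == rec.n_samples
        for a, b in truth.artifact_sample_ranges:
            assert 0 <= a < b <= rec.n_samples

    def test_intensity_strictly_positive(self, noisy_recording):
        _, rec, _ = noisy_recording
        assert (rec.intensity > 0).all()

    def test_noiseless_roundtrip_recovers_concentrations(self, clean_recording):
        """With zero noise, OD conversion + MBLL inversion reproduce the
        injected concentrations to near machine precision (up to the DC
        offset the mean-referenced OD introduces)."""
        cfg, rec, truth = clean_recording
        od = fp.intensity_to_od(rec)
        conc = fp.od_to_concentration(od, cfg.mbll)
        rec_hbo = conc.delta_hbo - conc.delta_hbo.mean()
        true_hbo = truth.true_hbo - truth.true_hbo.mean()
        np.testing.assert_allclose(rec_hbo, true_hbo, atol=1e-12 * abs(true_hbo).max())

    def test_cardiac_peak_dominates_above_half_hz(self, noisy_recording):
        cfg, rec, _ = noisy_recording
        od = fp.intensity_to_od(rec)
        f, p = periodogram(od.od[:, 0], fs=cfg.sampling_rate)
        hi = f > 0.5
        peak_freq = f[hi][np.argmax(p[hi])]
        df = f[1] - f[0]
        assert abs(peak_freq - cfg.noise_cardiac.freq_hz) <= df

    @pytest.mark.parametrize("name, comp_attr", [
        ("respiratory", "noise_respiratory"), ("mayer", "noise_mayer")])
    def test_each_component_peaks_at_its_frequency(self, finger_config, name, comp_attr):
        # isolate one component: all other noise off
        cfg = finger_config.without_noise()
        comp = getattr(finger_config, comp_attr)
        cfg = dataclasses.replace(cfg, **{comp_attr: comp}, seed=5,
                                  hrf_amplitude_hbo=0.0, hrf_amplitude_hbr=0.0)
        rec, _ = fp.simulate_recording(cfg)
        od = fp.intensity_to_od(rec)
        f, p = periodogram(od.od[:, 0], fs=cfg.sampling_rate)
        peak_freq = f[1:][np.argmax(p[1:])]
        assert abs(peak_freq - comp.freq_hz) <= f[1] - f[0]

    def test_absurd_noise_rejected_with_diagnostic(self, finger_config):
        cfg = dataclasses.replace(
            finger_config,
            noise_cardiac=fp.NoiseComponent(1.1, 400.0), seed=0)
        with pytest.raises(ValueError, match="intensity non-positive"):
            fp.simulate_recording(cfg)


class TestSimulateBehavioral:
    def test_zero_effect_zero_noise_mean_difference_zero(self):
        df = fp.simulate_behavioral(10, accuracy_drop=0.0, rt_increase_s=0.0,
                                    accuracy_sd=0.0, rt_sd_s=0.0, seed=0,
                                    mean_accuracy_a=0.8)
        assert (df["accuracy_a"] - df["accuracy_b"]).abs().max() == 0.0
        assert (df["rt_a_s"] - df["rt_b_s"]).abs().max() == 0.0

    def test_configured_shift_recovered(self):
        # mean difference over many participants within 3 SEM of the target
        df = fp.simulate_behavioral(2000, accuracy_drop=0.12, seed=3,
                                    mean_accuracy_a=0.7, accuracy_sd=0.05)
        diffs = df["accuracy_a"] - df["accuracy_b"]
        sem = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean() - 0.12) < 3 * sem

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_rt_strictly_positive_any_seed(self, seed):
        df = fp.simulate_behavioral(50, rt_increase_s=-2.0, rt_sd_s=1.0, seed=seed)
        assert (df["rt_a_s"] > 0).all() and (df["rt_b_s"] > 0).all()

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            fp.simulate_behavioral(2)
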