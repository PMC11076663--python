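import numpy as np
import pytest

from fnirspipe.epochs import (baseline_correct, block_average, condition_scalars, segment)
from fnirspipe.io_events import EventMarkers, Marker
from fnirspipe.mbll import ConcentrationSeries, MBLLParams


def conc_from(x, fs=10.0):
    x = np.asarray(x, float)
    return ConcentrationSeries(np.arange(x.size) / fs, x, -x / 3, MBLLParams(),
                               condition_number=2.0, sampling_rate=fs)


def design(n_blocks=5, rest=15.0, task=15.0, label="tap"):
    entries = []
    for k in range(n_blocks):
        entries.append(Marker(k * (rest + task), rest, "rest"))
        entries.append(Marker(k * (rest + task) + rest, task, label))
    entries.append(Marker(n_blocks * (rest + task), rest, "rest"))
    return EventMarkers(entries)


class TestSegment:
    def test_all_markers_in_range(self):
        conc = conc_from(np.zeros(1650))
        eps = segment(conc, design(), "tap", window=(-5.0, 25.0))
        assert eps.n_epochs == 5
        assert eps.epochs.shape == (5, 300)

    def test_edge_epoch_dropped(self):
        conc = conc_from(np.zeros(1400))  # ends 3 s after the last onset (135 s)
        eps = segment(conc, design(), "tap", window=(-5.0, 15.0))
        assert eps.n_epochs == 4

    def test_content_matches_brute_force_slicing(self, rng):
        x = rng.normal(0, 1, 1650)
        conc = conc_from(x)
        eps = segment(conc, design(), "tap", window=(-5.0, 25.0))
        fs = 10.0
        for row, onset in zip(eps.epochs, eps.onsets_s):
            i = int(round(onset * fs))
            np.testing.assert_array_equal(row, x[i - 50:i + 250])

    def test_missing_condition_errors(self):
        conc = conc_from(np.zeros(1650))
        with pytest.raises(ValueError, match="nothere"):
            segment(conc, design(), "nothere")


class TestBaselineCorrect:
    def test_constant_epoch_becomes_zero(self):
        conc = conc_from(np.full(1650, 3.5))
        eps = baseline_correct(segment(conc, design(), "tap"))
        np.testing.assert_allclose(eps.epochs, 0.0, atol=1e-12)

    def test_baseline_mean_zero_for_random_epochs(self, rng):
        conc = conc_from(rng.normal(0, 1, 1650))
        eps = baseline_correct(segment(conc, design(), "tap"))
        sel = (eps.times >= -5.0) & (eps.times < 0.0)
        np.testing.assert_allclose(eps.epochs[:, sel].mean(axis=1), 0.0, atol=1e-12)

    def test_idempotent(self, rng):
        conc = conc_from(rng.normal(0, 1, 1650))
        once = baseline_correct(segment(conc, design(), "tap"))
        twice = baseline_correct(once)
        np.testing.assert_allclose(twice.epochs, once.epochs, atol=1e-14)


class TestBlockAverage:
    def test_identical_epochs_average_is_epoch_sem_zero(self):
        conc = conc_from(np.tile(np.sin(np.arange(300) / 20.0), 6)[:1650])
        eps = segment(conc, design(), "tap", window=(-5.0, 15.0))
        # construct truly identical epochs
        eps.epochs = np.tile(eps.epochs[0], (4, 1))
        avg = block_average(eps)
        np.testing.assert_array_equal(avg.mean, eps.epochs[0])
        np.testing.assert_array_equal(avg.sem, 0.0)

    def test_two_epoch_mean(self, rng):
        conc = conc_from(rng.normal(0, 1, 1650))
        eps = segment(conc, design(), "tap")
        eps.epochs = eps.epochs[:2]
        avg = block_average(eps)
        np.testing.assert_allclose(avg.mean, eps.epochs.mean(axis=0), atol=1e-14)

    def test_permutation_invariance(self, rng):
        conc = conc_from(rng.normal(0, 1, 1650))
        eps = segment(conc, design(), "tap")
        avg1 = block_average(eps)
        eps.epochs = eps.epochs[::-1]
        avg2 = block_average(eps)
        np.testing.assert_allclose(avg1.mean, avg2.mean, atol=1e-14)
        np.testing.assert_allclose(avg1.sem, avg2.sem, atol=1e-14)

    def test_sem_scales_inverse_sqrt_n(self):
        # averaging n iid-noise epochs: SEM ratio between n=4 and n=16 is ~2
        rng = np.random.default_rng(99)
        sems = []
        for n in (4, 16):
            epochs = rng.normal(0, 1, (n, 100))
            sem = epochs.std(axis=0, ddof=1).mean() / np.sqrt(n)
            sems.append(sem)
        assert sems[0] / sems[1] == pytest.approx(2.0, rel=0.15)


class TestConditionScalars:
    def test_constant_signal_equal_scalars(self):
        conc = conc_from(np.full(1650, 2.0))
        s = condition_scalars(conc, design(), "tap")
        assert s.task_mean == pytest.approx(2.0) and s.rest_mean == pytest.approx(2.0)

    def test_boxcar_gives_one_zero(self):
        fs = 10.0
        x = np.zeros(1650)
        for m in design():
            if m.label == "tap":
                i = int(m.onset_s * fs)
                x[i:i + int(m.duration_s * fs)] = 1.0
        s = condition_scalars(conc_from(x), design(), "tap")
        assert s.task_mean == pytest.approx(1.0)
        assert s.rest_mean == pytest.approx(0.0)

    def test_dc_shift_moves_both_scalars_equally(self, rng):
        x = rng.normal(0, 1, 1650)
        s0 = condition_scalars(conc_from(x), design(), "tap")
        s1 = condition_scalars(conc_from(x + 7.0), design(), "tap")
        assert s1.task_mean - s0.task_mean == pytest.approx(7.0, abs=1e-9)
        assert s1.rest_mean - s0.rest_mean == pytest.approx(7.0, abs=1e-9)

    def test_task_window_past_block_end_rejected(self):
        conc = conc_from(np.zeros(1650))
        with pytest.raises(ValueError, match="task window"):
            condition_scalars(conc, design(), "tap", task_window_start_s=20.0)
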