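"""Quantitative validation studies run against the simulator's ground truth.

Each function here sets up a synthetic experiment, runs the pipeline on it
and measures performance: filter frequency response, artifact detection and
correction quality, end-to-end evoked-amplitude recovery, and the paired
t-test's type-I calibration and power.  The test suite and the acceptance
script both call these.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import binary_dilation

from . import preprocess as pp
from .pipeline import RunConfig, analyze_recording, recover_amplitude, segment_rmse_reduction
from .stats import paired_t
from .synth import ArtifactSpec, SimulationConfig, generate_block_design, simulate_recording

__all__ = [
    "filter_gain",
    "artifact_benchmark",
    "amplitude_recovery_study",
    "type1_calibration",
    "power_curve",
]


def filter_gain(freq_hz: float, sampling_rate: float = 10.0, duration_s: float = 1200.0,
                params: pp.BandpassParams | None = None, edge_discard_s: float = 100.0):
    """(amplitude, phase_rad) of the band-pass response to a unit sinusoid.

    Measured by sinusoid regression (sin/cos basis at the probe frequency)
    after discarding ``edge_discard_s`` of transient at each end.
    """
    t = np.arange(0.0, duration_s, 1.0 / sampling_rate)
    x = np.sin(2 * np.pi * freq_hz * t)
    od = pp.ODSeries(t, x[:, None], [660.0], np.ones(1), sampling_rate)
    y = pp.bandpass(od, params).od[:, 0]
    sel = (t > edge_discard_s) & (t < t[-1] - edge_discard_s)
    basis = np.column_stack([np.sin(2 * np.pi * freq_hz * t[sel]),
                             np.cos(2 * np.pi * freq_hz * t[sel])])
    c, *_ = np.linalg.lstsq(basis, y[sel], rcond=None)
    return float(np.hypot(*c)), float(np.arctan2(c[1], c[0]))


def _random_artifacts(rng: np.random.Generator, session_duration_s: float,
                      n: int = 3, amplitude: float = 0.5) -> list:
    """Alternating spikes and steps at random interior onsets."""
    kinds = ["spike", "step"]
    arts = []
    for k in range(n):
        onset = float(rng.uniform(20.0, session_duration_s - 25.0))
        arts.append(ArtifactSpec(onset, kinds[k % 2], amplitude, 0.4))
    return arts


def artifact_benchmark(n_recordings: int = 50, seed: int = 0,
                       amplitude: float = 0.5) -> dict:
    """Detection sensitivity/false-flag rate and spline RMSE reduction.

    ``n_recordings`` finger-tapping sessions each receive three injected
    0.5-OD artifacts (spikes and steps alternating).  Sensitivity counts a
    ground-truth artifact sample as found if a flag lies within the +/-0.1 s
    mask tolerance; the false-flag rate is evaluated on samples more than
    1 s away from any injected artifact; RMSE reduction is the in-segment,
    DC-aligned improvement against the artifact-free OD.
    """
    base = SimulationConfig.for_paradigm("finger_tapping")
    root = np.random.SeedSequence(seed)
    sim_seeds = root.generate_state(n_recordings) % (2**31)
    sens, fpr, red = [], [], []
    for i in range(n_recordings):
        rng = np.random.default_rng(sim_seeds[i])
        arts = _random_artifacts(rng, base.session_duration_s, amplitude=amplitude)
        cfg = dataclasses.replace(base, artifacts=arts, seed=int(sim_seeds[i]))
        rec, truth = simulate_recording(cfg)
        od = pp.intensity_to_od(rec)
        mask = pp.detect_motion(od)
        fs = cfg.sampling_rate
        truth_mask = np.zeros(od.n_samples, bool)
        for a, b in truth.artifact_sample_ranges:
            truth_mask[a:b] = True
        tol = max(1, int(round(mask.params.t_mask_s * fs)))
        detected = binary_dilation(mask.mask, iterations=tol)
        sens.append(float(detected[truth_mask].mean()))
        clean = ~binary_dilation(truth_mask, iterations=int(fs))
        fpr.append(float(mask.mask[clean].mean()))
        corrected = pp.spline_correct(od, mask)
        red.append(segment_rmse_reduction(od, corrected, truth.od_no_artifacts,
                                          truth.artifact_sample_ranges))
    return {
        "sensitivity": float(np.mean(sens)),
        "false_flag_rate": float(np.mean(fpr)),
        "rmse_reduction": float(np.mean(red)),
        "n_recordings": n_recordings,
    }


def amplitude_recovery_study(n_seeds: int = 20, noise: bool = True, seed: int = 0,
                             paradigm: str = "finger_tapping") -> dict:
    """Mean pipeline/truth evoked-amplitude ratio over ``n_seeds`` sessions."""
    base = SimulationConfig.for_paradigm(paradigm)
    if not noise:
        base = base.without_noise()
    markers = generate_block_design(base)
    sim_seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    ratios = []
    for s in sim_seeds:
        cfg = dataclasses.replace(base, seed=int(s))
        rec, truth = simulate_recording(cfg)
        run_cfg = RunConfig(simulation=cfg, seed=int(s))
        result = analyze_recording(rec, markers, cfg.paradigm, run_cfg)
        recovered, true_amp = recover_amplitude(result, truth, markers,
                                                cfg.paradigm, run_cfg)
        ratios.append(recovered / true_amp)
    return {"mean_ratio": float(np.mean(ratios)),
            "ratios": [float(r) for r in ratios], "n_seeds": n_seeds}


def type1_calibration(n_sims: int = 2000, n: int = 26, alpha: float = 0.05,
                      seed: int = 0) -> dict:
    """Rejection rate of the paired t-test under the null, with the
    99% binomial band around ``alpha`` for ``n_sims`` replicates."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        a = rng.normal(0.0, 1.0, n)
        b = rng.normal(0.0, 1.0, n)
        if paired_t(a, b).p_two_tailed < alpha:
            rejections += 1
    half = 2.576 * np.sqrt(alpha * (1 - alpha) / n_sims)
    return {"rate": rejections / n_sims, "n_sims": n_sims,
            "lower": alpha - half, "upper": alpha + half}


def power_curve(effects=(0.0, 0.3, 0.6), n_sims: int = 500, n: int = 26,
                alpha: float = 0.05, seed: int = 0) -> list:
    """Rejection rate per injected standardized effect, common seeds."""
    rates = []
    for eff in effects:
        rng = np.random.default_rng(seed)  # common seeds across grid points
        rej = sum(paired_t(rng.normal(eff, 1.0, n), rng.normal(0.0, 1.0, n)).p_two_tailed < alpha
                  for _ in range(n_sims))
        rates.append(rej / n_sims)
    return rates
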