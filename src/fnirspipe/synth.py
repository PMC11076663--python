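"""Forward simulator for single-channel, two-wavelength fNIRS recordings.

Generates raw intensity series with known ground truth by inverting the
analysis chain: a block design is convolved with a canonical double-gamma
hemodynamic response function to give true dHbO/dHbR time courses; these map
to clean dOD per wavelength through the forward modified Beer-Lambert law;
physiological oscillations (cardiac, respiratory, Mayer waves), slow drift,
white sensor noise and step/spike motion artifacts are superposed linearly
in OD space (which keeps the ground-truth bookkeeping exact); intensity is
derived last as I = I0 * 10**(-dOD).

Paradigm timing defaults follow the block designs of the motor, working
memory and divergent-thinking sessions being modeled: finger tapping
15 s rest / 15 s tapping x 5 blocks; 1-back and 2-back 16 s rest /
20 s task x 6 blocks; the self-paced alternate-uses task is approximated by
fixed 30 s pseudo-blocks separated by its 13 s rests.  One trailing rest
period closes every session so the last task block can be epoched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_events import EventMarkers, Marker, RawRecording
from .mbll import MBLLParams, forward_mbll

__all__ = [
    "SimulationConfig",
    "NoiseComponent",
    "ArtifactSpec",
    "GroundTruth",
    "PARADIGMS",
    "hrf_kernel",
    "generate_block_design",
    "simulate_recording",
    "simulate_behavioral",
]

#: (rest_duration_s, task_duration_s, n_blocks) per paradigm
PARADIGMS = {
    "finger_tapping": (15.0, 15.0, 5),
    "nback1": (16.0, 20.0, 6),
    "nback2": (16.0, 20.0, 6),
    "aut": (13.0, 30.0, 5),
}


@dataclass
class NoiseComponent:
    """A sinusoidal physiological noise component, amplitude in OD units."""

    freq_hz: float
    amplitude: float


@dataclass
class ArtifactSpec:
    """One injected motion artifact.

    ``spike``: a Gaussian bump of the given OD amplitude spanning roughly
    ``duration_s``.  ``step``: an abrupt, persistent baseline shift at
    ``onset_s``.  Both are applied identically to every wavelength (motion
    is common-mode).
    """

    onset_s: float
    kind: str  # "spike" | "step"
    amplitude: float  # OD units
    duration_s: float = 0.4


@dataclass
class SimulationConfig:
    """Everything the forward model needs; defaults are the study conditions.

    ``hrf_amplitude_hbo`` is the peak evoked dHbO over the session in mol/L
    (the HRF-convolved design regressor is scaled to unit peak); dHbR
    amplitude is typically negative at about one third the dHbO magnitude.
    Noise amplitudes are OD units; defaults are realistic relative to a
    1 uM evoked response on a 3 cm channel.
    """

    paradigm: str = "finger_tapping"
    sampling_rate: float = 10.0
    n_blocks: int = 5
    rest_duration_s: float = 15.0
    task_duration_s: float = 15.0
    hrf_amplitude_hbo: float = 1.0e-6
    hrf_amplitude_hbr: float = -0.33e-6
    noise_cardiac: NoiseComponent = field(default_factory=lambda: NoiseComponent(1.1, 0.010))
    noise_respiratory: NoiseComponent = field(default_factory=lambda: NoiseComponent(0.3, 0.005))
    noise_mayer: NoiseComponent = field(default_factory=lambda: NoiseComponent(0.1, 0.003))
    noise_white_od: float = 0.002
    drift_slope_per_s: float = 5.0e-5
    drift_quadratic_per_s2: float = 1.0e-7
    artifacts: list = field(default_factory=list)
    baseline_intensity: tuple = (2000.0, 2400.0)
    wavelengths_nm: tuple = (660.0, 880.0)
    mbll: MBLLParams = field(default_factory=MBLLParams)
    seed: int = 0

    def __post_init__(self):
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}; choose from {sorted(PARADIGMS)}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.rest_duration_s <= 0 or self.task_duration_s <= 0:
            raise ValueError("durations must be positive")
        if any(i <= 0 for i in self.baseline_intensity):
            raise ValueError("baseline_intensity must be positive")
        if len(self.baseline_intensity) != len(self.wavelengths_nm):
            raise ValueError("one baseline intensity per wavelength required")

    @classmethod
    def for_paradigm(cls, paradigm: str, **overrides) -> "SimulationConfig":
        """Config with the paradigm's block timings filled in."""
        rest, task, blocks = PARADIGMS[paradigm]
        defaults = dict(paradigm=paradigm, rest_duration_s=rest,
                        task_duration_s=task, n_blocks=blocks)
        defaults.update(overrides)
        return cls(**defaults)

    def without_noise(self) -> "SimulationConfig":
        """Copy with every noise, drift and artifact amplitude zeroed."""
        return replace(
            self,
            noise_cardiac=NoiseComponent(self.noise_cardiac.freq_hz, 0.0),
            noise_respiratory=NoiseComponent(self.noise_respiratory.freq_hz, 0.0),
            noise_mayer=NoiseComponent(self.noise_mayer.freq_hz, 0.0),
            noise_white_od=0.0,
            drift_slope_per_s=0.0,
            drift_quadratic_per_s2=0.0,
            artifacts=[],
        )

    @property
    def session_duration_s(self) -> float:
        # trailing rest closes the session
        return self.n_blocks * (self.rest_duration_s + self.task_duration_s) + self.rest_duration_s


@dataclass
class GroundTruth:
    """Sample-aligned truth for everything the simulator injected."""

    timestamps: np.ndarray
    true_hbo: np.ndarray
    true_hbr: np.ndarray
    clean_od: np.ndarray  # evoked-response OD only (no noise, no artifacts)
    od_no_artifacts: np.ndarray  # clean_od + noise + drift
    artifact_sample_ranges: list  # [(start, stop)] half-open index intervals
    block_onsets: np.ndarray  # task onsets, seconds

    def __post_init__(self):
        n = self.timestamps.size
        for arr in (self.true_hbo, self.true_hbr):
            if arr.size != n:
                raise ValueError("ground truth series length mismatch")
        for a, b in self.artifact_sample_ranges:
            if not (0 <= a < b <= n):
                raise ValueError(f"artifact range ({a}, {b}) outside recording bounds")


def hrf_kernel(sampling_rate: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function.

    Difference of two gamma densities (shape 6 and 16, unit scale) with a
    1/6 undershoot ratio; peak near 5 s, normalized to unit peak amplitude,
    back below 5 % of peak by 25 s.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if duration_s < 20.0:
        raise ValueError("HRF kernel must span at least 20 s")
    t = np.arange(0.0, duration_s, 1.0 / sampling_rate)
    h = sps.gamma.pdf(t, a=6.0, scale=1.0) - sps.gamma.pdf(t, a=16.0, scale=1.0) / 6.0
    return h / h.max()


def generate_block_design(config: SimulationConfig) -> EventMarkers:
    """Alternating rest/task markers for the configured block design.

    Task onsets fall at rest + k*(rest + task), k = 0..n_blocks-1; labels
    carry the paradigm name, rests are labeled ``rest``.  A final rest
    marker closes the session.
    """
    if config.n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rest, task = config.rest_duration_s, config.task_duration_s
    entries = []
    for k in range(config.n_blocks):
        cycle = k * (rest + task)
        entries.append(Marker(cycle, rest, "rest"))
        entries.append(Marker(cycle + rest, task, config.paradigm))
    entries.append(Marker(config.n_blocks * (rest + task), rest, "rest"))
    return EventMarkers(entries)


def _boxcar(config: SimulationConfig, t: np.ndarray) -> np.ndarray:
    box = np.zeros_like(t)
    for m in generate_block_design(config):
        if m.label == config.paradigm:
            box[(t >= m.onset_s) & (t < m.onset_s + m.duration_s)] = 1.0
    return box


def _artifact_od(config: SimulationConfig, t: np.ndarray) -> tuple[np.ndarray, list]:
    """Artifact OD waveform plus ground-truth index ranges."""
    fs = config.sampling_rate
    wave = np.zeros_like(t)
    ranges = []
    n = t.size
    for art in config.artifacts:
        i0 = int(round(art.onset_s * fs))
        i1 = int(round((art.onset_s + art.duration_s) * fs))
        if art.kind == "spike":
            center = art.onset_s + art.duration_s / 2.0
            sd = max(art.duration_s / 4.0, 1.0 / fs)
            wave += art.amplitude * np.exp(-0.5 * ((t - center) / sd) ** 2)
        elif art.kind == "step":
            wave[t >= art.onset_s] += art.amplitude
            i1 = i0 + max(1, int(round(0.2 * fs)))  # truth: the transition region
        else:
            raise ValueError(f"unknown artifact kind {art.kind!r}")
        a, b = max(0, i0), min(n, max(i1, i0 + 1))
        if b > a:
            ranges.append((a, b))
    return wave, ranges


def simulate_recording(config: SimulationConfig) -> tuple[RawRecording, GroundTruth]:
    """Run the forward model; deterministic given ``config.seed``.

    Per-component RNG sub-streams are spawned deterministically from the
    seed, so changing one noise amplitude never reshuffles the others.
    Raises if the combined OD excursion would underflow intensity to a
    non-positive float.
    """
    fs = config.sampling_rate
    n = int(round(config.session_duration_s * fs))
    t = np.arange(n) / fs

    # evoked response: HRF-convolved boxcar, unit peak, scaled to amplitude
    kernel = hrf_kernel(fs)
    box = _boxcar(config, t)
    reg = np.convolve(box, kernel)[:n]
    peak = reg.max()
    if peak > 0:
        reg = reg / peak
    true_hbo = config.hrf_amplitude_hbo * reg
    true_hbr = config.hrf_amplitude_hbr * reg

    clean = forward_mbll(true_hbo, true_hbr, t, config.wavelengths_nm,
                         config.mbll, sampling_rate=fs)
    clean_od = clean.od

    # deterministic per-component sub-streams
    root = np.random.SeedSequence(config.seed)
    keys = ("cardiac", "respiratory", "mayer", "white")
    rngs = dict(zip(keys, (np.random.default_rng(s) for s in root.spawn(len(keys)))))

    n_wl = len(config.wavelengths_nm)
    noise = np.zeros((n, n_wl))
    for name, comp in (("cardiac", config.noise_cardiac),
                       ("respiratory", config.noise_respiratory),
                       ("mayer", config.noise_mayer)):
        phases = rngs[name].uniform(0.0, 2.0 * np.pi, size=n_wl)
        for j in range(n_wl):
            noise[:, j] += comp.amplitude * np.sin(2 * np.pi * comp.freq_hz * t + phases[j])
    if config.noise_white_od > 0:
        noise += rngs["white"].normal(0.0, config.noise_white_od, size=(n, n_wl))
    drift = config.drift_slope_per_s * t + config.drift_quadratic_per_s2 * t**2
    noise += drift[:, None]

    artifact_wave, artifact_ranges = _artifact_od(config, t)
    total_od = clean_od + noise + artifact_wave[:, None]

    i0 = np.asarray(config.baseline_intensity, float)
    with np.errstate(over="ignore"):  # overflow -> inf, rejected just below
        intensity = i0 * np.power(10.0, -total_od)
    if (intensity <= 0).any() or not np.isfinite(intensity).all():
        worst = float(np.abs(total_od).max())
        raise ValueError(
            f"configured noise/artifacts drive intensity non-positive "
            f"(max |OD| = {worst:.3g}); reduce amplitudes"
        )

    rec = RawRecording(
        timestamps=t,
        intensity=intensity,
        wavelengths_nm=list(config.wavelengths_nm),
        source_detector_distance_cm=config.mbll.source_detector_distance_cm,
        sampling_rate=fs,
        device_meta={"simulated": "true", "paradigm": config.paradigm,
                     "seed": str(config.seed)},
    )
    truth = GroundTruth(
        timestamps=t,
        true_hbo=true_hbo,
        true_hbr=true_hbr,
        clean_od=clean_od,
        od_no_artifacts=clean_od + noise,
        artifact_sample_ranges=artifact_ranges,
        block_onsets=generate_block_design(config).onsets(config.paradigm),
    )
    return rec, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Sidecar delimited file mirroring the recording's time base."""
    df = pd.DataFrame({
        "time_s": truth.timestamps,
        "true_hbo": truth.true_hbo,
        "true_hbr": truth.true_hbr,
    })
    for j in range(truth.clean_od.shape[1]):
        df[f"clean_od_{j}"] = truth.clean_od[:, j]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# format=fnirspipe-groundtruth-v1\n")
        ranges = ";".join(f"{a}-{b}" for a, b in truth.artifact_sample_ranges)
        fh.write(f"# artifact_sample_ranges={ranges}\n")
        fh.write("# block_onsets_s=" + ",".join(f"{o:g}" for o in truth.block_onsets) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def simulate_behavioral(n_participants: int, accuracy_drop: float = 0.2,
                        rt_increase_s: float = 0.33, seed: int = 0,
                        mean_accuracy_a: float = 0.86, accuracy_sd: float = 0.15,
                        mean_rt_a_s: float = 0.66, rt_sd_s: float = 0.12) -> pd.DataFrame:
    """Per-participant accuracy/RT pairs for two task conditions.

    Condition b is condition a shifted by ``-accuracy_drop`` in accuracy and
    ``+rt_increase_s`` in reaction time, with independent between-subject
    noise per condition.  Accuracy is truncated to [0, 1], RT to > 0, so a
    configured shift can be attenuated near the bounds (documented; a
    degenerate zero-variance configuration is allowed and yields exactly the
    configured shift).
    """
    if n_participants < 3:
        raise ValueError("need n_participants >= 3")
    rng = np.random.default_rng(seed)
    acc_a = mean_accuracy_a + rng.normal(0.0, accuracy_sd, n_participants)
    acc_b = acc_a - accuracy_drop + rng.normal(0.0, accuracy_sd / 2, n_participants)
    rt_a = mean_rt_a_s + rng.normal(0.0, rt_sd_s, n_participants)
    rt_b = rt_a + rt_increase_s + rng.normal(0.0, rt_sd_s / 2, n_participants)
    return pd.DataFrame({
        "participant": np.arange(1, n_participants + 1),
        "accuracy_a": np.clip(acc_a, 0.0, 1.0),
        "accuracy_b": np.clip(acc_b, 0.0, 1.0),
        "rt_a_s": np.maximum(rt_a, 0.05),
        "rt_b_s": np.maximum(rt_b, 0.05),
    })
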