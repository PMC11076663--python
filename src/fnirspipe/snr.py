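"""Per-task signal-to-noise assessment.

Three documented SNR definitions sit behind one interface; every report
names the definition it used.  The default, ``amplitude_ratio``, is the
peak-to-peak amplitude of the task-evoked block average divided by the
standard deviation of the de-meaned rest-period signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .epochs import baseline_correct, block_average, segment
from .io_events import EventMarkers
from .mbll import ConcentrationSeries

__all__ = ["SNRReport", "compute_snr", "DEFINITIONS"]

DEFINITIONS = ("amplitude_ratio", "power_ratio", "db")


@dataclass
class SNRReport:
    task: str
    snr_value: float
    definition_id: str
    signal_window: tuple
    noise_window: str
    n_task_blocks: int
    n_rest_segments: int


def _evoked_prediction(conc, markers, condition, avg, epoch_window):
    """Block average tiled back onto the session at each task onset.

    Subtracting this from the recording leaves the non-evoked residual;
    where predictions from consecutive epochs overlap they are averaged.
    """
    fs = conc.sampling_rate
    t0 = conc.timestamps[0]
    n = conc.delta_hbo.size
    pred = np.zeros(n)
    weight = np.zeros(n)
    pre = epoch_window[0]
    m = avg.mean - avg.mean[0]  # anchor at epoch start to limit seams
    for onset in markers.onsets(condition):
        i = int(round((onset + pre - t0) * fs))
        a, b = max(i, 0), min(i + m.size, n)
        if b > a:
            pred[a:b] += m[a - i:b - i]
            weight[a:b] += 1.0
    covered = weight > 0
    pred[covered] /= weight[covered]
    return pred


def _rest_noise_sd(x, conc, markers, rest_label):
    """SD of the per-segment de-meaned residual over all rest periods."""
    fs = conc.sampling_rate
    t0 = conc.timestamps[0]
    pieces = []
    for m in markers:
        if m.label != rest_label:
            continue
        i0 = max(0, int(round((m.onset_s - t0) * fs)))
        i1 = min(x.size, int(round((m.onset_s + m.duration_s - t0) * fs)))
        if i1 - i0 >= 2:
            pieces.append(x[i0:i1] - x[i0:i1].mean())
    if not pieces:
        raise ValueError(f"no usable rest segments labeled {rest_label!r}")
    return float(np.concatenate(pieces).std(ddof=1)), len(pieces)


def compute_snr(conc: ConcentrationSeries, markers: EventMarkers, condition: str,
                definition: str = "amplitude_ratio", rest_label: str = "rest",
                epoch_window: tuple = (-5.0, 25.0)) -> SNRReport:
    """SNR of the task-evoked dHbO response for one condition.

    signal = peak-to-peak of the baseline-corrected block average over
    ``epoch_window``; noise = SD of the rest-segment residual signal, i.e.
    the recording minus the evoked estimate (the block average tiled onto
    the session), per-segment de-meaned — so the hemodynamic tail that
    spills into rest periods does not count as noise.  ``power_ratio``
    squares the amplitude ratio, ``db`` is 20*log10 of it.  A zero-variance
    rest segment yields +inf with a warning.
    """
    if definition not in DEFINITIONS:
        raise ValueError(f"unknown SNR definition {definition!r}; choose from {DEFINITIONS}")
    ep = baseline_correct(segment(conc, markers, condition, window=epoch_window))
    avg = block_average(ep)
    amplitude = float(np.ptp(avg.mean))
    residual = conc.delta_hbo - _evoked_prediction(conc, markers, condition, avg, epoch_window)
    noise_sd, n_rest = _rest_noise_sd(residual, conc, markers, rest_label)
    if noise_sd == 0.0:
        warnings.warn("zero-variance rest segment: SNR reported as inf")
        ratio = np.inf
    else:
        ratio = amplitude / noise_sd
    value = {"amplitude_ratio": ratio,
             "power_ratio": ratio**2,
             "db": 20.0 * np.log10(ratio) if ratio > 0 else -np.inf}[definition]
    return SNRReport(
        task=condition,
        snr_value=float(value),
        definition_id=definition,
        signal_window=epoch_window,
        noise_window=f"all {rest_label!r} periods, per-segment de-meaned",
        n_task_blocks=avg.n_epochs,
        n_rest_segments=n_rest,
    )
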