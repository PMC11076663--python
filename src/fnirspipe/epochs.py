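"""Task-locked segmentation, baseline correction and block averaging.

Epochs are cut around task-onset markers, baseline-corrected to a pre-onset
window, and averaged pointwise across blocks.  ``condition_scalars`` reduces
a run to the two numbers entering the paired rest-vs-task test: mean dHbO
over the task analysis window and over the rest analysis window, each
averaged across blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_events import EventMarkers
from .mbll import ConcentrationSeries

__all__ = [
    "EpochSet",
    "BlockAverage",
    "ConditionSummary",
    "segment",
    "baseline_correct",
    "block_average",
    "condition_scalars",
]

log = logging.getLogger(__name__)

# Default analysis windows (seconds relative to block onsets).  Task window
# starts 5 s post-onset to skip the hemodynamic rise; rest window is the
# final 10 s of each rest period, avoiding the post-task undershoot.
TASK_WINDOW_START_S = 5.0
REST_WINDOW_S = 10.0


@dataclass
class EpochSet:
    condition: str
    epochs: np.ndarray  # (n_epochs, n_samples)
    times: np.ndarray  # seconds relative to onset
    epoch_window: tuple  # (pre_s, post_s); pre_s <= 0
    baseline_window: tuple  # (start_s, end_s) relative to onset
    onsets_s: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.epochs = np.atleast_2d(np.asarray(self.epochs, float))
        pre, post = self.epoch_window
        b0, b1 = self.baseline_window
        if not (pre <= b0 < b1 <= post):
            raise ValueError("baseline window must lie within the epoch window")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass
class BlockAverage:
    condition: str
    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_epochs: int


@dataclass
class ConditionSummary:
    """Per-run scalars entering the paired test, with window provenance."""

    condition: str
    task_mean: float
    rest_mean: float
    task_window: tuple
    rest_window: tuple
    n_task_blocks: int
    n_rest_blocks: int


def _signal(conc: ConcentrationSeries, chromophore: str) -> np.ndarray:
    if chromophore == "hbo":
        return conc.delta_hbo
    if chromophore == "hbr":
        return conc.delta_hbr
    raise ValueError(f"unknown chromophore {chromophore!r}")


def segment(conc: ConcentrationSeries, markers: EventMarkers, condition: str,
            window: tuple = (-5.0, 25.0), baseline_window: tuple | None = None,
            chromophore: str = "hbo") -> EpochSet:
    """Cut epochs around every marker labeled ``condition``.

    ``window = (pre_s, post_s)`` relative to onset, pre_s <= 0.  Epochs
    overlapping the recording edges are dropped (never zero-padded) with a
    logged count.  Default baseline window: (pre_s, 0).
    """
    pre, post = window
    if pre > 0 or post <= pre:
        raise ValueError("epoch window must satisfy pre_s <= 0 < post_s")
    onsets = markers.onsets(condition)
    if onsets.size == 0:
        raise ValueError(f"no markers labeled {condition!r}")
    baseline_window = baseline_window or (pre, 0.0)
    fs = conc.sampling_rate
    t0 = conc.timestamps[0]
    n = conc.timestamps.size
    n_pre = int(round(-pre * fs))
    n_post = int(round(post * fs))
    x = _signal(conc, chromophore)
    rows, kept = [], []
    for onset in onsets:
        i = int(round((onset - t0) * fs))
        if i - n_pre < 0 or i + n_post > n:
            continue
        rows.append(x[i - n_pre:i + n_post])
        kept.append(onset)
    dropped = onsets.size - len(rows)
    if dropped:
        log.info("segment(%s): dropped %d/%d epoch(s) at recording edges",
                 condition, dropped, onsets.size)
    if not rows:
        raise ValueError(f"all {onsets.size} epochs for {condition!r} fall outside the recording")
    times = (np.arange(-n_pre, n_post)) / fs
    return EpochSet(condition, np.vstack(rows), times, window, baseline_window,
                    np.asarray(kept), fs)


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each epoch's mean over the baseline window."""
    b0, b1 = epochs.baseline_window
    sel = (epochs.times >= b0) & (epochs.times < b1)
    if not sel.any():
        raise ValueError("baseline window selects no samples")
    corrected = epochs.epochs - epochs.epochs[:, sel].mean(axis=1, keepdims=True)
    return EpochSet(epochs.condition, corrected, epochs.times, epochs.epoch_window,
                    epochs.baseline_window, epochs.onsets_s, epochs.sampling_rate)


def block_average(epochs: EpochSet) -> BlockAverage:
    """Pointwise mean and standard error across epochs."""
    if epochs.n_epochs < 1:
        raise ValueError("need at least one epoch")
    mean = epochs.epochs.mean(axis=0)
    if epochs.n_epochs > 1:
        sem = epochs.epochs.std(axis=0, ddof=1) / np.sqrt(epochs.n_epochs)
    else:
        sem = np.zeros_like(mean)
    return BlockAverage(epochs.condition, epochs.times, mean, sem, epochs.n_epochs)


def condition_scalars(conc: ConcentrationSeries, markers: EventMarkers,
                      condition: str, rest_label: str = "rest",
                      task_window_start_s: float = TASK_WINDOW_START_S,
                      rest_window_s: float = REST_WINDOW_S,
                      chromophore: str = "hbo") -> ConditionSummary:
    """Task and rest scalars for one run.

    Task scalar: mean signal from ``task_window_start_s`` after each task
    onset to the end of that task block, averaged across blocks.  Rest
    scalar: mean over the final ``rest_window_s`` seconds of each rest
    period.  Windows may not overlap (validated per block pair).
    """
    fs = conc.sampling_rate
    t0 = conc.timestamps[0]
    n = conc.timestamps.size
    x = _signal(conc, chromophore)

    def window_mean(start_s: float, end_s: float) -> float | None:
        i0 = int(round((start_s - t0) * fs))
        i1 = int(round((end_s - t0) * fs))
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 <= i0:
            return None
        return float(x[i0:i1].mean())

    task_markers = [m for m in markers if m.label == condition]
    rest_markers = [m for m in markers if m.label == rest_label]
    if not task_markers:
        raise ValueError(f"no markers labeled {condition!r}")
    if not rest_markers:
        raise ValueError(f"no markers labeled {rest_label!r}")
    for m in task_markers:
        if task_window_start_s >= m.duration_s:
            raise ValueError(
                f"task window start {task_window_start_s}s reaches past the "
                f"{m.duration_s}s task block at {m.onset_s}s"
            )
    task_vals = [v for m in task_markers
                 if (v := window_mean(m.onset_s + task_window_start_s,
                                      m.onset_s + m.duration_s)) is not None]
    rest_vals = [v for m in rest_markers
                 if (v := window_mean(m.onset_s + max(0.0, m.duration_s - rest_window_s),
                                      m.onset_s + m.duration_s)) is not None]
    if not task_vals or not rest_vals:
        raise ValueError("analysis windows select no samples inside the recording")
    return ConditionSummary(
        condition=condition,
        task_mean=float(np.mean(task_vals)),
        rest_mean=float(np.mean(rest_vals)),
        task_window=(task_window_start_s, "task_end"),
        rest_window=(f"-{rest_window_s}", "rest_end"),
        n_task_blocks=len(task_vals),
        n_rest_blocks=len(rest_vals),
    )
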