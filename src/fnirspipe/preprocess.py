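"""Signal conditioning for single-channel fNIRS recordings.

Four-stage chain applied to the raw two-wavelength intensity series:

1. ``intensity_to_od``  — convert to optical density, OD(t) = -log10(I/I0);
2. ``detect_motion``    — flag abrupt changes (windowed peak-to-peak against an
   amplitude threshold and a robust-scale multiplier);
3. ``spline_correct``   — MARA-style smoothing-spline subtraction inside
   flagged segments with sequential re-leveling;
4. ``bandpass``         — zero-phase Butterworth band-pass, 0.01-0.1 Hz by
   default, isolating the hemodynamic band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.interpolate import make_smoothing_spline

from .io_events import RawRecording

__all__ = [
    "ODSeries",
    "ArtifactDetectionParams",
    "ArtifactMask",
    "BandpassParams",
    "intensity_to_od",
    "detect_motion",
    "spline_correct",
    "bandpass",
]

log = logging.getLogger(__name__)


@dataclass
class ODSeries:
    """Optical density per wavelength on the source recording's time base."""

    timestamps: np.ndarray
    od: np.ndarray  # (n_samples, n_wavelengths)
    wavelengths_nm: list
    reference_intensity: np.ndarray
    sampling_rate: float = 10.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, float)
        self.od = np.atleast_2d(np.asarray(self.od, float))
        if self.od.shape[0] != self.timestamps.size:
            raise ValueError("od rows must match timestamps")
        if not np.isfinite(self.od).all():
            raise ValueError("OD contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.timestamps.size

    def replace_od(self, od: np.ndarray, **meta) -> "ODSeries":
        return ODSeries(self.timestamps, od, list(self.wavelengths_nm),
                        np.asarray(self.reference_intensity), self.sampling_rate,
                        {**self.meta, **meta})


@dataclass
class ArtifactDetectionParams:
    """Motion-artifact detection parameters.

    ``t_motion_s``: sliding-window length over which abrupt change is
    assessed.  ``t_mask_s``: half-width of the dilation applied around each
    detection.  ``stdev_thresh``: multiplier applied to a robust scale
    (1.4826 x MAD) of the series' first differences.  ``amp_thresh``:
    absolute peak-to-peak OD threshold.
    """

    t_motion_s: float = 0.2
    t_mask_s: float = 0.1
    stdev_thresh: float = 10.0
    amp_thresh: float = 0.3

    def __post_init__(self):
        for name in ("t_motion_s", "t_mask_s", "stdev_thresh", "amp_thresh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ArtifactMask:
    """Boolean artifact annotation, pooled across wavelengths."""

    mask: np.ndarray  # (n_samples,) bool, OR-ed over wavelengths
    params: ArtifactDetectionParams
    segments: list  # [(start, stop) half-open index intervals], maximal runs
    per_wavelength: np.ndarray | None = None  # (n_samples, n_wl) pre-pooling

    @property
    def n_flagged(self) -> int:
        return int(self.mask.sum())


@dataclass
class BandpassParams:
    low_cutoff_hz: float = 0.01
    high_cutoff_hz: float = 0.1
    order: int = 3
    design: str = "butter"

    def validate(self, sampling_rate: float) -> None:
        if not (0 < self.low_cutoff_hz < self.high_cutoff_hz):
            raise ValueError("need 0 < low_cutoff < high_cutoff")
        if self.high_cutoff_hz >= sampling_rate / 2:
            raise ValueError(
                f"high_cutoff {self.high_cutoff_hz} Hz >= Nyquist "
                f"{sampling_rate / 2} Hz"
            )
        if self.design != "butter":
            raise ValueError(f"unknown filter design {self.design!r}")


def intensity_to_od(rec: RawRecording, reference: str = "mean_full",
                    reference_window_s: tuple | None = None) -> ODSeries:
    """Convert raw intensity to optical density, OD = -log10(I / I0).

    ``reference`` selects I0: ``mean_full`` (mean intensity over the whole
    recording, the Homer convention) or ``mean_window`` (mean over
    ``reference_window_s = (start_s, end_s)``, for baseline-referenced OD).
    """
    if (rec.intensity <= 0).any():
        raise ValueError("non-positive intensity; cannot take log")
    if reference == "mean_full":
        i0 = rec.intensity.mean(axis=0)
    elif reference == "mean_window":
        if reference_window_s is None:
            raise ValueError("mean_window reference requires reference_window_s")
        t0, t1 = reference_window_s
        sel = (rec.timestamps >= t0) & (rec.timestamps < t1)
        if not sel.any():
            raise ValueError(f"reference window {reference_window_s} selects no samples")
        i0 = rec.intensity[sel].mean(axis=0)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    od = -np.log10(rec.intensity / i0)
    return ODSeries(rec.timestamps, od, list(rec.wavelengths_nm), i0,
                    rec.sampling_rate, {"od_reference": reference})


def _runs(mask: np.ndarray) -> list:
    """Maximal runs of True as half-open (start, stop) index intervals."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return list(zip(starts.tolist(), stops.tolist()))


def robust_diff_scale(x: np.ndarray) -> float:
    """1.4826 x median absolute deviation of first differences.

    An artifact-resistant stand-in for the standard deviation of the
    sample-to-sample signal change: a handful of artifact samples barely
    move the median, where they would dominate a raw SD.
    """
    d = np.diff(x)
    return 1.4826 * float(np.median(np.abs(d - np.median(d))))


def detect_motion(od: ODSeries, params: ArtifactDetectionParams | None = None) -> ArtifactMask:
    """Flag samples showing abrupt OD change indicative of motion.

    For every window of ``t_motion_s`` seconds, the windowed peak-to-peak OD
    excursion is compared against (a) ``amp_thresh`` and (b)
    ``stdev_thresh`` x the robust scale of the series' first differences.  A
    sample is flagged when any window covering it trips either criterion;
    flagged regions are then dilated by +/-``t_mask_s``.  Per-wavelength flags
    are OR-ed into one pooled mask (motion is common-mode across wavelengths).
    """
    params = params or ArtifactDetectionParams()
    fs = od.sampling_rate
    w = int(round(params.t_motion_s * fs))
    if w < 2:
        raise ValueError(
            f"t_motion_s={params.t_motion_s}s spans {w} sample(s) at "
            f"{fs} Hz; need at least 2"
        )
    if od.n_samples <= w:
        raise ValueError("recording shorter than the detection window")
    n_mask = int(round(params.t_mask_s * fs))
    per_wl = np.zeros_like(od.od, dtype=bool)
    for j in range(od.od.shape[1]):
        x = od.od[:, j]
        sigma = robust_diff_scale(x)
        ptp = (ndimage.maximum_filter1d(x, size=w, mode="nearest")
               - ndimage.minimum_filter1d(x, size=w, mode="nearest"))
        hit = (ptp > params.amp_thresh) | (ptp > params.stdev_thresh * sigma)
        # a hit at the window centered on i implicates every sample the
        # window covers, then +/- t_mask_s on top
        per_wl[:, j] = ndimage.binary_dilation(hit, iterations=max(1, w // 2 + n_mask))
    pooled = per_wl.any(axis=1)
    segs = _runs(pooled)
    if segs:
        log.info("detect_motion: %d segment(s), %d/%d samples flagged",
                 len(segs), int(pooled.sum()), pooled.size)
    return ArtifactMask(mask=pooled, params=params, segments=segs, per_wavelength=per_wl)


def _seg_window(length: int, fs: float) -> int:
    """Re-leveling window: min(len/3, 2 s), at least 1 sample."""
    return max(1, min(length // 3, int(round(2.0 * fs))))


def spline_correct(od: ODSeries, mask: ArtifactMask, tension: float = 0.99) -> ODSeries:
    """MARA-style spline correction of motion-contaminated segments.

    Within each flagged segment a cubic smoothing spline with smoothing
    parameter p = ``tension`` (the 0..1 fit/smoothness trade-off; mapped to
    the regularization weight lambda = (1-p)/p on the sample-index grid, so
    the fit tracks even single-sample spikes) is fit and subtracted,
    removing the artifact's trajectory.  The series is then reassembled
    piece by piece, shifting each piece by a constant so the means of short
    boundary windows (min of one third of the piece and 2 s) match the most
    recent *clean* level — clean pieces re-level against the clean piece
    before the artifact, bridging the gap, so persistent baseline steps are
    eliminated rather than frozen into the record.  Clean samples are thus
    preserved up to a per-piece constant offset, which the subsequent
    band-pass removes anyway.  Segments touching the recording edge are
    re-leveled one-sidedly.
    """
    if not 0 < tension < 1:
        raise ValueError("tension must be in (0, 1)")
    if mask.mask.size != od.n_samples:
        raise ValueError("mask length does not match series")
    if not mask.segments:
        return od
    fs = od.sampling_rate
    lam = (1.0 - tension) / tension
    bounds = sorted({0, od.n_samples, *(i for s in mask.segments for i in s)})
    pieces = [(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]
    is_artifact = [bool(mask.mask[a]) for a, b in pieces]
    out = od.od.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        # pass 1: replace artifact segments by their spline residual
        for a, b in mask.segments:
            y = col[a:b]
            if b - a >= 4:
                idx = np.arange(b - a, dtype=float)
                spl = make_smoothing_spline(idx, y, lam=lam)
                col[a:b] = y - spl(idx)
            else:  # too short for a cubic spline: remove the linear trend
                col[a:b] = y - np.linspace(y[0], y[-1], b - a)
        # pass 2: sequential re-leveling against the last clean level
        ref_level = None
        for k, (a, b) in enumerate(pieces):
            w = _seg_window(b - a, fs)
            if k > 0 and ref_level is not None:
                col[a:b] += ref_level - col[a:a + w].mean()
            if not is_artifact[k] or ref_level is None:
                ref_level = col[b - w:b].mean()
        out[:, j] = col
    n_edge = sum(1 for a, b in mask.segments if a == 0 or b == od.n_samples)
    if n_edge:
        log.info("spline_correct: %d segment(s) at recording edge, one-sided re-leveling", n_edge)
    return od.replace_od(out, spline_tension=tension)


def bandpass(od: ODSeries, params: BandpassParams | None = None) -> ODSeries:
    """Zero-phase Butterworth band-pass.

    A 3rd-order Butterworth band-pass applied forward-backward
    (``sosfiltfilt``; effective 6th order, no passband group delay).  Edge
    transients are handled by odd-reflection padding of ``1/low_cutoff``
    seconds; recordings shorter than one pad length are rejected rather than
    silently truncated.
    """
    params = params or BandpassParams()
    params.validate(od.sampling_rate)
    fs = od.sampling_rate
    padlen = int(round(fs / params.low_cutoff_hz))
    if od.n_samples <= padlen:
        raise ValueError(
            f"recording ({od.n_samples} samples) shorter than the filter pad "
            f"length ({padlen} samples = 1/low_cutoff); refusing to filter"
        )
    sos = signal.butter(params.order, [params.low_cutoff_hz, params.high_cutoff_hz],
                        btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, od.od, axis=0, padtype="odd", padlen=padlen)
    return od.replace_od(filtered, bandpass=(params.low_cutoff_hz, params.high_cutoff_hz),
                         filter_order=params.order, filter_design=params.design)
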