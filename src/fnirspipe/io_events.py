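"""Delimited-file readers/writers for raw recordings and event markers.

File dialect (both formats): UTF-8, comma-delimited, '.' decimal point,
``#``-prefixed header lines carrying ``key=value`` metadata, then a column
header row, then one row per sample/marker.  Timestamps are seconds relative
to recording start.  No locale dependence.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RawRecording",
    "EventMarkers",
    "Marker",
    "read_recording",
    "write_recording",
    "read_markers",
    "write_markers",
]


class FormatError(ValueError):
    """Raised on malformed input files; carries a machine-readable position."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class RawRecording:
    """Timestamped multi-wavelength light-intensity series.

    Attributes
    ----------
    timestamps : ndarray, seconds, strictly increasing, 0-based
    intensity : ndarray, shape (n_samples, n_wavelengths), detector units, > 0
    wavelengths_nm : list of float
    source_detector_distance_cm : float
    sampling_rate : float
        Nominal rate; the median timestamp increment must agree within 10 %.
    device_meta : dict
        Free-form key-value metadata (device name, firmware, ...).
    """

    timestamps: np.ndarray
    intensity: np.ndarray
    wavelengths_nm: list
    source_detector_distance_cm: float = 3.0
    sampling_rate: float = 10.0
    device_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.intensity = np.atleast_2d(np.asarray(self.intensity, dtype=float))
        if self.intensity.shape[0] != self.timestamps.size:
            raise ValueError(
                f"intensity has {self.intensity.shape[0]} rows but "
                f"{self.timestamps.size} timestamps"
            )
        if len(self.wavelengths_nm) != self.intensity.shape[1]:
            raise ValueError(
                f"{len(self.wavelengths_nm)} wavelengths declared for "
                f"{self.intensity.shape[1]} intensity columns"
            )
        bad = np.flatnonzero(~(self.intensity > 0).all(axis=1))
        if bad.size:
            raise ValueError(
                f"non-positive intensity at sample {bad[0]} "
                f"(row values {self.intensity[bad[0]].tolist()})"
            )
        dt = np.diff(self.timestamps)
        if dt.size and not (dt > 0).all():
            i = int(np.flatnonzero(dt <= 0)[0])
            raise ValueError(f"timestamps not strictly increasing at sample {i + 1}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if dt.size:
            nominal = 1.0 / self.sampling_rate
            med = float(np.median(dt))
            if abs(med - nominal) > 0.1 * nominal:
                raise ValueError(
                    f"median timestamp increment {med:.6g}s deviates >10% from "
                    f"nominal 1/sampling_rate={nominal:.6g}s"
                )

    @property
    def n_samples(self) -> int:
        return self.timestamps.size

    @property
    def duration_s(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0]) if self.n_samples else 0.0


@dataclass
class Marker:
    onset_s: float
    duration_s: float
    label: str


@dataclass
class EventMarkers:
    """Ordered event stream of (onset, duration, label) triples."""

    entries: list = field(default_factory=list)

    def __post_init__(self):
        prev = -np.inf
        for i, m in enumerate(self.entries):
            if m.duration_s < 0:
                raise ValueError(f"marker {i} ({m.label!r}): negative duration")
            if not m.label:
                raise ValueError(f"marker {i}: empty label")
            if m.onset_s < prev:
                raise ValueError(f"marker {i} ({m.label!r}): onsets must be non-decreasing")
            prev = m.onset_s

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def select(self, label: str) -> "EventMarkers":
        return EventMarkers([m for m in self.entries if m.label == label])

    def onsets(self, label: str | None = None) -> np.ndarray:
        ms = self.entries if label is None else [m for m in self.entries if m.label == label]
        return np.array([m.onset_s for m in ms], dtype=float)


def _parse_header(path) -> tuple[dict, int]:
    """Read '#'-prefixed key=value lines; return (meta, n_header_lines)."""
    meta: dict = {}
    n = 0
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            if not raw.startswith("#"):
                break
            n += 1
            body = raw[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta, n


def write_recording(rec: RawRecording, path) -> None:
    """Write a recording with a self-describing header (17 significant digits)."""
    buf = io.StringIO()
    buf.write("# format=fnirspipe-recording-v1\n")
    buf.write("# wavelengths_nm=" + ",".join(f"{w:g}" for w in rec.wavelengths_nm) + "\n")
    buf.write(f"# source_detector_distance_cm={rec.source_detector_distance_cm:.17g}\n")
    buf.write(f"# sampling_rate_hz={rec.sampling_rate:.17g}\n")
    for k, v in rec.device_meta.items():
        buf.write(f"# meta.{k}={v}\n")
    cols = ["time_s"] + [f"intensity_{w:g}nm" for w in rec.wavelengths_nm]
    buf.write(",".join(cols) + "\n")
    data = np.column_stack([rec.timestamps, rec.intensity])
    np.savetxt(buf, data, delimiter=",", fmt="%.17g")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_recording(path) -> RawRecording:
    """Read and validate a recording written by :func:`write_recording`.

    Validation failures name the first offending data row (1-based file line).
    """
    meta, n_header = _parse_header(path)
    if "wavelengths_nm" not in meta or "sampling_rate_hz" not in meta:
        raise FormatError(f"{path}: header must declare wavelengths_nm and sampling_rate_hz")
    wavelengths = [float(w) for w in meta["wavelengths_nm"].split(",")]
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.shape[1] != 1 + len(wavelengths):
        raise FormatError(
            f"{path}: expected {1 + len(wavelengths)} columns, found {df.shape[1]}"
        )
    ts = df.iloc[:, 0].to_numpy(float)
    inten = df.iloc[:, 1:].to_numpy(float)
    # first file line of data = header lines + column-header row + 1
    offset = n_header + 2
    bad = np.flatnonzero(~(inten > 0).all(axis=1))
    if bad.size:
        raise FormatError("non-positive intensity", line=int(bad[0]) + offset)
    dt = np.diff(ts)
    nonmono = np.flatnonzero(dt <= 0)
    if nonmono.size:
        raise FormatError("non-monotonic timestamp", line=int(nonmono[0]) + 1 + offset)
    device_meta = {k[5:]: v for k, v in meta.items() if k.startswith("meta.")}
    return RawRecording(
        timestamps=ts,
        intensity=inten,
        wavelengths_nm=wavelengths,
        source_detector_distance_cm=float(meta.get("source_detector_distance_cm", 3.0)),
        sampling_rate=float(meta["sampling_rate_hz"]),
        device_meta=device_meta,
    )


def write_markers(markers: EventMarkers, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# format=fnirspipe-markers-v1\n")
        fh.write("onset_s,duration_s,label\n")
        for m in markers:
            fh.write(f"{m.onset_s:.17g},{m.duration_s:.17g},{m.label}\n")


def read_markers(path) -> EventMarkers:
    meta, n_header = _parse_header(path)
    df = pd.read_csv(path, comment="#", dtype={"label": str}, float_precision="round_trip")
    required = {"onset_s", "duration_s", "label"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: marker file needs columns {sorted(required)}")
    entries = []
    prev = -np.inf
    for i, row in df.iterrows():
        line = int(i) + n_header + 2
        onset, dur = float(row["onset_s"]), float(row["duration_s"])
        if dur < 0:
            raise FormatError("negative duration", line=line)
        if onset < prev:
            raise FormatError("out-of-order onset", line=line)
        prev = onset
        entries.append(Marker(onset, dur, str(row["label"])))
    return EventMarkers(entries)
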