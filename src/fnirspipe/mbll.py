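"""Modified Beer-Lambert law: optical-density changes <-> chromophore changes.

The modified Beer-Lambert law (MBLL) models the change in optical density at
wavelength ``lambda`` as a linear mixture of oxy- and deoxyhemoglobin
concentration changes::

    dOD(lambda) = [eps_HbO(lambda) * dHbO + eps_HbR(lambda) * dHbR] * d * DPF(lambda)

where ``eps`` are decadic molar extinction coefficients (cm^-1 M^-1), ``d``
the source-detector distance (cm) and ``DPF`` the dimensionless differential
pathlength factor correcting geometric distance to effective photon path.
With two distinct wavelengths this is a 2x2 linear system solved exactly per
sample; concentrations are in mol/L.

Scattering losses are assumed constant over the recording, so they cancel in
*changes* of OD; no partial-volume correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ODSeries

__all__ = [
    "ExtinctionTable",
    "MBLLParams",
    "ConcentrationSeries",
    "od_to_concentration",
    "forward_mbll",
]

_DATA_FILE = Path(__file__).parent / "data" / "extinction_hb.csv"


@dataclass
class ExtinctionTable:
    """Map (wavelength_nm, chromophore) -> decadic extinction coefficient.

    Coefficients are in cm^-1 / (mol/L).  ``source`` records provenance.
    Lookups interpolate linearly between tabulated wavelengths.
    """

    wavelengths_nm: np.ndarray
    hbo: np.ndarray
    hbr: np.ndarray
    source: str = "Gratzer/Kollias compilation (Prahl 1998), decadic"

    def __post_init__(self):
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, float)
        self.hbo = np.asarray(self.hbo, float)
        self.hbr = np.asarray(self.hbr, float)
        if (self.hbo <= 0).any() or (self.hbr <= 0).any():
            raise ValueError("extinction coefficients must be positive")

    @classmethod
    def from_csv(cls, path=_DATA_FILE) -> "ExtinctionTable":
        df = pd.read_csv(path, comment="#")
        return cls(df["wavelength_nm"].to_numpy(), df["hbo"].to_numpy(), df["hbr"].to_numpy(),
                   source=str(path))

    def coefficients(self, wavelength_nm: float) -> tuple[float, float]:
        """(eps_HbO, eps_HbR) at ``wavelength_nm``, linearly interpolated."""
        w = self.wavelengths_nm
        if not (w.min() <= wavelength_nm <= w.max()):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside tabulated range "
                f"[{w.min():g}, {w.max():g}]"
            )
        return (
            float(np.interp(wavelength_nm, w, self.hbo)),
            float(np.interp(wavelength_nm, w, self.hbr)),
        )


@dataclass
class MBLLParams:
    """Geometry and pathlength parameters of the conversion.

    ``dpf`` may be a scalar (applied to all wavelengths) or a mapping
    wavelength -> DPF.  Defaults: 3.0 cm separation, DPF 6.0 — common
    adult-forehead conventions for a continuous-wave device.
    """

    source_detector_distance_cm: float = 3.0
    dpf: float | dict = 6.0
    extinction: ExtinctionTable = field(default_factory=ExtinctionTable.from_csv)
    max_condition_number: float = 1e3

    def __post_init__(self):
        if self.source_detector_distance_cm <= 0:
            raise ValueError("source_detector_distance_cm must be positive")
        vals = self.dpf.values() if isinstance(self.dpf, dict) else [self.dpf]
        if any(v <= 0 for v in vals):
            raise ValueError("dpf must be positive")

    def dpf_at(self, wavelength_nm: float) -> float:
        if isinstance(self.dpf, dict):
            return float(self.dpf[wavelength_nm])
        return float(self.dpf)

    def system_matrix(self, wavelengths_nm) -> np.ndarray:
        """Rows: [eps_HbO, eps_HbR] * d * DPF(lambda), one per wavelength."""
        rows = []
        for w in wavelengths_nm:
            e_hbo, e_hbr = self.extinction.coefficients(w)
            scale = self.source_detector_distance_cm * self.dpf_at(w)
            rows.append([e_hbo * scale, e_hbr * scale])
        return np.array(rows, float)


@dataclass
class ConcentrationSeries:
    """Chromophore concentration-change time courses, mol/L."""

    timestamps: np.ndarray
    delta_hbo: np.ndarray
    delta_hbr: np.ndarray
    params: MBLLParams
    condition_number: float
    sampling_rate: float = 10.0

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, float)
        self.delta_hbo = np.asarray(self.delta_hbo, float)
        self.delta_hbr = np.asarray(self.delta_hbr, float)
        if not (self.timestamps.size == self.delta_hbo.size == self.delta_hbr.size):
            raise ValueError("timestamps/delta_hbo/delta_hbr length mismatch")
        if not (np.isfinite(self.delta_hbo).all() and np.isfinite(self.delta_hbr).all()):
            raise ValueError("non-finite concentration values")


def od_to_concentration(od: ODSeries, params: MBLLParams | None = None) -> ConcentrationSeries:
    """Invert the MBLL per sample.

    Requires >= 2 distinct wavelengths.  With more than two, the
    least-squares solution of the overdetermined system is returned.
    The condition number of the system matrix is computed and enforced
    against ``params.max_condition_number`` (a degenerate pair such as
    880/880 nm is rejected).
    """
    params = params or MBLLParams()
    wl = list(od.wavelengths_nm)
    if len(set(wl)) < 2:
        raise ValueError(f"need >=2 distinct wavelengths, got {wl}")
    E = params.system_matrix(wl)
    cond = float(np.linalg.cond(E))
    if not np.isfinite(cond) or cond > params.max_condition_number:
        raise ValueError(
            f"extinction system matrix ill-conditioned (condition number "
            f"{cond:.3g} > {params.max_condition_number:g}) for wavelengths {wl}"
        )
    # od.od is (n, n_wl); solve E @ c = od_row for every row at once
    conc, *_ = np.linalg.lstsq(E, od.od.T, rcond=None)
    return ConcentrationSeries(
        timestamps=od.timestamps,
        delta_hbo=conc[0],
        delta_hbr=conc[1],
        params=params,
        condition_number=cond,
        sampling_rate=od.sampling_rate,
    )


def forward_mbll(
    delta_hbo: np.ndarray,
    delta_hbr: np.ndarray,
    timestamps: np.ndarray,
    wavelengths_nm,
    params: MBLLParams | None = None,
    sampling_rate: float = 10.0,
) -> ODSeries:
    """Forward MBLL: concentration changes -> dOD per wavelength.

    Exact linear inverse of :func:`od_to_concentration`; used by the
    simulator and by round-trip tests.
    """
    params = params or MBLLParams()
    E = params.system_matrix(wavelengths_nm)
    conc = np.vstack([np.asarray(delta_hbo, float), np.asarray(delta_hbr, float)])
    od = (E @ conc).T
    return ODSeries(
        timestamps=np.asarray(timestamps, float),
        od=od,
        wavelengths_nm=list(wavelengths_nm),
        reference_intensity=np.ones(len(wavelengths_nm)),
        sampling_rate=sampling_rate,
    )
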