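"""Acquisition channels of the bimodal fiber-probe spectrometer.

The instrument acquires six spectroscopic modalities — five narrow-band
autofluorescence excitations (AF1–AF5, 365–415 nm) and broadband diffuse
reflectance (DR) — each collected simultaneously at four source-to-detector
separations (SDS1–SDS4, 400–1000 µm).  Every (modality, SDS) pair is treated
as an independent data stream ("channel"); there are exactly 24 of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class Modality(str, Enum):
    AF1 = "AF1"
    AF2 = "AF2"
    AF3 = "AF3"
    AF4 = "AF4"
    AF5 = "AF5"
    DR = "DR"

    @property
    def is_af(self) -> bool:
        return self is not Modality.DR


#: LED excitation peak wavelengths (nm) for the AF modalities.
EXCITATION_NM = {
    Modality.AF1: 365.0,
    Modality.AF2: 385.0,
    Modality.AF3: 395.0,
    Modality.AF4: 400.0,
    Modality.AF5: 415.0,
}

#: Acquisition spectral range (nm) per modality.  The AF ranges are cropped
#: to reject residual excitation light passing the long-pass emission filters.
ACQUISITION_RANGE_NM = {
    Modality.DR: (340.0, 785.0),
    Modality.AF1: (420.0, 785.0),
    Modality.AF2: (420.0, 785.0),
    Modality.AF3: (420.0, 785.0),
    Modality.AF4: (440.0, 785.0),
    Modality.AF5: (450.0, 785.0),
}

#: Source-to-detector separation in micrometers, by SDS index.
SDS_UM = {1: 400, 2: 600, 3: 800, 4: 1000}

#: Wavelength windows (nm) over which the replicate coefficient of variation
#: is averaged, per modality.  AF lower bounds sit at the emission-filter cut-on;
#: upper bounds exclude the noisy red tail.  The DR window spans almost the
#: whole acquisition range.
CV_WINDOW_NM = {
    Modality.AF1: (421.0, 550.0),
    Modality.AF2: (421.0, 550.0),
    Modality.AF3: (421.0, 550.0),
    Modality.AF4: (451.0, 580.0),
    Modality.AF5: (451.0, 580.0),
    Modality.DR: (340.0, 780.0),
}

#: Search windows (nm) for the maximum used by max-normalization: for AF the
#: noisy region above 600 nm is avoided; for DR the 630–690 nm band is
#: dominated by scattering rather than hemoglobin absorption.
MAX_NORM_WINDOW_NM = {"AF": (420.0, 600.0), "DR": (630.0, 690.0)}


@dataclass(frozen=True, order=True)
class Channel:
    """One (modality, source-detector separation) data stream."""

    modality: Modality
    sds: int

    def __post_init__(self) -> None:
        if self.sds not in SDS_UM:
            raise ValueError(f"sds must be one of {sorted(SDS_UM)}, got {self.sds!r}")
        if not isinstance(self.modality, Modality):
            object.__setattr__(self, "modality", Modality(self.modality))

    @property
    def key(self) -> str:
        return f"{self.modality.value}-{self.sds}"

    @property
    def is_af(self) -> bool:
        return self.modality.is_af

    @property
    def excitation_nm(self) -> float | None:
        return EXCITATION_NM.get(self.modality)

    @property
    def acquisition_range_nm(self) -> tuple[float, float]:
        return ACQUISITION_RANGE_NM[self.modality]

    @property
    def sds_um(self) -> int:
        return SDS_UM[self.sds]

    @property
    def cv_window_nm(self) -> tuple[float, float]:
        return CV_WINDOW_NM[self.modality]

    def grid(self, step_nm: float = 1.0) -> np.ndarray:
        """Wavelength grid covering the acquisition range at ``step_nm``."""
        lo, hi = self.acquisition_range_nm
        n = int(np.floor((hi - lo) / step_nm + 1e-9)) + 1
        return lo + step_nm * np.arange(n)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.key


#: Canonical channel order used in every report and fusion vector:
#: (AF1,SDS1), (AF1,SDS2), ..., (AF5,SDS4), (DR,SDS1), ..., (DR,SDS4).
ALL_CHANNELS: tuple[Channel, ...] = tuple(
    Channel(m, s) for m in Modality for s in (1, 2, 3, 4)
)

_BY_KEY = {c.key: c for c in ALL_CHANNELS}


def channel_from_key(key: str) -> Channel:
    """Parse a channel key like ``"AF2-3"`` or ``"DR-1"``."""
    try:
        return _BY_KEY[key]
    except KeyError:
        raise ValueError(
            f"unknown channel {key!r}; expected one of {sorted(_BY_KEY)}"
        ) from None


def channel_index(channel: Channel) -> int:
    """Position of ``channel`` in the canonical order (0-based)."""
    return ALL_CHANNELS.index(channel)
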