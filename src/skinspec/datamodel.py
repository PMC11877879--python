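"""Core domain types: spectra, measurement trios, skin sites and datasets."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .channels import ALL_CHANNELS, Channel

SITE_KINDS = ("L", "PL", "NL")
HISTOLOGY_CLASSES = ("BCC", "SCC", "AK", "H")
INVASIVENESS = ("CI", "CNI", "NA")

#: Expected number of sites of each kind around one lesion: one lesional spot,
#: two peri-lesional spots on the safety margin, two clinically healthy spots.
SITES_PER_LESION = {"L": 1, "PL": 2, "NL": 2}


class SchemaError(ValueError):
    """A table or config violates the documented schema."""


class DataError(ValueError):
    """Well-formed input with inconsistent content."""


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class LeakageError(RuntimeError):
    """Test-fold information reached a training-only computation."""


@dataclass
class Spectrum:
    """One wavelength-indexed intensity vector of a single acquisition.

    ``dark`` holds the simultaneously recorded dark trace (thermal electrons)
    and is cleared by dark subtraction during preprocessing.
    """

    channel: Channel
    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    dark: np.ndarray | None = None
    repeat_index: int = 1

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.dark is not None:
            self.dark = np.asarray(self.dark, dtype=float)
        n = self.wavelengths_nm.size
        if n < 2 or self.intensities.size != n:
            raise DataError(
                "wavelengths and intensities must have equal length >= 2 "
                f"(got {n} and {self.intensities.size})"
            )
        if self.dark is not None and self.dark.size != n:
            raise DataError("dark trace length differs from spectrum length")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise DataError(
                f"wavelengths must be strictly increasing (channel {self.channel.key}, "
                f"repeat {self.repeat_index})"
            )

    def copy_with(self, **kw) -> "Spectrum":
        out = replace(self, **kw)
        return out

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        w = self.wavelengths_nm
        return (w >= lo) & (w <= hi)

    def __len__(self) -> int:
        return self.wavelengths_nm.size


@dataclass
class MeasurementTrio:
    """The (up to) three repeated spectra of one site x channel before averaging."""

    channel: Channel
    spectra: list[Spectrum] = field(default_factory=list)

    @property
    def n_repeats(self) -> int:
        return len(self.spectra)


@dataclass(frozen=True)
class SkinSite:
    """One measured skin area with its histological ground truth."""

    site_id: str
    patient_id: str
    lesion_id: str
    site_kind: str
    histology: str
    invasiveness: str = "NA"

    def __post_init__(self) -> None:
        if self.site_kind not in SITE_KINDS:
            raise SchemaError(
                f"site_kind must be one of {SITE_KINDS}, got {self.site_kind!r}"
            )
        if self.histology not in HISTOLOGY_CLASSES:
            raise SchemaError(
                f"histology must be one of {HISTOLOGY_CLASSES}, got {self.histology!r}"
            )
        if self.invasiveness not in INVASIVENESS:
            raise SchemaError(
                f"invasiveness must be one of {INVASIVENESS}, got {self.invasiveness!r}"
            )
        if self.invasiveness != "NA" and self.histology not in ("BCC", "SCC"):
            raise SchemaError(
                "invasiveness can be set only for carcinoma classes BCC/SCC "
                f"(histology {self.histology!r})"
            )


@dataclass
class Dataset:
    """Sites plus their per-channel measurement trios and/or averaged spectra."""

    sites: dict[str, SkinSite] = field(default_factory=dict)
    trios: dict[tuple[str, Channel], MeasurementTrio] = field(default_factory=dict)
    averaged: dict[tuple[str, Channel], Spectrum] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (site_id, _ch) in list(self.trios) + list(self.averaged):
            if site_id not in self.sites:
                raise DataError(f"measurement references unknown site {site_id!r}")

    def lesion_ids(self) -> list[str]:
        return sorted({s.lesion_id for s in self.sites.values()})

    def sites_of_lesion(self, lesion_id: str) -> list[SkinSite]:
        return [s for s in self.sites.values() if s.lesion_id == lesion_id]

    def channels(self) -> list[Channel]:
        seen = {ch for (_sid, ch) in self.trios} | {ch for (_sid, ch) in self.averaged}
        return [c for c in ALL_CHANNELS if c in seen]

    def n_spectra(self) -> int:
        return sum(t.n_repeats for t in self.trios.values()) + len(self.averaged)


@dataclass
class ValidationIssue:
    lesion_id: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def is_ok(self) -> bool:
        return not self.issues

    def to_dict(self) -> dict:
        return {
            "ok": self.is_ok,
            "issues": [
                {"lesion_id": i.lesion_id, "message": i.message} for i in self.issues
            ],
        }


def validate_dataset(d: Dataset, channels: Iterable[Channel] = ALL_CHANNELS) -> ValidationReport:
    """Report departures from the full study design.

    The full design has, per lesion, 1 L + 2 PL + 2 NL sites, each measured on
    all 24 channels with 3 repeats.  The report is empty iff the dataset
    matches it exactly (on the requested ``channels``).
    """
    channels = list(channels)
    report = ValidationReport()
    for lesion_id in d.lesion_ids():
        sites = d.sites_of_lesion(lesion_id)
        for kind, expected in SITES_PER_LESION.items():
            n = sum(1 for s in sites if s.site_kind == kind)
            if n != expected:
                report.issues.append(
                    ValidationIssue(lesion_id, f"{kind} count = {n} (expected {expected})")
                )
        for s in sites:
            for ch in channels:
                key = (s.site_id, ch)
                trio = d.trios.get(key)
                if trio is None:
                    if key not in d.averaged:
                        report.issues.append(
                            ValidationIssue(
                                lesion_id, f"site {s.site_id}: missing channel {ch.key}"
                            )
                        )
                elif trio.n_repeats != 3:
                    report.issues.append(
                        ValidationIssue(
                            lesion_id,
                            f"site {s.site_id}, channel {ch.key}: repeats = {trio.n_repeats}",
                        )
                    )
    return report
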