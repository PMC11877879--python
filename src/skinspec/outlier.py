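"""Replicate-dispersion outlier screening.

Each skin site is measured three times per channel without moving the probe.
Before averaging, the three repeats are screened with an averaged coefficient
of variation (CV): at every wavelength in a modality-specific window, the
population SD of the three intensities is divided by their mean, and these
per-wavelength CVs are averaged over the window.  If the trio CV exceeds the
threshold (0.08), the three pairwise CVs are examined; the best pair below
the threshold is kept, otherwise the measurement is discarded for that
(modality, SDS) combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import Channel, CV_WINDOW_NM
from .datamodel import DataError, Dataset, MeasurementTrio, Spectrum

#: CV threshold separating acceptable replicate dispersion from outliers.
DEFAULT_THRESHOLD = 0.08

#: Wavelengths whose replicate mean falls below this floor (detector units)
#: are excluded from the CV average to avoid division by ~0.
MEAN_FLOOR = 1e-9


@dataclass(frozen=True)
class CvWindow:
    """Wavelength bounds (nm) over which the replicate CV is averaged."""

    lo: float
    hi: float

    @classmethod
    def for_channel(cls, channel: Channel) -> "CvWindow":
        lo, hi = CV_WINDOW_NM[channel.modality]
        return cls(lo, hi)


def _avg_cv(stack: np.ndarray, wavelengths: np.ndarray, window: CvWindow) -> float:
    """Mean over window wavelengths of popSD/mean across the replicate axis."""
    mask = (wavelengths >= window.lo) & (wavelengths <= window.hi)
    if not mask.any():
        raise DataError(
            f"CV window [{window.lo}, {window.hi}] nm does not overlap the grid"
        )
    vals = stack[:, mask]
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=0)  # population SD: replicate count under the root
    ok = mean > MEAN_FLOOR
    if not ok.any():
        return 0.0
    return float(np.mean(sd[ok] / mean[ok]))


def _common_stack(spectra: list[Spectrum]) -> tuple[np.ndarray, np.ndarray]:
    w0 = spectra[0].wavelengths_nm
    for s in spectra[1:]:
        if s.wavelengths_nm.size != w0.size or not np.array_equal(s.wavelengths_nm, w0):
            raise DataError("repeats are not on a common wavelength grid")
    return np.stack([s.intensities for s in spectra]), w0


def trio_cv(trio: MeasurementTrio, window: CvWindow | None = None) -> float:
    """Averaged coefficient of variation of a three-repeat series."""
    if trio.n_repeats != 3:
        raise DataError(f"trio_cv requires exactly 3 repeats, got {trio.n_repeats}")
    window = window or CvWindow.for_channel(trio.channel)
    stack, w = _common_stack(trio.spectra)
    return _avg_cv(stack, w, window)


def pair_cv(a: Spectrum, b: Spectrum, window: CvWindow | None = None) -> float:
    """Averaged CV of a pair of repeats (population SD over the 2 values)."""
    window = window or CvWindow.for_channel(a.channel)
    stack, w = _common_stack([a, b])
    return _avg_cv(stack, w, window)


@dataclass
class ScreenResult:
    kept_repeats: tuple[int, ...]
    averaged: Spectrum | None
    trio_cv: float
    pair_cvs: dict[tuple[int, int], float] | None
    status: str  # kept_all | kept_pair | removed


def _mean_spectrum(spectra: list[Spectrum]) -> Spectrum:
    stack, w = _common_stack(spectra)
    return Spectrum(
        channel=spectra[0].channel,
        wavelengths_nm=w,
        intensities=stack.mean(axis=0),
        repeat_index=0,
    )


def screen_trio(
    trio: MeasurementTrio,
    threshold: float = DEFAULT_THRESHOLD,
    window: CvWindow | None = None,
) -> ScreenResult:
    """Two-stage screen of one replicate trio.

    Stage 1: trio CV <= threshold keeps all three repeats.  Stage 2: of the
    three pairwise CVs, the smallest one at or below the threshold selects the
    pair to keep (ties broken by lowest repeat indices); if all exceed the
    threshold the measurement is removed.
    """
    window = window or CvWindow.for_channel(trio.channel)
    cv3 = trio_cv(trio, window)
    if cv3 <= threshold:
        return ScreenResult(
            kept_repeats=tuple(s.repeat_index for s in trio.spectra),
            averaged=_mean_spectrum(trio.spectra),
            trio_cv=cv3,
            pair_cvs=None,
            status="kept_all",
        )
    pairs = [(0, 1), (0, 2), (1, 2)]
    cvs = {
        (trio.spectra[i].repeat_index, trio.spectra[j].repeat_index): pair_cv(
            trio.spectra[i], trio.spectra[j], window
        )
        for i, j in pairs
    }
    best_key = min(cvs, key=lambda k: (cvs[k], k))
    if cvs[best_key] <= threshold:
        keep = [s for s in trio.spectra if s.repeat_index in best_key]
        return ScreenResult(
            kept_repeats=best_key,
            averaged=_mean_spectrum(keep),
            trio_cv=cv3,
            pair_cvs=cvs,
            status="kept_pair",
        )
    return ScreenResult(
        kept_repeats=(), averaged=None, trio_cv=cv3, pair_cvs=cvs, status="removed"
    )


@dataclass
class QcReport:
    """Per-channel / per-class accounting of the outlier screen."""

    threshold: float
    statuses: dict = field(default_factory=dict)  # (site_id, channel_key) -> status
    per_channel: dict = field(default_factory=dict)
    per_channel_class: dict = field(default_factory=dict)

    @property
    def retained_fraction(self) -> float:
        n = len(self.statuses)
        if n == 0:
            return 1.0
        kept = sum(1 for s in self.statuses.values() if s != "removed")
        return kept / n

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "retained_fraction": self.retained_fraction,
            "per_channel": self.per_channel,
            "per_channel_class": {
                f"{ch}|{cls}": v for (ch, cls), v in self.per_channel_class.items()
            },
        }


def screen_dataset(
    d: Dataset,
    threshold: float = DEFAULT_THRESHOLD,
    windows: dict[str, CvWindow] | None = None,
) -> tuple[Dataset, QcReport]:
    """Screen every trio and average the retained repeats.

    Returns a dataset whose ``averaged`` map holds one spectrum per surviving
    (site, channel), plus a QC report with kept_all/kept_pair/removed counts
    per channel and per histology class.
    """
    out = Dataset(sites=dict(d.sites), provenance=dict(d.provenance))
    report = QcReport(threshold=threshold)
    for (site_id, ch), trio in d.trios.items():
        window = (windows or {}).get(ch.key) or CvWindow.for_channel(ch)
        res = screen_trio(trio, threshold, window)
        report.statuses[(site_id, ch.key)] = res.status
        hist = d.sites[site_id].histology
        chan_stats = report.per_channel.setdefault(
            ch.key, {"kept_all": 0, "kept_pair": 0, "removed": 0}
        )
        chan_stats[res.status] += 1
        cls_stats = report.per_channel_class.setdefault(
            (ch.key, hist), {"kept_all": 0, "kept_pair": 0, "removed": 0}
        )
        cls_stats[res.status] += 1
        if res.averaged is not None:
            out.averaged[(site_id, ch)] = res.averaged
    for stats in list(report.per_channel.values()) + list(
        report.per_channel_class.values()
    ):
        total = sum(stats.values())
        stats["retained_fraction"] = (
            (stats["kept_all"] + stats["kept_pair"]) / total if total else 1.0
        )
    out.provenance.setdefault("log", []).append(
        {
            "stage": "outlier_screen",
            "trios_in": len(d.trios),
            "trios_kept": len(out.averaged),
            "retained_fraction": report.retained_fraction,
        }
    )
    return out, report


def screen_score(report: QcReport, injected: list) -> dict:
    """Recall/precision of the screen against the generator's truth record.

    A trio counts as detected when the screen did anything other than keep all
    three repeats (pair rescue or removal).
    """
    injected_keys = {(row[0], row[1]) for row in injected}
    flagged = {k for k, s in report.statuses.items() if s != "kept_all"}
    clean = set(report.statuses) - injected_keys
    tp = len(flagged & injected_keys)
    recall = tp / len(injected_keys) if injected_keys else 1.0
    clean_retained = (
        sum(1 for k in clean if report.statuses[k] != "removed") / len(clean)
        if clean
        else 1.0
    )
    precision = tp / len(flagged) if flagged else 1.0
    return {
        "n_injected": len(injected_keys),
        "recall": recall,
        "precision": precision,
        "clean_retained": clean_retained,
    }
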