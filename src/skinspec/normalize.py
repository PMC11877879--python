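"""Spectrum normalization against healthy-skin references.

Three schemes (plus "none"):

* ``max`` — divide each spectrum by its maximum inside a modality-specific
  search window (AF: 420-600 nm, avoiding the noisy red tail; DR: 630-690 nm,
  where scattering dominates hemoglobin absorption).
* ``ratio`` — multiply by the constant scalar (global healthy mean intensity)
  / (peak of the lesion's local healthy mean spectrum); pure rescaling, shape
  preserved.
* ``baseline`` — multiply pointwise by (global healthy mean spectrum) /
  (lesion's local healthy mean spectrum); corrects shape as well as scale.

The local reference of a lesion is the mean spectrum of its healthy-labelled
sites (typically the 2 NL + 2 PL spots); global healthy statistics are
computed from training-fold sites only, so test folds never leak into them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .channels import Channel, MAX_NORM_WINDOW_NM
from .datamodel import ConfigError, DataError, Dataset, Spectrum

NORMALIZATION_MODES = ("none", "max", "ratio", "baseline")

#: Floor applied to reference spectra before division.
REF_FLOOR = 1e-9


def _max_window(channel: Channel) -> tuple[float, float]:
    return MAX_NORM_WINDOW_NM["AF" if channel.is_af else "DR"]


def normalize_max(s: Spectrum) -> Spectrum:
    """Divide by the spectrum's own maximum inside the modality search window."""
    lo, hi = _max_window(s.channel)
    mask = s.window_mask(lo, hi)
    if not mask.any():
        raise DataError(
            f"max-normalization window [{lo}, {hi}] nm does not overlap the grid"
        )
    peak = float(s.intensities[mask].max())
    if peak <= 0:
        raise DataError("window maximum is not positive; cannot max-normalize")
    return s.copy_with(intensities=s.intensities / peak)


@dataclass
class NormalizationContext:
    """Healthy-skin references for ratio and baseline normalization.

    Per channel key: the global healthy mean spectrum, its scalar
    wavelength-average, and the per-lesion local healthy mean spectra,
    all on the channel's common post-resampling grid.
    """

    grids: dict[str, np.ndarray] = field(default_factory=dict)
    global_mean: dict[str, np.ndarray] = field(default_factory=dict)
    global_scalar: dict[str, float] = field(default_factory=dict)
    lesion_mean: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    training_sites: frozenset = frozenset()
    lesions_without_reference: list[str] = field(default_factory=list)

    def _lesion_ref(self, lesion_id: str, channel: Channel) -> np.ndarray:
        key = (lesion_id, channel.key)
        if key not in self.lesion_mean:
            raise DataError(
                f"no healthy reference for lesion {lesion_id!r} on channel {channel.key}"
            )
        return self.lesion_mean[key]


def build_context(
    d: Dataset,
    training_site_ids: Iterable[str],
    channels: Iterable[Channel] | None = None,
) -> NormalizationContext:
    """Compute healthy references from a dataset of averaged spectra.

    The per-lesion reference is the mean of that lesion's H-labelled site
    spectra (a fixed local reference); the global mean spectrum and its
    scalar wavelength-average use only training-flagged healthy sites.
    """
    training = frozenset(training_site_ids)
    channels = list(channels) if channels is not None else d.channels()
    ctx = NormalizationContext(training_sites=training)

    for ch in channels:
        per_lesion: dict[str, list[np.ndarray]] = {}
        train_specs: list[np.ndarray] = []
        grid = None
        for (site_id, c), spec in d.averaged.items():
            if c != ch:
                continue
            if grid is None:
                grid = spec.wavelengths_nm
            site = d.sites[site_id]
            if site.histology != "H":
                continue
            per_lesion.setdefault(site.lesion_id, []).append(spec.intensities)
            if site_id in training:
                train_specs.append(spec.intensities)
        if grid is None:
            continue
        ctx.grids[ch.key] = grid
        if train_specs:
            gmean = np.mean(train_specs, axis=0)
            ctx.global_mean[ch.key] = gmean
            ctx.global_scalar[ch.key] = float(gmean.mean())
        for lesion_id, specs in per_lesion.items():
            ctx.lesion_mean[(lesion_id, ch.key)] = np.mean(specs, axis=0)

    for lesion_id in d.lesion_ids():
        if not any(k[0] == lesion_id for k in ctx.lesion_mean):
            ctx.lesions_without_reference.append(lesion_id)
    return ctx


def normalize_ratio(s: Spectrum, ctx: NormalizationContext, lesion_id: str) -> Spectrum:
    """Rescale by (global healthy scalar mean) / (peak of the lesion reference).

    For DR channels the reference peak is searched in the 630-690 nm window;
    for AF the full-grid maximum is used.  The factor is a constant scalar, so
    the spectral shape is preserved exactly.
    """
    ref = ctx._lesion_ref(lesion_id, s.channel)
    if s.channel.is_af:
        peak = float(ref.max())
    else:
        lo, hi = _max_window(s.channel)
        grid = ctx.grids[s.channel.key]
        mask = (grid >= lo) & (grid <= hi)
        peak = float(ref[mask].max()) if mask.any() else float(ref.max())
    if peak <= 0:
        raise DataError(
            f"healthy reference peak for lesion {lesion_id!r} is not positive"
        )
    if s.channel.key not in ctx.global_scalar:
        raise DataError(f"no global healthy mean for channel {s.channel.key}")
    factor = ctx.global_scalar[s.channel.key] / peak
    return s.copy_with(intensities=s.intensities * factor)


def normalize_baseline(s: Spectrum, ctx: NormalizationContext, lesion_id: str) -> Spectrum:
    """Pointwise reshaping: input x (global healthy mean) / (lesion reference)."""
    ref = ctx._lesion_ref(lesion_id, s.channel)
    if s.channel.key not in ctx.global_mean:
        raise DataError(f"no global healthy mean for channel {s.channel.key}")
    gmean = ctx.global_mean[s.channel.key]
    if ref.size != len(s) or gmean.size != len(s):
        raise DataError("reference spectra are not on the spectrum's grid")
    if np.any(ref < REF_FLOOR):
        warnings.warn(
            f"lesion {lesion_id!r} reference has near-zero values on channel "
            f"{s.channel.key}; flooring at {REF_FLOOR}",
            stacklevel=2,
        )
        ref = np.maximum(ref, REF_FLOOR)
    return s.copy_with(intensities=s.intensities * gmean / ref)


def normalize_spectrum(
    s: Spectrum, mode: str, ctx: NormalizationContext | None = None,
    lesion_id: str | None = None,
) -> Spectrum:
    """Dispatch to one of the normalization modes; ``none`` is the identity."""
    if mode not in NORMALIZATION_MODES:
        raise ConfigError(
            f"unknown normalization mode {mode!r}; choose from {NORMALIZATION_MODES}"
        )
    if mode == "none":
        return s
    if mode == "max":
        return normalize_max(s)
    if ctx is None or lesion_id is None:
        raise ConfigError(f"mode {mode!r} requires a context and a lesion id")
    if mode == "ratio":
        return normalize_ratio(s, ctx, lesion_id)
    return normalize_baseline(s, ctx, lesion_id)
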