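"""Raw spectrum conditioning.

Fixed stage order: median filtering (impulse suppression) -> dark subtraction
-> Savitzky-Golay smoothing -> resampling onto the integer-nm grid ->
spectral-response correction (AF channels only).  The order is chosen so that
impulse noise cannot leak into the smoother and smoothing precedes decimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter as _nd_median
from scipy.signal import savgol_filter

from .channels import Channel
from .datamodel import ConfigError, DataError, Dataset, MeasurementTrio, Spectrum


@dataclass
class PreprocessConfig:
    """Parameters of the conditioning stages.

    ``savgol_window`` is expressed in samples of the raw acquisition grid; the
    default 81 corresponds to ~24 nm on the instrument's native 0.3-nm grid.
    When ``scale_window_to_grid`` is set, the window is rescaled to preserve
    that physical width on inputs with a different wavelength step.
    """

    median_kernel: int = 3
    savgol_window: int = 81
    savgol_order: int = 4
    raw_step_nm: float = 0.3  # grid step the savgol_window default refers to
    scale_window_to_grid: bool = True
    target_step_nm: float = 1.0
    response_curves: dict = field(default_factory=dict)  # channel key -> (wavelengths, gains)

    def __post_init__(self) -> None:
        if self.median_kernel % 2 == 0:
            raise ConfigError("median_kernel must be odd")
        if self.savgol_window % 2 == 0 or self.savgol_window <= self.savgol_order:
            raise ConfigError("savgol_window must be odd and > savgol_order")

    def window_for_step(self, step_nm: float) -> int:
        """Savitzky-Golay window (odd sample count) for a given grid step."""
        if not self.scale_window_to_grid:
            return self.savgol_window
        width_nm = self.savgol_window * self.raw_step_nm
        n = max(int(round(width_nm / step_nm)), self.savgol_order + 1)
        if n % 2 == 0:
            n += 1
        return n


def median_filter(s: Spectrum, kernel: int = 3) -> Spectrum:
    """Sliding-median impulse suppression with edge-value padding."""
    if kernel % 2 == 0:
        raise ConfigError(f"median kernel must be odd, got {kernel}")
    if kernel > len(s):
        raise ConfigError("median kernel exceeds spectrum length")
    out = _nd_median(s.intensities, size=kernel, mode="nearest")
    return s.copy_with(intensities=out)


def subtract_dark(s: Spectrum) -> Spectrum:
    """Subtract the dark trace, clip at zero, and clear the dark field."""
    if s.dark is None:
        raise DataError("spectrum has no dark trace to subtract")
    out = np.clip(s.intensities - s.dark, 0.0, None)
    return s.copy_with(intensities=out, dark=None)


def savgol_smooth(s: Spectrum, window: int = 81, order: int = 4) -> Spectrum:
    """Savitzky-Golay least-squares polynomial smoothing (length-preserving).

    Requires a uniform wavelength grid; edges are handled by refitting the
    polynomial on the truncated terminal windows.
    """
    if window % 2 == 0 or order >= window:
        raise ConfigError("window must be odd and > order")
    steps = np.diff(s.wavelengths_nm)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise DataError(
            "savgol_smooth requires a uniform wavelength grid; resample first "
            "or apply on the raw grid"
        )
    window = min(window, len(s) if len(s) % 2 == 1 else len(s) - 1)
    if window <= order:
        return s.copy_with(intensities=s.intensities.copy())
    out = savgol_filter(s.intensities, window_length=window, polyorder=order, mode="interp")
    return s.copy_with(intensities=np.clip(out, 0.0, None))


def resample(s: Spectrum, step_nm: float = 1.0) -> Spectrum:
    """Linear interpolation onto the integer-step grid within the channel range.

    The target grid is the ``step_nm`` multiples covering the intersection of
    the source wavelength range and the channel's acquisition range; no
    extrapolation is performed.
    """
    if step_nm <= 0:
        raise ConfigError("step_nm must be > 0")
    lo = max(s.wavelengths_nm[0], s.channel.acquisition_range_nm[0])
    hi = min(s.wavelengths_nm[-1], s.channel.acquisition_range_nm[1])
    start = np.ceil(lo / step_nm - 1e-9) * step_nm
    stop = np.floor(hi / step_nm + 1e-9) * step_nm
    if stop < start:
        raise DataError("resampling target grid is empty")
    grid = start + step_nm * np.arange(int(round((stop - start) / step_nm)) + 1)
    out = np.interp(grid, s.wavelengths_nm, s.intensities)
    dark = None if s.dark is None else np.interp(grid, s.wavelengths_nm, s.dark)
    return s.copy_with(wavelengths_nm=grid, intensities=out, dark=dark)


def correct_response(s: Spectrum, response: np.ndarray) -> Spectrum:
    """Divide by the detection-channel spectral response (gain per wavelength)."""
    response = np.asarray(response, dtype=float)
    if response.size != len(s):
        raise DataError("response curve not defined on the spectrum's grid")
    if np.any(response <= 0):
        raise DataError("response curve must be strictly positive")
    return s.copy_with(intensities=s.intensities / response)


def preprocess_spectrum(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Apply the full conditioning chain to one raw spectrum."""
    cfg = cfg or PreprocessConfig()
    step = float(np.median(np.diff(s.wavelengths_nm)))
    out = median_filter(s, cfg.median_kernel)
    if out.dark is not None:
        out = subtract_dark(out)
    out = savgol_smooth(out, cfg.window_for_step(step), cfg.savgol_order)
    out = resample(out, cfg.target_step_nm)
    if s.channel.is_af and s.channel.key in cfg.response_curves:
        rw, rg = cfg.response_curves[s.channel.key]
        out = correct_response(out, np.interp(out.wavelengths_nm, rw, rg))
    return out


def preprocess_dataset(d: Dataset, cfg: PreprocessConfig | None = None) -> Dataset:
    """Condition every repeat of every trio; sites and provenance are carried over."""
    cfg = cfg or PreprocessConfig()
    out = Dataset(sites=dict(d.sites), provenance=dict(d.provenance))
    for key, trio in d.trios.items():
        out.trios[key] = MeasurementTrio(
            channel=trio.channel,
            spectra=[preprocess_spectrum(s, cfg) for s in trio.spectra],
        )
    out.provenance.setdefault("log", []).append(
        {
            "stage": "preprocess",
            "spectra_in": d.n_spectra(),
            "spectra_out": out.n_spectra(),
        }
    )
    return out
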