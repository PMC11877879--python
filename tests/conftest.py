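import numpy as np
import pytest

from skinspec import Channel, Modality, Spectrum, SynthConfig, generate_dataset
from skinspec.datamodel import MeasurementTrio


def make_spectrum(values, channel=None, wavelengths=None, dark=None, repeat=1):
    """Spectrum helper: values on a default grid inside the channel's range."""
    channel = channel or Channel(Modality.AF2, 1)
    values = np.asarray(values, dtype=float)
    if wavelengths is None:
        wavelengths = 500.0 + np.arange(values.size)
    return Spectrum(
        channel=channel,
        wavelengths_nm=np.asarray(wavelengths, dtype=float),
        intensities=values,
        dark=None if dark is None else np.asarray(dark, dtype=float),
        repeat_index=repeat,
    )


def make_trio(rows, channel=None, wavelengths=None):
    channel = channel or Channel(Modality.AF2, 1)
    return MeasurementTrio(
        channel=channel,
        spectra=[
            make_spectrum(r, channel=channel, wavelengths=wavelengths, repeat=i + 1)
            for i, r in enumerate(rows)
        ],
    )


@pytest.fixture(scope="session")
def small_dataset():
    """6 lesions / 4 patients, full 24-channel design, default noise."""
    return generate_dataset(SynthConfig(n_patients=4, n_lesions_total=6, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
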