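"""Synthetic bimodal skin-spectroscopy datasets.

Emulates the clinical dataset's structure — patients carrying lesions, five
measurement sites per lesion (1 lesional, 2 peri-lesional, 2 non-lesional),
24 channels per site (5 AF excitations + DR, each at 4 source-detector
separations) and 3 repeats per site/channel — with class-dependent spectral
shapes, per-patient gain variability, dark counts, impulse noise and injected
replicate outliers.  Spectral realism is intentionally schematic (Gaussian
emission bands, Beer-Lambert-style hemoglobin dips): the downstream pipeline
is shape-agnostic, so only the topology and noise structure need to be
faithful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .channels import ALL_CHANNELS, Channel, Modality
from .datamodel import ConfigError, Dataset, MeasurementTrio, SkinSite, Spectrum

#: Class mix over lesional areas, from the study's histology counts
#: BCC=90, SCC=57, AK=96 (of 243 lesional areas).
DEFAULT_CLASS_MIX = {"BCC": 90 / 243, "SCC": 57 / 243, "AK": 96 / 243}

#: Fraction of carcinomas that are invasive, per class (derived from the
#: reported composition of the invasive/non-invasive regroupings).
DEFAULT_INVASIVE_FRACTION = {"BCC": 0.52, "SCC": 0.78}


@dataclass
class SynthConfig:
    """Study-design and noise parameters of the generator.

    Defaults reproduce the clinical study's design: 131 patients carrying 218
    lesions in total (distributed round-robin, so some patients carry two).
    ``effect_size`` scales the class-dependent spectral contrast; 0 makes all
    classes spectrally indistinguishable.
    """

    n_patients: int = 131
    lesions_per_patient: int = 1
    n_lesions_total: int | None = 218
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    invasive_fraction: dict = field(default_factory=lambda: dict(DEFAULT_INVASIVE_FRACTION))
    effect_size: float = 1.0
    patient_gain_sd: float = 0.3  # log-scale SD of the per-patient gain
    site_bio_sd: float = 0.15  # relative SD of per-site band amplitudes / dip depths
    noise_sd: float = 0.02  # relative multiplicative noise per wavelength
    dark_level: float = 50.0  # mean dark counts
    impulse_rate: float = 0.001  # per-sample spike probability
    outlier_rate: float = 0.05  # per-trio probability of an injected outlier
    pl_contamination: float = 0.0  # probability a PL site carries the lesion class
    grid_step_nm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("class_mix must sum to 1")
        unknown = set(self.class_mix) - {"BCC", "SCC", "AK"}
        if unknown:
            raise ConfigError(f"class_mix has unknown classes {sorted(unknown)}")
        for name, rate in [
            ("noise_sd", self.noise_sd),
            ("impulse_rate", self.impulse_rate),
            ("outlier_rate", self.outlier_rate),
            ("pl_contamination", self.pl_contamination),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {rate}")
        if self.patient_gain_sd < 0 or self.dark_level < 0 or self.site_bio_sd < 0:
            raise ConfigError(
                "patient_gain_sd, dark_level and site_bio_sd must be >= 0"
            )

    @property
    def n_lesions(self) -> int:
        if self.n_lesions_total is not None:
            return self.n_lesions_total
        return self.n_patients * self.lesions_per_patient


# --- noiseless class templates ------------------------------------------------

#: AF emission bands: centers (nm), widths (nm) and base relative amplitudes.
#: Near 440 nm (collagen/elastin + NADH) and 500/520 nm (flavins).
_AF_CENTERS = np.array([440.0, 500.0, 520.0])
_AF_WIDTHS = np.array([26.0, 36.0, 30.0])
_AF_BASE_AMP = np.array([1.0, 0.65, 0.45])

#: Per-class amplitude shifts of the three AF bands at effect_size = 1:
#: carcinomas lose the structural-protein band and gain flavin emission.
_AF_CLASS_DELTA = {
    "H": np.array([0.0, 0.0, 0.0]),
    "AK": np.array([-0.08, 0.06, -0.05]),
    "BCC": np.array([-0.15, 0.12, 0.05]),
    "SCC": np.array([-0.25, 0.05, 0.15]),
}

#: Small excitation-dependent reweighting of the bands so channels differ.
_AF_MODALITY_WEIGHT = {
    Modality.AF1: np.array([1.10, 0.95, 0.90]),
    Modality.AF2: np.array([1.05, 1.00, 0.95]),
    Modality.AF3: np.array([1.00, 1.00, 1.00]),
    Modality.AF4: np.array([0.95, 1.05, 1.00]),
    Modality.AF5: np.array([0.90, 1.05, 1.10]),
}

#: Hemoglobin absorption dips in DR: centers/widths (nm) and base depths.
_DR_DIP_CENTERS = np.array([542.0, 577.0])
_DR_DIP_WIDTHS = np.array([12.0, 10.0])
_DR_BASE_DEPTH = np.array([0.35, 0.30])

#: Per-class dip-depth shifts at effect_size = 1 (tumor vascularisation).
_DR_CLASS_DELTA = {
    "H": np.array([0.0, 0.0]),
    "AK": np.array([0.08, 0.06]),
    "BCC": np.array([0.15, 0.12]),
    "SCC": np.array([0.25, 0.20]),
}

#: Geometric intensity attenuation per SDS step (identical for all classes so
#: the spatially-resolved structure carries no class signal by itself).
_SDS_FACTOR = 0.65

#: Overall detector-unit scales.
_AF_SCALE = 1000.0
_DR_SCALE = 3000.0


def _af_band_matrix(w: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * ((w[:, None] - _AF_CENTERS[None, :]) / _AF_WIDTHS[None, :]) ** 2)


def _dr_dip_matrix(w: np.ndarray) -> np.ndarray:
    return np.exp(
        -0.5 * ((w[:, None] - _DR_DIP_CENTERS[None, :]) / _DR_DIP_WIDTHS[None, :]) ** 2
    )


def _af_class_amps(histology: str, channel: Channel, effect_size: float) -> np.ndarray:
    amps = _AF_BASE_AMP * _AF_MODALITY_WEIGHT[channel.modality]
    return np.clip(amps + effect_size * _AF_CLASS_DELTA[histology], 0.0, None)


def _dr_class_depths(histology: str, effect_size: float) -> np.ndarray:
    return np.clip(_DR_BASE_DEPTH + effect_size * _DR_CLASS_DELTA[histology], 0.0, None)


def class_template(histology: str, channel: Channel, effect_size: float,
                   grid: np.ndarray | None = None) -> Spectrum:
    """Deterministic noiseless population template for one class and channel.

    AF channels are sums of Gaussian emission bands whose relative amplitudes
    shift with class; DR channels are a smooth decreasing scattering baseline
    multiplied by exp(-absorption) with hemoglobin-like dips near 542/577 nm
    whose depth shifts with class.  ``effect_size = 0`` yields identical
    templates for all classes.
    """
    if histology not in _AF_CLASS_DELTA:
        raise ConfigError(f"unknown histology class {histology!r}")
    if effect_size < 0:
        raise ConfigError("effect_size must be >= 0")
    w = channel.grid(1.0) if grid is None else np.asarray(grid, dtype=float)
    sds_gain = _SDS_FACTOR ** (channel.sds - 1)
    if channel.is_af:
        intens = _AF_SCALE * sds_gain * (
            _af_band_matrix(w) @ _af_class_amps(histology, channel, effect_size)
        )
    else:
        baseline = (w / 785.0) ** (-1.2)
        absorption = _dr_dip_matrix(w) @ _dr_class_depths(histology, effect_size)
        intens = _DR_SCALE * sds_gain * baseline * np.exp(-absorption)
    return Spectrum(channel=channel, wavelengths_nm=w, intensities=intens)


# --- dataset generation -------------------------------------------------------

def _lesion_assignment(cfg: SynthConfig) -> list[tuple[str, str]]:
    """(patient_id, lesion_id) pairs, lesions distributed round-robin."""
    pairs = []
    n_lesions = cfg.n_lesions
    for i in range(n_lesions):
        p = i % cfg.n_patients if cfg.n_lesions_total is not None else i // cfg.lesions_per_patient
        pairs.append((f"P{p + 1:03d}", f"L{i + 1:03d}"))
    return pairs


def _class_quota(class_mix: dict, n: int) -> dict[str, int]:
    """Per-class lesion counts by largest remainder, faithful to the mix.

    A cohort has fixed histology counts, so classes are assigned by quota
    rather than iid draws — every class with nonzero share is represented
    once n is large enough.
    """
    classes = sorted(class_mix)
    exact = {c: class_mix[c] * n for c in classes}
    counts = {c: int(np.floor(exact[c])) for c in classes}
    short = n - sum(counts.values())
    for c in sorted(classes, key=lambda c: exact[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def generate_dataset(cfg: SynthConfig, channels: tuple[Channel, ...] = ALL_CHANNELS) -> Dataset:
    """Generate a full synthetic dataset.

    Each repeat is ``patient_gain x template x (1 + noise) + dark + impulses``
    with the dark trace stored separately.  With probability ``outlier_rate``
    one repeat of a trio is corrupted, either by a gain factor drawn outside
    [0.5, 2] or by replacement with a flat low signal emulating probe
    lift-off; the affected (site, channel) keys are recorded in
    ``provenance["injected_outliers"]`` so the outlier screen can be scored.
    """
    # independent streams so the cohort design (classes, gains, outlier
    # placement) is invariant to which channels are generated
    ss = np.random.SeedSequence(cfg.seed)
    rng_design, rng_noise, rng_outlier = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    ds = Dataset()
    quota = _class_quota(cfg.class_mix, cfg.n_lesions)
    class_sequence = rng_design.permutation(
        [c for c, n in sorted(quota.items()) for _ in range(n)]
    )
    injected: list[list] = []

    grids = {ch: ch.grid(cfg.grid_step_nm) for ch in channels}
    shapes = {}
    for ch in channels:
        w = grids[ch]
        if ch.is_af:
            shapes[ch] = (_AF_SCALE * _SDS_FACTOR ** (ch.sds - 1)) * _af_band_matrix(w)
        else:
            baseline = (w / 785.0) ** (-1.2)
            shapes[ch] = (
                _DR_SCALE * _SDS_FACTOR ** (ch.sds - 1) * baseline,
                _dr_dip_matrix(w),
            )

    def site_spectrum(hist: str, ch: Channel, z_af: np.ndarray, z_dr: np.ndarray) -> np.ndarray:
        """Noiseless per-site spectrum: the class template with biological
        jitter of the band amplitudes / dip depths (shared by all repeats)."""
        if ch.is_af:
            amps = _af_class_amps(hist, ch, cfg.effect_size) * np.clip(
                1.0 + cfg.site_bio_sd * z_af, 0.0, None
            )
            return shapes[ch] @ amps
        depths = _dr_class_depths(hist, cfg.effect_size) * np.clip(
            1.0 + cfg.site_bio_sd * z_dr, 0.0, None
        )
        base, dips = shapes[ch]
        return base * np.exp(-(dips @ depths))

    patient_gain = {
        f"P{p + 1:03d}": float(np.exp(rng_design.normal(0.0, cfg.patient_gain_sd)))
        for p in range(cfg.n_patients)
    }

    for (patient_id, lesion_id), lesion_class in zip(
        _lesion_assignment(cfg), map(str, class_sequence)
    ):
        if lesion_class in cfg.invasive_fraction:
            invasive = (
                "CI"
                if rng_design.random() < cfg.invasive_fraction[lesion_class]
                else "CNI"
            )
        else:
            invasive = "NA"

        site_specs = [("L", lesion_class, invasive)]
        for j in (1, 2):
            if cfg.pl_contamination > 0 and rng_design.random() < cfg.pl_contamination:
                site_specs.append((f"PL{j}", lesion_class, invasive))
            else:
                site_specs.append((f"PL{j}", "H", "NA"))
        site_specs += [("NL1", "H", "NA"), ("NL2", "H", "NA")]

        gain = patient_gain[patient_id]
        for tag, hist, inv in site_specs:
            kind = "L" if tag == "L" else ("PL" if tag.startswith("PL") else "NL")
            site_id = f"{lesion_id}-{tag}"
            ds.sites[site_id] = SkinSite(
                site_id=site_id,
                patient_id=patient_id,
                lesion_id=lesion_id,
                site_kind=kind,
                histology=hist,
                invasiveness=inv,
            )
            z_af = rng_design.standard_normal(_AF_CENTERS.size)
            z_dr = rng_design.standard_normal(_DR_DIP_CENTERS.size)
            for ch in channels:
                w = grids[ch]
                base = gain * site_spectrum(hist, ch, z_af, z_dr)
                trio = MeasurementTrio(channel=ch)
                for rep in (1, 2, 3):
                    signal = base * (
                        1.0 + cfg.noise_sd * rng_noise.standard_normal(w.size)
                    )
                    if cfg.impulse_rate > 0:
                        spikes = rng_noise.random(w.size) < cfg.impulse_rate
                        if spikes.any():
                            signal = signal + spikes * rng_noise.uniform(
                                2.0, 5.0, w.size
                            ) * base.max()
                    dark = np.clip(
                        cfg.dark_level
                        + 0.05 * cfg.dark_level * rng_noise.standard_normal(w.size),
                        0.0,
                        None,
                    )
                    trio.spectra.append(
                        Spectrum(
                            channel=ch,
                            wavelengths_nm=w,
                            intensities=np.clip(signal, 0.0, None) + dark,
                            dark=dark,
                            repeat_index=rep,
                        )
                    )
                if cfg.outlier_rate > 0 and rng_outlier.random() < cfg.outlier_rate:
                    k = int(rng_outlier.integers(0, 3))
                    spec = trio.spectra[k]
                    signal_part = np.clip(spec.intensities - spec.dark, 0.0, None)
                    if rng_outlier.random() < 0.5:
                        # gain outlier: factor outside [0.5, 2]
                        factor = (
                            float(rng_outlier.uniform(2.0, 4.0))
                            if rng_outlier.random() < 0.5
                            else float(rng_outlier.uniform(0.15, 0.45))
                        )
                        corrupted = factor * signal_part
                        mode = f"gain:{factor:.3f}"
                    else:
                        # probe lift-off: flat low signal
                        corrupted = np.full(
                            w.size, 0.02 * base.max()
                        ) * (1.0 + cfg.noise_sd * rng_outlier.standard_normal(w.size))
                        mode = "liftoff"
                    trio.spectra[k] = spec.copy_with(
                        intensities=np.clip(corrupted, 0.0, None) + spec.dark
                    )
                    injected.append([site_id, ch.key, k + 1, mode])
                ds.trios[(site_id, ch)] = trio

    ds.provenance = {
        "generator": "skinspec.synthetic.generate_dataset",
        "config": asdict(cfg),
        "seed": cfg.seed,
        "injected_outliers": injected,
        "class_counts": {
            c: sum(1 for s in ds.sites.values() if s.histology == c)
            for c in ("BCC", "SCC", "AK", "H")
        },
    }
    return ds
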