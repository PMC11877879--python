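"""Long-format CSV reader/writer for spectra tables.

One row per wavelength sample; UTF-8, "." decimal separator, header required.
Required columns: patient_id, lesion_id, site_kind, histology, invasiveness,
modality, sds, repeat, wavelength_nm, intensity, dark.  An additional
``site_id`` column disambiguates the two PL (and two NL) sites of a lesion;
the writer always emits it, and the reader falls back to grouping by
(lesion_id, site_kind) when it is absent.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import Channel, Modality, channel_index
from .datamodel import (
    DataError,
    Dataset,
    HISTOLOGY_CLASSES,
    INVASIVENESS,
    MeasurementTrio,
    SchemaError,
    SkinSite,
    Spectrum,
    SITE_KINDS,
)

REQUIRED_COLUMNS = [
    "patient_id",
    "lesion_id",
    "site_kind",
    "histology",
    "invasiveness",
    "modality",
    "sds",
    "repeat",
    "wavelength_nm",
    "intensity",
    "dark",
]

_COLUMN_ORDER = ["site_id"] + REQUIRED_COLUMNS


def _check_enum(df: pd.DataFrame, column: str, allowed: tuple) -> None:
    bad = set(df[column].unique()) - set(allowed)
    if bad:
        raise SchemaError(
            f"column {column!r} contains {sorted(map(str, bad))}; "
            f"allowed values are {list(allowed)}"
        )


def read_spectra_table(path: str | Path) -> Dataset:
    """Read a long-format spectra CSV into a :class:`Dataset` of trios."""
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "lesion_id": str, "invasiveness": str},
        float_precision="round_trip",
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    _check_enum(df, "modality", tuple(m.value for m in Modality))
    _check_enum(df, "site_kind", SITE_KINDS)
    _check_enum(df, "histology", HISTOLOGY_CLASSES)
    df["invasiveness"] = df["invasiveness"].fillna("NA")
    _check_enum(df, "invasiveness", INVASIVENESS)
    bad_sds = set(df["sds"].unique()) - {1, 2, 3, 4}
    if bad_sds:
        raise SchemaError(f"column 'sds' contains {sorted(bad_sds)}; allowed values are [1, 2, 3, 4]")

    if "site_id" not in df.columns:
        df = df.copy()
        df["site_id"] = (
            df["patient_id"] + "-" + df["lesion_id"] + "-" + df["site_kind"]
        )

    ds = Dataset()
    for site_id, g in df.groupby("site_id", sort=True):
        first = g.iloc[0]
        ds.sites[str(site_id)] = SkinSite(
            site_id=str(site_id),
            patient_id=str(first["patient_id"]),
            lesion_id=str(first["lesion_id"]),
            site_kind=str(first["site_kind"]),
            histology=str(first["histology"]),
            invasiveness=str(first["invasiveness"]),
        )
        for (mod, sds), gc in g.groupby(["modality", "sds"], sort=False):
            ch = Channel(Modality(mod), int(sds))
            trio = MeasurementTrio(channel=ch)
            for rep, gr in sorted(gc.groupby("repeat", sort=True), key=lambda kv: kv[0]):
                gr = gr.sort_values("wavelength_nm", kind="mergesort")
                w = gr["wavelength_nm"].to_numpy(float)
                if np.any(np.diff(w) <= 0):
                    raise DataError(
                        f"non-monotone wavelengths in site {site_id}, channel {ch.key}, "
                        f"repeat {rep}"
                    )
                dark = gr["dark"].to_numpy(float)
                trio.spectra.append(
                    Spectrum(
                        channel=ch,
                        wavelengths_nm=w,
                        intensities=gr["intensity"].to_numpy(float),
                        dark=None if np.all(np.isnan(dark)) else dark,
                        repeat_index=int(rep),
                    )
                )
            key = (str(site_id), ch)
            if len(trio.spectra) == 1 and trio.spectra[0].repeat_index == 0:
                # repeat index 0 marks an already-averaged spectrum
                ds.averaged[key] = trio.spectra[0].copy_with(repeat_index=0)
            else:
                ds.trios[key] = trio
    return ds


def dataset_to_frame(d: Dataset) -> pd.DataFrame:
    """Flatten a dataset into the canonical long-format table."""
    rows = []

    def emit(site: SkinSite, spec: Spectrum, repeat: int) -> None:
        n = len(spec)
        dark = spec.dark if spec.dark is not None else np.full(n, np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "site_id": site.site_id,
                    "patient_id": site.patient_id,
                    "lesion_id": site.lesion_id,
                    "site_kind": site.site_kind,
                    "histology": site.histology,
                    "invasiveness": site.invasiveness,
                    "modality": spec.channel.modality.value,
                    "sds": spec.channel.sds,
                    "repeat": repeat,
                    "wavelength_nm": spec.wavelengths_nm,
                    "intensity": spec.intensities,
                    "dark": dark,
                }
            )
        )

    def sort_key(item):
        (site_id, ch) = item[0]
        return (site_id, channel_index(ch))

    for (site_id, ch), trio in sorted(d.trios.items(), key=sort_key):
        site = d.sites[site_id]
        for spec in sorted(trio.spectra, key=lambda s: s.repeat_index):
            emit(site, spec, spec.repeat_index)
    for (site_id, ch), spec in sorted(d.averaged.items(), key=sort_key):
        emit(d.sites[site_id], spec, 0)

    if not rows:
        return pd.DataFrame(columns=_COLUMN_ORDER)
    return pd.concat(rows, ignore_index=True)[_COLUMN_ORDER]


def write_spectra_table(d: Dataset, path: str | Path) -> None:
    """Write a dataset as long-format CSV (canonical row and column order)."""
    df = dataset_to_frame(d)
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
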