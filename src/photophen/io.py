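"""Readers and writers for the plain-text and TIFF formats the pipeline uses.

Supported inputs: two-column spectrum CSV (``wavelength_nm,intensity``), a
tab-separated spectrometer text export (``#``-prefixed header lines, then
``wavelength<TAB>counts``), trace CSV
(``time_s,fluorescence,is_pulse,ppfd,light_label``), a semicolon-separated
fluorometer export dialect (device header lines skipped up to the column
header), single-plane grayscale TIFF with the pixel size from config or the
TIFF resolution tag, and YAML experiment configs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .pam import FluorescenceTrace, LightCurve, PhotoParams
from .shapes import Micrograph, ObjectShape, ReplicateShapeSummary
from .spectra import EmissionSpectrum, ProcessedSpectrum

__all__ = [
    "read_spectrum_csv",
    "read_spectrum_txt",
    "write_spectrum_csv",
    "read_trace_csv",
    "read_trace_fluorometer",
    "write_trace_csv",
    "read_micrograph",
    "write_micrograph",
    "write_object_table",
    "write_replicate_summaries",
    "write_light_curve",
    "photoparams_table",
    "load_config",
]


def read_spectrum_csv(path: str | Path, **meta) -> EmissionSpectrum:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength, intensity)")
    return EmissionSpectrum(
        wavelength_nm=df.iloc[:, 0].to_numpy(float),
        intensity=df.iloc[:, 1].to_numpy(float),
        meta=meta,
    )


def read_spectrum_txt(path: str | Path, **meta) -> EmissionSpectrum:
    """Tab-separated spectrometer export: ``#`` header lines, then wl<TAB>counts."""
    wl, counts = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        wl.append(float(parts[0]))
        counts.append(float(parts[1]))
    return EmissionSpectrum(np.array(wl), np.array(counts), meta=meta)


def write_spectrum_csv(s: EmissionSpectrum | ProcessedSpectrum, path: str | Path) -> None:
    pd.DataFrame({"wavelength_nm": s.wavelength_nm, "intensity": s.intensity}).to_csv(
        path, index=False
    )


def read_trace_csv(path: str | Path, **meta) -> FluorescenceTrace:
    df = pd.read_csv(path)
    required = {"time_s", "fluorescence", "is_pulse", "ppfd", "light_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return FluorescenceTrace(
        time_s=df["time_s"].to_numpy(float),
        fluorescence=df["fluorescence"].to_numpy(float),
        is_pulse=df["is_pulse"].to_numpy().astype(bool),
        ppfd=df["ppfd"].to_numpy(float),
        light_label=df["light_label"].to_numpy(object),
        meta=meta,
    )


def read_trace_fluorometer(path: str | Path, **meta) -> FluorescenceTrace:
    """Semicolon-separated fluorometer export; device header lines are skipped
    up to the line that starts with ``time_s;``."""
    lines = Path(path).read_text().splitlines()
    start = next(
        (i for i, ln in enumerate(lines) if ln.lower().startswith("time_s;")), None
    )
    if start is None:
        raise ValueError(f"{path}: no 'time_s;...' column header found")
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines[start:])), sep=";")
    return FluorescenceTrace(
        time_s=df["time_s"].to_numpy(float),
        fluorescence=df["fluorescence"].to_numpy(float),
        is_pulse=df["is_pulse"].to_numpy().astype(bool),
        ppfd=df["ppfd"].to_numpy(float),
        light_label=df["light_label"].to_numpy(object),
        meta=meta,
    )


def write_trace_csv(t: FluorescenceTrace, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": t.time_s,
            "fluorescence": t.fluorescence,
            "is_pulse": t.is_pulse.astype(int),
            "ppfd": t.ppfd,
            "light_label": t.light_label,
        }
    ).to_csv(path, index=False)


def read_micrograph(path: str | Path, pixel_size_um: float | None = None, **meta) -> Micrograph:
    """Read a single-plane grayscale TIFF; pixel size from argument or the
    TIFF X-resolution tag (pixels per micrometre)."""
    with tifffile.TiffFile(str(path)) as tf:
        img = tf.asarray()
        if pixel_size_um is None:
            page = tf.pages[0]
            tag = page.tags.get("XResolution")
            if tag is not None:
                num, den = tag.value
                if num > 0:
                    pixel_size_um = den / num
    if pixel_size_um is None:
        raise ValueError(f"{path}: pixel size not given and no TIFF resolution tag")
    if img.ndim == 3 and img.shape[0] == 1:
        img = img[0]
    return Micrograph(image=img, pixel_size_um=float(pixel_size_um), meta=meta)


def write_micrograph(image: np.ndarray, path: str | Path, pixel_size_um: float) -> None:
    ppu = 1.0 / pixel_size_um  # pixels per micrometre
    tifffile.imwrite(str(path), image, resolution=(ppu, ppu))


def photoparams_table(params: list[PhotoParams]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": [p.time_s for p in params],
            "ppfd": [p.ppfd for p in params],
            "light_label": [p.light_label for p in params],
            "F": [p.F for p in params],
            "Fm_prime": [p.Fm_prime for p in params],
            "F0_prime": [p.F0_prime for p in params],
            "fv_fm": [p.fv_fm for p in params],
            "phi_psii": [p.phi_psii for p in params],
            "npq": [p.npq for p in params],
            "ql": [p.ql for p in params],
            "retr": [p.retr for p in params],
            "flags": [";".join(p.flags) for p in params],
        }
    )


def write_light_curve(lc: LightCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"ppfd": lc.ppfd, "retr_mean": lc.retr_mean, "retr_sd": lc.retr_sd}
    ).to_csv(path, index=False)


def write_object_table(objects: list[ObjectShape], path: str | Path) -> None:
    pd.DataFrame(
        {
            "label": [o.label for o in objects],
            "area_um2": [o.area_um2 for o in objects],
            "perimeter_um": [o.perimeter_um for o in objects],
            "circularity": [o.circularity for o in objects],
            "touches_border": [o.touches_border for o in objects],
            "flags": [";".join(o.flags) for o in objects],
        }
    ).to_csv(path, index=False)


def write_replicate_summaries(summaries: list[ReplicateShapeSummary], path: str | Path) -> None:
    pd.DataFrame(
        {
            "replicate_id": [s.replicate_id for s in summaries],
            "n_objects": [s.n_objects for s in summaries],
            "median_circularity": [s.median_circularity for s in summaries],
            "iqr_circularity": [s.iqr_circularity for s in summaries],
            "median_area_um2": [s.median_area_um2 for s in summaries],
            "iqr_area_um2": [s.iqr_area_um2 for s in summaries],
            "flags": [";".join(s.flags) for s in summaries],
        }
    ).to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
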