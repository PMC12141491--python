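"""77 K chlorophyll-fluorescence spectra: processing and the PSI/PSII statistic.

At liquid-nitrogen temperature the two photosystems emit in separable bands —
PSII around 680–695 nm, PSI around 710–730 nm — so a single emission spectrum
reads out how excitation is distributed between them.  State transitions
(movement of mobile LHCII antenna between the photosystems) shift this
balance, and the quantity analysed here is the *normalized PSI fluorescence*:
the maximum emission in the PSI window after the spectrum has been smoothed
(4 nm running average), zeroed against its 800 nm signal, and normalized to
the PSII peak between 680 and 690 nm.

Concentrated samples re-absorb their own fluorescence (self-absorption),
distorting the spectral shape especially in the 710–730 nm region.  Samples
are therefore measured as a dilution series, and :func:`qc_select_dilution`
picks the most concentrated dilution whose PSI statistic agrees with the next
more dilute one — i.e. the least noisy spectrum whose shape is already
dilution-independent.

The processing order is fixed (resample -> smooth -> baseline -> normalize)
and tracked as provenance; applying steps out of order raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import stats as _stats

PSII_WINDOW_NM = (680.0, 690.0)
PSI_WINDOW_NM = (710.0, 730.0)
BASELINE_NM = 800.0

__all__ = [
    "PSII_WINDOW_NM",
    "PSI_WINDOW_NM",
    "BASELINE_NM",
    "EmissionSpectrum",
    "ProcessedSpectrum",
    "DilutionSeries",
    "resample_uniform",
    "smooth_running_average",
    "subtract_baseline",
    "normalize_to_psii",
    "process_spectrum",
    "psi_statistic",
    "qc_select_dilution",
    "compare_states",
]


@dataclass
class EmissionSpectrum:
    """A wavelength-indexed fluorescence spectrum with sample metadata.

    ``meta`` typically carries sample id, species, treatment label (e.g.
    PSII-light / PSI-light / dark, salinity in PPT), ``dilution_percent``
    and replicate id.  ``provenance`` lists the processing steps applied.
    """

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.wavelength_nm) < 2:
            raise ValueError("spectrum needs at least two points")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if len(self.intensity) != len(self.wavelength_nm):
            raise ValueError("wavelength and intensity lengths differ")

    @property
    def step_nm(self) -> float | None:
        """Grid step if uniform, else None."""
        d = np.diff(self.wavelength_nm)
        return float(d[0]) if np.allclose(d, d[0], rtol=1e-8, atol=1e-10) else None


@dataclass
class ProcessedSpectrum:
    """Fully processed spectrum with the PSII peak pinned at 1."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    psii_peak_nm: float
    meta: dict = field(default_factory=dict)
    provenance: tuple[str, ...] = ()
    flags: list[str] = field(default_factory=list)


@dataclass
class DilutionSeries:
    """Spectra of one biological replicate at several dilutions, plus QC."""

    spectra: list[ProcessedSpectrum]
    psi_values: list[float]
    selected_dilution: float | None = None
    flags: list[str] = field(default_factory=list)


def _window_mask(wl: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (wl >= lo - 1e-9) & (wl <= hi + 1e-9)


def resample_uniform(s: EmissionSpectrum, step_nm: float) -> EmissionSpectrum:
    """Linearly interpolate onto a uniform grid spanning the original range.

    Never extrapolates: the new grid runs from the first original wavelength
    in steps of ``step_nm`` up to the last, so endpoints are preserved within
    one step.
    """
    if step_nm <= 0:
        raise ValueError("step_nm must be positive")
    wl = s.wavelength_nm
    n = int(np.floor((wl[-1] - wl[0]) / step_nm + 1e-9)) + 1
    grid = wl[0] + step_nm * np.arange(n)
    vals = np.interp(grid, wl, s.intensity)
    return replace(s, wavelength_nm=grid, intensity=vals, provenance=s.provenance + ("resample",))


def smooth_running_average(s: EmissionSpectrum, window_nm: float = 4.0) -> EmissionSpectrum:
    """Centred running average over all points within ±window_nm/2, inclusive.

    Requires a uniform grid; the window shrinks (truncated mean) at the
    spectrum edges.
    """
    step = s.step_nm
    if step is None:
        raise ValueError("running average requires a uniform grid; resample first")
    if window_nm < step:
        raise ValueError("window_nm must be at least the grid step")
    half_pts = int(np.floor(window_nm / 2.0 / step + 1e-9))
    kernel = np.ones(2 * half_pts + 1)
    sums = np.convolve(s.intensity, kernel, mode="same")
    counts = np.convolve(np.ones_like(s.intensity), kernel, mode="same")
    return replace(s, intensity=sums / counts, provenance=s.provenance + ("smooth",))


def subtract_baseline(
    s: EmissionSpectrum, ref_nm: float = BASELINE_NM, half_width_nm: float = 2.0
) -> EmissionSpectrum:
    """Zero the spectrum against its signal near ``ref_nm``.

    The zero level is the mean intensity over [ref_nm - half_width,
    ref_nm + half_width]; chlorophyll no longer fluoresces at 800 nm, so this
    estimates the instrument offset.  Resulting negative values are permitted
    (they are noise about zero), not clamped.
    """
    if "normalize" in s.provenance:
        raise ValueError("baseline subtraction must precede normalization")
    mask = _window_mask(s.wavelength_nm, ref_nm - half_width_nm, ref_nm + half_width_nm)
    if not mask.any():
        raise ValueError(f"grid does not cover the {ref_nm} nm baseline region")
    level = float(s.intensity[mask].mean())
    return replace(s, intensity=s.intensity - level, provenance=s.provenance + ("baseline",))


def normalize_to_psii(
    s: EmissionSpectrum, window_nm: tuple[float, float] = PSII_WINDOW_NM
) -> ProcessedSpectrum:
    """Divide the spectrum by its maximum over the PSII window (680–690 nm).

    Requires the baseline to have been subtracted already.  Records the peak
    wavelength; ties are broken toward the shorter wavelength.
    """
    if "baseline" not in s.provenance:
        raise ValueError("subtract the baseline before normalizing")
    mask = _window_mask(s.wavelength_nm, *window_nm)
    if not mask.any():
        raise ValueError("grid does not cover the PSII window")
    win = s.intensity[mask]
    peak = float(win.max())
    if peak <= 0:
        raise ValueError("PSII window maximum is non-positive (dead or empty sample)")
    peak_nm = float(s.wavelength_nm[mask][int(np.argmax(win))])  # first max = shortest wavelength
    meta = dict(s.meta)
    meta["raw_psii_max"] = peak  # pre-normalization counts; used by dilution QC noise floor
    return ProcessedSpectrum(
        wavelength_nm=s.wavelength_nm,
        intensity=s.intensity / peak,
        psii_peak_nm=peak_nm,
        meta=meta,
        provenance=s.provenance + ("normalize",),
    )


def process_spectrum(
    s: EmissionSpectrum,
    step_nm: float = 0.5,
    window_nm: float = 4.0,
    baseline_nm: float = BASELINE_NM,
) -> ProcessedSpectrum:
    """Full fixed-order pipeline: resample -> smooth -> baseline -> normalize."""
    r = resample_uniform(s, step_nm)
    sm = smooth_running_average(r, window_nm)
    b = subtract_baseline(sm, baseline_nm)
    return normalize_to_psii(b)


def psi_statistic(
    p: ProcessedSpectrum, window_nm: tuple[float, float] = PSI_WINDOW_NM
) -> tuple[float, float, bool]:
    """Normalized PSI fluorescence: the window maximum over 710–730 nm.

    Returns ``(value, wavelength, has_local_peak)``.  Some taxa (notably
    *Bryopsis plumosa*) lack a distinct PSI emission peak; the window maximum
    is still returned then, with ``has_local_peak`` False so downstream
    reporting can flag it.
    """
    mask = _window_mask(p.wavelength_nm, *window_nm)
    if not mask.any():
        raise ValueError("grid does not cover the PSI window")
    win = p.intensity[mask]
    wl = p.wavelength_nm[mask]
    idx = int(np.argmax(win))
    value = float(win[idx])
    # a local PSI peak exists if some interior window point beats both neighbours
    interior = np.zeros(len(win), dtype=bool)
    if len(win) >= 3:
        interior[1:-1] = (win[1:-1] > win[:-2]) & (win[1:-1] >= win[2:])
    has_local_peak = bool(interior.any())
    return value, float(wl[idx]), has_local_peak


def qc_select_dilution(
    series: list[ProcessedSpectrum],
    tol_rel: float = 0.05,
    noise_floor: float = 0.0,
) -> DilutionSeries:
    """Select the working dilution of a serially diluted sample.

    ``series`` holds processed spectra of one biological replicate, each with
    ``dilution_percent`` in its metadata.  Walking from most concentrated to
    most dilute, the selected dilution is the most concentrated one whose PSI
    statistic agrees with the next more dilute one within ``tol_rel``
    (relative) — agreement in shape means self-absorption is no longer
    distorting the spectrum, so the less noisy concentrated data can be used.
    If no neighbouring pair agrees, the most dilute spectrum whose raw PSII
    window maximum exceeds ``noise_floor`` is selected and the series flagged
    for self-absorption.  A single-dilution series is returned selected but
    flagged unverified.
    """
    if not series:
        raise ValueError("empty dilution series")
    ids = {s.meta.get("sample_id") for s in series}
    if len(ids) > 1:
        raise ValueError("dilution series mixes sample ids")
    ordered = sorted(series, key=lambda s: -float(s.meta["dilution_percent"]))
    psi = [psi_statistic(s)[0] for s in ordered]
    dils = [float(s.meta["dilution_percent"]) for s in ordered]
    if len(ordered) == 1:
        return DilutionSeries(ordered, psi, selected_dilution=dils[0], flags=["unverified"])
    for i in range(len(ordered) - 1):
        ref = psi[i + 1]
        if ref != 0 and abs(psi[i] - ref) / abs(ref) <= tol_rel:
            return DilutionSeries(ordered, psi, selected_dilution=dils[i])
    flags = ["self_absorption_warning"]
    for s, d in zip(reversed(ordered), reversed(dils)):
        raw_max = s.meta.get("raw_psii_max", np.inf)
        if raw_max > noise_floor:
            return DilutionSeries(ordered, psi, selected_dilution=d, flags=flags)
    flags.append("all_below_noise_floor")
    return DilutionSeries(ordered, psi, selected_dilution=None, flags=flags)


def compare_states(
    group_a: list[float] | np.ndarray,
    group_b: list[float] | np.ndarray,
    alpha: float = 0.05,
    name_a: str = "A",
    name_b: str = "B",
) -> _stats.GroupComparison:
    """Gated comparison of normalized PSI fluorescence between two treatments.

    Each value is one biological replicate's PSI statistic (one well = one
    replicate).  Delegates to the gated parametric/non-parametric decision
    tree in :mod:`photophen.stats`.
    """
    return _stats.gated_compare(
        _stats.GroupData({name_a: np.asarray(group_a), name_b: np.asarray(group_b)}, alpha=alpha)
    )
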