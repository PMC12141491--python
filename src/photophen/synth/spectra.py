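"""Synthetic 77 K emission spectra with known PSI/PSII ground truth.

A spectrum is a sum of Gaussian emission bands — two PSII bands near
680–695 nm and one PSI band near 715 nm — on a constant instrument offset,
optionally distorted by concentration-dependent self-absorption and additive
Gaussian noise.  The light-acclimation state enters through the PSI band
amplitude: state 2 (far-red-driven antenna movement towards PSI) multiplies
it by a configurable factor > 1.

Self-absorption is modelled as attenuation by ``exp(-c * A(lambda))`` where
``A`` is an idealized chlorophyll-like red-region absorption profile peaking
near 680 nm (shipped as a packaged table; it is a constructed synthetic
curve, not a measured one).  Because ``A`` is much larger in the PSII window
than at 710–730 nm, increasing ``c`` suppresses the PSII peak preferentially
and inflates the normalized PSI statistic — the distortion the dilution-series
QC exists to catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from ..spectra import EmissionSpectrum

__all__ = ["SpectrumGenConfig", "SpectrumTruth", "load_absorption_profile", "gen_spectrum"]

_STATES = ("state1", "state2", "custom")


@dataclass
class SpectrumGenConfig:
    """Generative parameters for one synthetic 77 K spectrum.

    The last band in ``band_centers_nm`` is the PSI band (state-dependent);
    the preceding bands belong to PSII.  Amplitudes are in detector counts.
    """

    band_centers_nm: tuple[float, ...] = (685.0, 695.0, 715.0)
    band_sigmas_nm: tuple[float, ...] = (6.0, 7.0, 10.0)
    band_amplitudes: tuple[float, ...] = (1000.0, 550.0, 450.0)
    baseline_offset: float = 50.0
    noise_sd: float = 0.0
    self_absorption_strength: float = 0.0
    grid: tuple[float, float, float] = (650.0, 800.0, 0.5)
    state2_psi_factor: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.band_centers_nm) == len(self.band_sigmas_nm) == len(self.band_amplitudes)):
            raise ValueError("band parameter tuples must have equal length")
        if any(a < 0 for a in self.band_amplitudes):
            raise ValueError("band amplitudes must be non-negative")
        if any(s <= 0 for s in self.band_sigmas_nm):
            raise ValueError("band sigmas must be positive")
        start, stop, step = self.grid
        if step <= 0 or stop <= start:
            raise ValueError("grid must have positive step and stop > start")
        if start > 650.0 or stop < 800.0:
            raise ValueError("grid must span at least 650-800 nm (800 nm baseline region)")
        if self.self_absorption_strength < 0:
            raise ValueError("self_absorption_strength must be non-negative")
        if self.state2_psi_factor <= 1.0:
            raise ValueError("state2_psi_factor must exceed 1")

    @property
    def wavelengths(self) -> np.ndarray:
        start, stop, step = self.grid
        n = int(np.floor((stop - start) / step + 1e-9)) + 1
        return start + step * np.arange(n)


@dataclass
class SpectrumTruth:
    """Ground truth attached to a generated spectrum."""

    state: str
    effective_amplitudes: tuple[float, ...]
    psi_over_psii_amplitude: float  # pre-distortion PSI / max PSII band amplitude
    self_absorption_strength: float
    seed: int
    flags: list[str] = field(default_factory=list)


def load_absorption_profile() -> tuple[np.ndarray, np.ndarray]:
    """Packaged idealized chlorophyll absorption profile (wavelength, A).

    Normalized to a maximum of 1 near 680 nm; synthetic by construction.
    """
    path = resources.files("photophen").joinpath("data", "chl_absorption_synthetic.csv")
    arr = np.loadtxt(str(path), delimiter=",", skiprows=1)
    return arr[:, 0], arr[:, 1]


def band_sum(
    wavelengths: np.ndarray,
    centers: tuple[float, ...],
    sigmas: tuple[float, ...],
    amplitudes: tuple[float, ...],
) -> np.ndarray:
    """Sum of Gaussian emission bands evaluated on a wavelength grid."""
    wl = np.asarray(wavelengths, dtype=float)
    out = np.zeros_like(wl)
    for c, s, a in zip(centers, sigmas, amplitudes):
        out += a * np.exp(-0.5 * ((wl - c) / s) ** 2)
    return out


def gen_spectrum(
    cfg: SpectrumGenConfig, state: str = "state1", meta: dict | None = None
) -> tuple[EmissionSpectrum, SpectrumTruth]:
    """Generate one synthetic emission spectrum for the given light state.

    ``state2`` multiplies the PSI band amplitude by ``cfg.state2_psi_factor``;
    ``state1`` and ``custom`` use the configured amplitudes as-is.  The
    returned ground truth records the pre-distortion PSI/PSII peak-amplitude
    ratio.
    """
    if state not in _STATES:
        raise ValueError(f"state must be one of {_STATES}")
    wl = cfg.wavelengths
    amps = list(cfg.band_amplitudes)
    if state == "state2":
        amps[-1] *= cfg.state2_psi_factor
    clean = band_sum(wl, cfg.band_centers_nm, cfg.band_sigmas_nm, tuple(amps))
    if cfg.self_absorption_strength > 0:
        awl, aval = load_absorption_profile()
        profile = np.interp(wl, awl, aval)
        clean = clean * np.exp(-cfg.self_absorption_strength * profile)
    intensity = clean + cfg.baseline_offset
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        intensity = intensity + rng.normal(0.0, cfg.noise_sd, size=len(wl))
    psii_amp = max(amps[:-1]) if len(amps) > 1 else amps[0]
    truth = SpectrumTruth(
        state=state,
        effective_amplitudes=tuple(amps),
        psi_over_psii_amplitude=amps[-1] / psii_amp if psii_amp > 0 else float("inf"),
        self_absorption_strength=cfg.self_absorption_strength,
        seed=cfg.seed,
    )
    spectrum = EmissionSpectrum(wavelength_nm=wl, intensity=intensity, meta=dict(meta or {}))
    return spectrum, truth
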