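"""Saturating-pulse (PAM) fluorometry: pulse extraction and photosynthetic parameters.

A pulse-amplitude-modulation fluorometer records chlorophyll *a* fluorescence
while firing brief saturating light pulses that transiently close all PSII
reaction centres.  From the steady fluorescence ``F`` just before a pulse and
the pulse maximum ``Fm'`` (``Fm`` in darkness), the standard quenching
parameters are derived:

* ``Fv/Fm = (Fm - F0)/Fm`` — maximum PSII quantum yield of a dark-acclimated
  sample,
* ``PhiPSII = (Fm' - F)/Fm'`` — effective PSII yield in the light,
* ``NPQ = Fm/Fm' - 1`` — non-photochemical quenching,
* ``F0' = F0 / (Fv/Fm + F0/Fm')`` — estimated minimal fluorescence of the
  light-acclimated state (Oxborough–Baker estimate),
* ``qL = ((Fm' - F)/(Fm' - F0')) * (F0'/F)`` — fraction of open PSII centres
  (oxidised QA); 1 = fully open, 0 = fully closed,
* ``rETR = absorption_factor * PhiPSII * PPFD`` — relative electron transport
  rate, with a plant-based default absorption factor of 0.42.

Out-of-range values (negative NPQ, qL outside [0, 1]) are reported raw and
flagged, never silently clipped: they carry quality-control information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Default fraction of incident photons absorbed by PSII (plant-based estimate).
DEFAULT_ABSORPTION_FACTOR = 0.42

__all__ = [
    "DEFAULT_ABSORPTION_FACTOR",
    "FluorescenceTrace",
    "PulseRecord",
    "PhotoParams",
    "LightCurve",
    "extract_pulses",
    "fv_over_fm",
    "npq",
    "f0_prime",
    "ql",
    "phi_psii",
    "retr",
    "trace_timecourse",
    "build_light_curve",
]


@dataclass
class FluorescenceTrace:
    """A sampled PAM fluorescence trace with pulse and actinic annotations.

    ``is_pulse`` marks samples recorded during a saturating pulse; ``ppfd``
    and ``light_label`` carry the actinic schedule per sample (labels such as
    ``dark``, ``PSII-red``, ``PSI-far-red``, ``actinic-step``).
    """

    time_s: np.ndarray
    fluorescence: np.ndarray
    is_pulse: np.ndarray
    ppfd: np.ndarray
    light_label: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.is_pulse = np.asarray(self.is_pulse, dtype=bool)
        self.ppfd = np.asarray(self.ppfd, dtype=float)
        self.light_label = np.asarray(self.light_label, dtype=object)
        if self.time_s.ndim != 1 or len(self.time_s) < 2:
            raise ValueError("trace needs at least two samples")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.ppfd < 0):
            raise ValueError("PPFD must be non-negative")
        for arr in (self.fluorescence, self.is_pulse, self.ppfd, self.light_label):
            if len(arr) != len(self.time_s):
                raise ValueError("all channels must have equal length")


@dataclass
class PulseRecord:
    """One saturating pulse: pre-pulse steady F and the pulse maximum."""

    time_s: float
    F: float
    Fm_or_Fmp: float
    ppfd: float
    light_label: str
    is_dark_reference: bool = False
    flags: list[str] = field(default_factory=list)


@dataclass
class PhotoParams:
    """Derived photosynthetic parameters at one saturating pulse."""

    time_s: float
    ppfd: float
    light_label: str
    F: float
    Fm_prime: float
    F0_prime: float
    fv_fm: float
    phi_psii: float
    npq: float
    ql: float
    retr: float
    flags: list[str] = field(default_factory=list)


@dataclass
class LightCurve:
    """Group light-response curve (PPFD vs rETR) with per-replicate curves.

    The group curve is truncated at the highest PPFD step for which rETR is
    positive in *all* replicates; per-replicate curves are kept untruncated.
    """

    ppfd: np.ndarray
    retr_mean: np.ndarray
    retr_sd: np.ndarray
    replicate_curves: list[np.ndarray]
    truncation_ppfd: float
    truncated: bool


def fv_over_fm(F0: float, Fm: float) -> float:
    """Maximum PSII quantum yield ``(Fm - F0)/Fm`` of a dark-acclimated sample."""
    if Fm <= 0:
        raise ValueError("Fm must be positive")
    if F0 > Fm:
        raise ValueError("F0 cannot exceed Fm")
    return (Fm - F0) / Fm


def npq(Fm: float, Fm_prime: float) -> float:
    """Non-photochemical quenching ``Fm/Fm' - 1``.

    Negative values (``Fm' > Fm``) are returned as-is; callers flag them.
    """
    if Fm_prime <= 0:
        raise ValueError("Fm' must be positive")
    return Fm / Fm_prime - 1.0


def f0_prime(F0: float, FvFm: float, Fm_prime: float) -> float:
    """Oxborough–Baker estimate ``F0' = F0 / (Fv/Fm + F0/Fm')``.

    Equals ``F0`` exactly when ``Fm' = Fm`` (dark limit).
    """
    denom = FvFm + F0 / Fm_prime
    if denom <= 0:
        raise ValueError("Fv/Fm + F0/Fm' must be positive")
    return F0 / denom


def ql(F: float, Fm_prime: float, F0_prime: float) -> float:
    """Fraction of open PSII centres ``((Fm'-F)/(Fm'-F0')) * (F0'/F)``.

    By construction qL = 1 at F = F0' and qL = 0 at F = Fm'.  Values outside
    [0, 1] are returned raw for the caller to flag.
    """
    if Fm_prime <= F0_prime:
        raise ValueError("Fm' must exceed F0'")
    if F <= 0:
        raise ValueError("F must be positive")
    return ((Fm_prime - F) / (Fm_prime - F0_prime)) * (F0_prime / F)


def phi_psii(F: float, Fm_prime: float) -> float:
    """Effective PSII quantum yield ``(Fm' - F)/Fm'``."""
    if Fm_prime <= 0:
        raise ValueError("Fm' must be positive")
    return (Fm_prime - F) / Fm_prime


def retr(phi: float, ppfd: float, absorption_factor: float = DEFAULT_ABSORPTION_FACTOR) -> float:
    """Relative electron transport rate ``absorption_factor * phi * PPFD``."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi_psii must lie in [0, 1]")
    if ppfd < 0:
        raise ValueError("PPFD must be non-negative")
    return absorption_factor * phi * ppfd


def _pulse_onsets(is_pulse: np.ndarray) -> np.ndarray:
    """Indices where a pulse begins (rising edges of the pulse channel)."""
    padded = np.concatenate(([False], is_pulse))
    return np.nonzero(is_pulse & ~padded[:-1])[0]


def extract_pulses(
    trace: FluorescenceTrace,
    pre_window_s: float = 2.0,
    peak_window_s: float = 1.0,
    peak_method: str = "mean",
) -> list[PulseRecord]:
    """Locate saturating pulses and read off F and Fm'/Fm for each.

    ``F`` is the mean fluorescence over ``pre_window_s`` immediately before
    pulse onset (pulse samples excluded); ``Fm'`` is estimated over
    ``peak_window_s`` from onset.  A saturating pulse holds fluorescence at
    a plateau, so the default estimator is the mean of the in-pulse samples —
    unbiased under noise, whereas the sample maximum is biased upward by
    roughly half a noise SD.  ``peak_method="max"`` selects the maximum
    instead (useful when the window spans a rising transient).  The first
    pulse inside a dark segment is marked as the dark reference defining F0
    and Fm.  A pulse whose peak falls below its pre-pulse mean is flagged,
    not dropped.
    """
    if pre_window_s <= 0 or peak_window_s <= 0:
        raise ValueError("windows must be positive")
    if peak_method not in ("mean", "max"):
        raise ValueError("peak_method must be 'mean' or 'max'")
    onsets = _pulse_onsets(trace.is_pulse)
    if len(onsets) == 0:
        raise ValueError("trace contains no pulse annotations")
    records: list[PulseRecord] = []
    dark_seen = False
    t = trace.time_s
    for i0 in onsets:
        t_on = t[i0]
        pre = (t >= t_on - pre_window_s) & (t < t_on) & ~trace.is_pulse
        peak = (t >= t_on) & (t <= t_on + peak_window_s) & trace.is_pulse
        if not pre.any():
            # pulse at the very start of the trace: no steady-state estimate
            continue
        F = float(trace.fluorescence[pre].mean())
        peak_vals = trace.fluorescence[peak]
        Fmp = float(peak_vals.mean() if peak_method == "mean" else peak_vals.max())
        rec = PulseRecord(
            time_s=float(t_on),
            F=F,
            Fm_or_Fmp=Fmp,
            ppfd=float(trace.ppfd[i0]),
            light_label=str(trace.light_label[i0]),
            is_dark_reference=False,
        )
        if Fmp < F:
            rec.flags.append("peak_below_steady")
        if not dark_seen and rec.light_label == "dark":
            rec.is_dark_reference = True
            dark_seen = True
        records.append(rec)
    return records


def trace_timecourse(
    trace: FluorescenceTrace,
    pre_window_s: float = 2.0,
    peak_window_s: float = 1.0,
    dark_reference: tuple[float, float] | None = None,
    absorption_factor: float = DEFAULT_ABSORPTION_FACTOR,
) -> list[PhotoParams]:
    """Full per-pulse parameter time course for a trace.

    The dark reference (F0, Fm) comes from the first pulse in a dark segment,
    or from ``dark_reference`` when the protocol was run without dark
    acclimation (e.g. rapid light curves measured straight from growth light).
    """
    records = extract_pulses(trace, pre_window_s, peak_window_s)
    if dark_reference is not None:
        F0, Fm = dark_reference
    else:
        ref = next((r for r in records if r.is_dark_reference), None)
        if ref is None:
            raise ValueError(
                "no dark reference: trace has no pulse in a dark segment; "
                "pass dark_reference=(F0, Fm) explicitly"
            )
        F0, Fm = ref.F, ref.Fm_or_Fmp
    FvFm = fv_over_fm(F0, Fm)
    out: list[PhotoParams] = []
    for rec in records:
        Fmp = rec.Fm_or_Fmp
        F = rec.F
        flags = list(rec.flags)
        npq_val = npq(Fm, Fmp)
        if npq_val < 0:
            flags.append("npq_negative")
        F0p = f0_prime(F0, FvFm, Fmp)
        if math.isclose(Fmp, F0p):
            ql_val = float("nan")
            flags.append("ql_undefined")
        else:
            ql_val = ql(F, Fmp, F0p)
            if not 0.0 <= ql_val <= 1.0:
                flags.append("ql_out_of_range")
        phi = phi_psii(F, Fmp)
        retr_val = absorption_factor * phi * rec.ppfd  # phi may be <0 on flagged pulses
        out.append(
            PhotoParams(
                time_s=rec.time_s,
                ppfd=rec.ppfd,
                light_label=rec.light_label,
                F=F,
                Fm_prime=Fmp,
                F0_prime=F0p,
                fv_fm=FvFm,
                phi_psii=phi,
                npq=npq_val,
                ql=ql_val,
                retr=retr_val,
                flags=flags,
            )
        )
    return out


def build_light_curve(replicates: list[list[PhotoParams]], rtol: float = 1e-6) -> LightCurve:
    """Aggregate per-replicate rapid light curves onto a common PPFD ladder.

    All replicates must have been measured on the same, strictly increasing
    PPFD ladder.  The group curve is truncated before the first step at which
    any replicate's rETR is not positive, so that the reported curve only
    spans intensities with positive electron transport in every replicate.
    """
    if not replicates:
        raise ValueError("no replicates")
    ladders = []
    curves = []
    for rep in replicates:
        rep_sorted = sorted(rep, key=lambda p: p.ppfd)
        ppfd = np.array([p.ppfd for p in rep_sorted])
        if np.any(np.diff(ppfd) <= 0):
            raise ValueError("PPFD steps must be strictly increasing")
        ladders.append(ppfd)
        curves.append(np.array([p.retr for p in rep_sorted]))
    ref = ladders[0]
    for lad in ladders[1:]:
        if len(lad) != len(ref) or not np.allclose(lad, ref, rtol=rtol):
            raise ValueError("replicates measured on inconsistent PPFD ladders")
    mat = np.vstack(curves)
    nonpos = np.any(mat <= 0, axis=0)
    cut = int(np.argmax(nonpos)) if nonpos.any() else len(ref)
    truncated = cut < len(ref)
    if cut == 0:
        raise ValueError("no PPFD step has positive rETR in all replicates")
    return LightCurve(
        ppfd=ref[:cut],
        retr_mean=mat[:, :cut].mean(axis=0),
        retr_sd=mat[:, :cut].std(axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros(cut),
        replicate_curves=curves,
        truncation_ppfd=float(ref[cut - 1]),
        truncated=truncated,
    )
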