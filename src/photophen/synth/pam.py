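"""Synthetic PAM fluorescence traces with exact per-pulse ground truth.

The generator is defined by *inverting* the saturating-pulse analysis
formulas rather than by a mechanistic kinetic model: the user supplies the
quenching time courses NPQ(t) and qL(t) together with a dark reference
(F0, Fm), and the fluorescence levels at each pulse follow uniquely:

    Fm'(t) = Fm / (1 + NPQ(t))
    F0'(t) = F0 / (Fv/Fm + F0/Fm'(t))
    F(t)   = Fm' F0' / (qL(t) (Fm' - F0') + F0')

the last being the unique root in (0, Fm'] of the qL definition
``qL = ((Fm'-F)/(Fm'-F0')) (F0'/F)``.  Analysing a noise-free generated
trace must therefore return exactly the requested courses — this round trip
is the primary oracle for the analysis module.

The steady fluorescence between pulses is held piecewise-constant at the
value implied by the courses at the *next* pulse onset, so that the
pre-pulse-window mean used by the analyser recovers F exactly rather than
approximately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ..pam import DEFAULT_ABSORPTION_FACTOR, FluorescenceTrace

__all__ = ["TraceGenConfig", "PulseTruth", "TraceTruth", "steady_fluorescence", "gen_pam_trace"]


@dataclass
class TraceGenConfig:
    """Generative parameters for one PAM trace.

    ``light_schedule`` is an ordered list of ``(duration_s, ppfd, label)``
    segments; the first segment must be dark so the first pulse defines the
    F0/Fm reference.  ``npq_course`` and ``ql_course`` map time (s) to NPQ(t)
    and qL(t).
    """

    F0: float = 400.0
    Fm: float = 2000.0
    npq_course: Callable[[float], float] = lambda t: 0.0
    ql_course: Callable[[float], float] = lambda t: 1.0
    light_schedule: tuple[tuple[float, float, str], ...] = (
        (120.0, 0.0, "dark"),
        (900.0, 50.0, "PSII-red"),
        (900.0, 50.0, "PSI-far-red"),
    )
    pulse_interval_s: float = 30.0
    pulse_width_s: float = 1.0
    sample_dt_s: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.Fm > self.F0 > 0:
            raise ValueError("need Fm > F0 > 0")
        if self.pulse_interval_s <= 0 or self.pulse_width_s <= 0 or self.sample_dt_s <= 0:
            raise ValueError("pulse interval, width and sample step must be positive")
        if self.pulse_width_s >= self.pulse_interval_s:
            raise ValueError("pulse width must be shorter than the pulse interval")
        if not self.light_schedule or any(d <= 0 for d, _, _ in self.light_schedule):
            raise ValueError("schedule segments must have positive duration")
        if self.light_schedule[0][2] != "dark":
            raise ValueError("first schedule segment must be dark (defines F0 and Fm)")


@dataclass
class PulseTruth:
    """True per-pulse fluorescence levels and parameters."""

    time_s: float
    F: float
    Fm_prime: float
    F0_prime: float
    npq: float
    ql: float
    phi_psii: float
    retr: float
    ppfd: float
    light_label: str


@dataclass
class TraceTruth:
    F0: float
    Fm: float
    fv_fm: float
    pulses: list[PulseTruth]
    seed: int
    flags: list[str] = field(default_factory=list)


def steady_fluorescence(F0: float, Fm: float, npq_t: float, ql_t: float) -> tuple[float, float, float]:
    """Solve the quenching formulas for (F, Fm', F0') at one time point."""
    fvfm = (Fm - F0) / Fm
    fmp = Fm / (1.0 + npq_t)
    f0p = F0 / (fvfm + F0 / fmp)
    F = fmp * f0p / (ql_t * (fmp - f0p) + f0p)
    return F, fmp, f0p


def _segment_at(schedule, t: float) -> tuple[float, str]:
    edge = 0.0
    for dur, ppfd, label in schedule:
        edge += dur
        if t < edge:
            return ppfd, label
    dur, ppfd, label = schedule[-1]
    return ppfd, label


def gen_pam_trace(cfg: TraceGenConfig) -> tuple[FluorescenceTrace, TraceTruth]:
    """Generate a pulse-train fluorescence trace and its exact ground truth.

    Pulses fire every ``pulse_interval_s`` starting at t = pulse_interval_s.
    qL outside [0, 1] at a pulse time is a generation error; negative NPQ is
    permitted but flagged in the ground truth.  Noise (if any) is added to
    the assembled trace, never to the stored truth.
    """
    total = sum(d for d, _, _ in cfg.light_schedule)
    pulse_times = np.arange(cfg.pulse_interval_s, total - cfg.pulse_width_s, cfg.pulse_interval_s)
    if len(pulse_times) == 0:
        raise ValueError("schedule too short for a single pulse")
    if pulse_times[0] >= cfg.light_schedule[0][0]:
        raise ValueError("first pulse falls outside the dark segment; lengthen it")

    flags: list[str] = []
    fvfm = (cfg.Fm - cfg.F0) / cfg.Fm
    pulses: list[PulseTruth] = []
    for tp in pulse_times:
        npq_t = float(cfg.npq_course(tp))
        ql_t = float(cfg.ql_course(tp))
        if not 0.0 <= ql_t <= 1.0:
            raise ValueError(f"qL course value {ql_t} at t={tp} outside [0, 1]")
        if npq_t < 0:
            flags.append(f"negative NPQ at t={tp}")
        F, fmp, f0p = steady_fluorescence(cfg.F0, cfg.Fm, npq_t, ql_t)
        ppfd, label = _segment_at(cfg.light_schedule, tp)
        phi = (fmp - F) / fmp
        pulses.append(
            PulseTruth(
                time_s=float(tp),
                F=F,
                Fm_prime=fmp,
                F0_prime=f0p,
                npq=npq_t,
                ql=ql_t,
                phi_psii=phi,
                retr=DEFAULT_ABSORPTION_FACTOR * phi * ppfd,
                ppfd=ppfd,
                light_label=label,
            )
        )

    if abs(pulses[0].npq) > 1e-12 or pulses[0].ql < 1.0 - 1e-12:
        flags.append("dark reference pulse not fully relaxed (NPQ != 0 or qL != 1)")

    t = np.arange(0.0, total, cfg.sample_dt_s)
    fluor = np.empty_like(t)
    is_pulse = np.zeros(len(t), dtype=bool)
    # steady level: zero-order hold at the value of the next pulse onset
    next_idx = np.searchsorted(pulse_times, t, side="left")
    next_idx = np.minimum(next_idx, len(pulses) - 1)
    fluor[:] = [pulses[i].F for i in next_idx]
    for p in pulses:
        in_pulse = (t >= p.time_s) & (t < p.time_s + cfg.pulse_width_s)
        fluor[in_pulse] = p.Fm_prime
        is_pulse |= in_pulse
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        fluor = fluor + rng.normal(0.0, cfg.noise_sd, size=len(t))
    ppfd_ch = np.array([_segment_at(cfg.light_schedule, ti)[0] for ti in t])
    label_ch = np.array([_segment_at(cfg.light_schedule, ti)[1] for ti in t], dtype=object)
    trace = FluorescenceTrace(
        time_s=t, fluorescence=fluor, is_pulse=is_pulse, ppfd=ppfd_ch, light_label=label_ch
    )
    truth = TraceTruth(F0=cfg.F0, Fm=cfg.Fm, fv_fm=fvfm, pulses=pulses, seed=cfg.seed, flags=flags)
    return trace, truth
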