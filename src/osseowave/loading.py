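"""Boundary-condition protocols: shock wave pulse trains and physiological ramps.

Shock wave therapy is modelled by rigidly moving the copper applicator
plate along +X.  Within each pulse the plate velocity rises smoothly
(half-sine) during ``t_rise`` (default 0.01 us) to the peak value V, holds
for ``tau_hold`` (default 0.1 us), mirrors the ramp back down and stays at
zero until the next pulse; the train repeats every ``period`` (default
1 us) for ``n_pulses`` pulses (default 5).

The peak velocity V follows from the requested energy flux density (EFD)
through a plane-wave energy balance at the applicator face,

    V = sqrt(EFD / (Z * tau_eff)),   Z = rho_Cu * cp_Cu,

with tau_eff the effective pulse duration of the conversion (default: the
pulse period).  The delivered-EFD estimator ``Z * int(v^2) dt`` over one
period is corrected by the documented shape factor
``tau_eff / (tau_hold + t_rise)`` that accounts for the hold/ramp waveform.

Physiological loading moves the top boundary of the model down at a
constant velocity (default 0.1 m/s) until the reaction force reaches the
target (100 N rest, 200 N mastication), after which the set is held fixed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .materials import Material, derived_moduli

__all__ = [
    "ESWTProtocol",
    "PhysioProtocol",
    "acoustic_impedance",
    "efd_to_velocity",
    "applicator_waveform",
    "delivered_efd",
]

EFD_STUDY_RANGE = (0.01, 0.5)  # mJ/mm^2, intensity range studied

_MJ_PER_MM2 = 1e3  # 1 mJ/mm^2 = 1000 J/m^2


@dataclass(frozen=True)
class ESWTProtocol:
    """Shock wave pulse train.  EFD in mJ/mm^2; times in seconds."""

    efd: float                  # energy flux density, mJ/mm^2
    t_rise: float = 0.01e-6
    tau_hold: float = 0.1e-6
    period: float = 1e-6
    n_pulses: int = 5
    tau_eff: float | None = None  # defaults to the pulse period

    def __post_init__(self) -> None:
        if self.efd <= 0:
            raise ValueError("EFD must be positive")
        lo, hi = EFD_STUDY_RANGE
        if not lo <= self.efd <= hi:
            warnings.warn(
                f"EFD {self.efd} mJ/mm^2 outside the studied range "
                f"[{lo}, {hi}] mJ/mm^2",
                stacklevel=2,
            )
        if self.t_rise >= self.period:
            raise ValueError("rise time must be shorter than the pulse period")
        if self.n_pulses < 1:
            raise ValueError("need at least one pulse")

    @property
    def tau_eff_resolved(self) -> float:
        return self.period if self.tau_eff is None else self.tau_eff

    @property
    def duration(self) -> float:
        return self.n_pulses * self.period

    def peak_velocity(self, applicator: Material) -> float:
        return efd_to_velocity(self.efd, applicator, self.tau_eff_resolved)


@dataclass(frozen=True)
class PhysioProtocol:
    """Displacement-controlled physiological loading."""

    target_force: float          # N (100 rest | 200 mastication)
    ramp_velocity: float = 0.1   # m/s, downward
    max_displacement: float = 0.5e-3  # abort limit, m
    hold_duration: float = 0.0

    def __post_init__(self) -> None:
        if self.target_force <= 0:
            raise ValueError("target force must be positive")
        if self.ramp_velocity <= 0:
            raise ValueError("ramp velocity must be positive")


def acoustic_impedance(applicator: Material) -> float:
    """Plane-wave acoustic impedance Z = rho * cp of the applicator, Pa s/m."""
    dm = derived_moduli(applicator)
    return applicator.rho * dm.cp


def efd_to_velocity(efd: float, applicator: Material, tau_eff: float) -> float:
    """Peak applicator velocity from the energy flux density.

    ``efd`` in mJ/mm^2; plane-wave energy balance V = sqrt(EFD/(Z tau_eff)).
    """
    if efd <= 0:
        raise ValueError("EFD must be positive")
    Z = acoustic_impedance(applicator)
    return math.sqrt(efd * _MJ_PER_MM2 / (Z * tau_eff))


def applicator_waveform(t: np.ndarray | float, V: float, protocol: ESWTProtocol):
    """Prescribed applicator speed along +X at time(s) t.

    Half-sine ramp to V during t_rise, hold, mirrored ramp down, zero until
    the next period; n_pulses periods in total.
    """
    t = np.asarray(t, dtype=float)
    tp = np.where(t < protocol.duration, np.mod(t, protocol.period), np.inf)
    rise, hold = protocol.t_rise, protocol.tau_hold
    v = np.zeros_like(tp)
    up = tp < rise
    v[up] = V * np.sin(np.pi * tp[up] / (2.0 * rise))
    flat = (tp >= rise) & (tp < rise + hold)
    v[flat] = V
    down = (tp >= rise + hold) & (tp < 2 * rise + hold)
    v[down] = V * np.sin(np.pi * (2 * rise + hold - tp[down]) / (2.0 * rise))
    return v if v.ndim else float(v)


def delivered_efd(protocol: ESWTProtocol, applicator: Material, n_t: int = 20001) -> float:
    """Delivered EFD estimate, mJ/mm^2: Z int(v^2) dt with the shape correction.

    The raw plane-wave integral Z*int(v^2)dt over one period measures the
    energy of the actual hold/ramp waveform; multiplying by the documented
    shape factor tau_eff/(tau_hold + t_rise) refers it to the effective
    pulse duration used by the EFD -> velocity conversion.
    """
    V = protocol.peak_velocity(applicator)
    t = np.linspace(0.0, protocol.period, n_t)
    v = applicator_waveform(t, V, protocol)
    Z = acoustic_impedance(applicator)
    raw = Z * np.trapezoid(v**2, t)
    shape = protocol.tau_eff_resolved / (protocol.tau_hold + protocol.t_rise)
    return raw * shape / _MJ_PER_MM2
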