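"""Shared domain types and frequency conventions.

All internal spin physics is done in angular frequency (rad/s); chemical
shifts in ppm appear only at the interface.  Frequencies are expressed on
the chemical-shift scale with a positive Larmor frequency — the negative
gyromagnetic ratio of 15N is irrelevant because only relative offsets enter
the rotating-frame equations, and fitted shift differences are reported in
ppm on the usual shift axis.

The static field is configured as the 15N Larmor frequency in Hz rather
than in tesla, which avoids carrying a gyromagnetic-ratio constant.
Nominal values for 600 and 700 MHz (1H) instruments are provided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "TWO_PI",
    "N15_LARMOR_14T1_HZ",
    "N15_LARMOR_16T4_HZ",
    "DEFAULT_TEMPERATURE_K",
    "FieldContext",
    "ExchangeParams",
    "SpinExchangeModel",
    "SpinLockCondition",
    "ppm_to_angular",
    "angular_to_ppm",
    "state_offsets",
]

TWO_PI = 2.0 * math.pi

#: Nominal 15N Larmor frequency at 14.1 T (600 MHz 1H), Hz.
N15_LARMOR_14T1_HZ = 60.83e6
#: Nominal 15N Larmor frequency at 16.4 T (700 MHz 1H), Hz.
N15_LARMOR_16T4_HZ = 70.97e6
#: Default sample temperature, kelvin (10 degC).
DEFAULT_TEMPERATURE_K = 283.15


@dataclass(frozen=True)
class FieldContext:
    """Static-field context: 15N Larmor frequency (Hz) and temperature (K)."""

    nitrogen_larmor_hz: float = N15_LARMOR_14T1_HZ
    temperature_k: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not (self.nitrogen_larmor_hz > 0 and math.isfinite(self.nitrogen_larmor_hz)):
            raise ValueError(f"Larmor frequency must be positive, got {self.nitrogen_larmor_hz}")
        if not (self.temperature_k > 0 and math.isfinite(self.temperature_k)):
            raise ValueError(f"temperature must be positive, got {self.temperature_k}")


@dataclass(frozen=True)
class ExchangeParams:
    """Two-state exchange: minor-state population pB and total rate kex.

    kex = k1 + k-1 with forward rate k1 = pB*kex (major -> minor) and
    reverse rate k-1 = (1-pB)*kex; the identity k1 + k-1 = kex holds by
    construction.
    """

    p_minor: float
    k_ex: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_minor <= 0.5):
            raise ValueError(f"p_minor must be in [0, 0.5], got {self.p_minor}")
        # k_ex = 0 is admitted as the degenerate no-exchange limit
        if not (self.k_ex >= 0 and math.isfinite(self.k_ex)):
            raise ValueError(f"k_ex must be non-negative, got {self.k_ex}")

    @property
    def p_major(self) -> float:
        return 1.0 - self.p_minor

    @property
    def k_forward(self) -> float:
        """k1, major-to-minor rate, s^-1."""
        return self.p_minor * self.k_ex

    @property
    def k_reverse(self) -> float:
        """k-1, minor-to-major rate, s^-1."""
        return (1.0 - self.p_minor) * self.k_ex


@dataclass
class SpinExchangeModel:
    """One residue's spin parameters bound to a shared exchange process.

    delta_omega_ppm is the signed chemical-shift difference
    (minor minus major state) of the observed 15N nucleus.
    """

    residue_label: str
    r1: float
    r2: float
    ground_state_shift_ppm: float
    delta_omega_ppm: float
    exchange: ExchangeParams

    def __post_init__(self) -> None:
        if not (self.r1 > 0 and math.isfinite(self.r1)):
            raise ValueError(f"{self.residue_label}: R1 must be positive, got {self.r1}")
        if not math.isfinite(self.r2) or self.r2 <= 0:
            raise ValueError(f"{self.residue_label}: R2 must be positive, got {self.r2}")
        if self.r2 < self.r1:
            warnings.warn(
                f"{self.residue_label}: R2 ({self.r2}) < R1 ({self.r1}) is physically unusual",
                stacklevel=2,
            )
        if abs(self.delta_omega_ppm) > 20.0:
            raise ValueError(
                f"{self.residue_label}: |delta_omega| = {abs(self.delta_omega_ppm)} ppm "
                "exceeds the 20 ppm window"
            )


@dataclass(frozen=True)
class SpinLockCondition:
    """One spin-lock setting: power (omega_SL/2pi, Hz), carrier offset of the
    major-state resonance from the lock carrier (Omega/2pi, Hz, signed), and
    the relaxation-delay grid (s)."""

    spinlock_power_hz: float
    carrier_offset_hz: float
    duration_grid_s: tuple[float, ...] = field(default=(0.0,))

    def __post_init__(self) -> None:
        # power 0 is admitted as the degenerate free-precession limit
        if not (self.spinlock_power_hz >= 0 and math.isfinite(self.spinlock_power_hz)):
            raise ValueError(f"spin-lock power must be non-negative, got {self.spinlock_power_hz}")
        if not math.isfinite(self.carrier_offset_hz):
            raise ValueError("carrier offset must be finite")
        grid = tuple(float(t) for t in self.duration_grid_s)
        if len(grid) == 0 or grid[0] != 0.0:
            raise ValueError("duration grid must start at 0")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("duration grid must be strictly increasing")
        if any(t < 0 for t in grid):
            raise ValueError("delays must be non-negative")
        object.__setattr__(self, "duration_grid_s", grid)

    @property
    def is_on_resonance(self) -> bool:
        return self.carrier_offset_hz == 0.0


def ppm_to_angular(shift_ppm: float, fieldctx: FieldContext) -> float:
    """Convert a chemical shift in ppm to angular frequency in rad/s."""
    return shift_ppm * 1e-6 * TWO_PI * fieldctx.nitrogen_larmor_hz


def angular_to_ppm(omega_rad_s: float, fieldctx: FieldContext) -> float:
    """Inverse of :func:`ppm_to_angular`."""
    return omega_rad_s / (1e-6 * TWO_PI * fieldctx.nitrogen_larmor_hz)


def state_offsets(
    model: SpinExchangeModel, condition: SpinLockCondition, fieldctx: FieldContext
) -> tuple[float, float]:
    """Resonance offsets (rad/s) of the major and minor state from the lock carrier.

    The condition's carrier offset is defined relative to the major-state
    resonance, so Omega_GS = 2*pi*offset and Omega_ES = Omega_GS + dw.
    """
    omega_gs = TWO_PI * condition.carrier_offset_hz
    omega_es = omega_gs + ppm_to_angular(model.delta_omega_ppm, fieldctx)
    return omega_gs, omega_es
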