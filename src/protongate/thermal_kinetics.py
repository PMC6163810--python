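"""Closed-form thermodynamic and kinetic arithmetic.

Arrhenius Q10 ↔ activation-energy conversion, molar kBT unit conversion,
the thermal mode-cutoff frequency kB·T/h, vibrational degree-of-freedom
counting (3N−6 / 3N−5), and gating-cycle counting for a channel lifetime.

Conventions: "Q10 at T °C" refers to the decade [T−10 °C, T °C]; "room
temperature" defaults to 300 K; energy per mole uses the gas constant R, so
1 kBT ≙ R·T joules per mole.  Constants are CODATA via scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import constants as _const

__all__ = [
    "CONSTANTS",
    "PhysicalConstants",
    "ROOM_TEMPERATURE_K",
    "celsius_decade",
    "q10_from_ea",
    "ea_from_q10",
    "energy_in_kbt",
    "kbt_in_kj",
    "mode_cutoff_frequency",
    "vibrational_dof",
    "gating_cycle_count",
]

ROOM_TEMPERATURE_K = 300.0


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA constants used throughout (SI)."""

    R: float = _const.R                 # J mol^-1 K^-1
    k_B: float = _const.k               # J K^-1
    h: float = _const.h                 # J s
    e: float = _const.e                 # C
    N_A: float = _const.N_A             # mol^-1


CONSTANTS = PhysicalConstants()


def celsius_decade(t_celsius: float) -> tuple[float, float]:
    """The (T1, T2) kelvin pair for 'the decade ending at t_celsius °C'."""
    t2 = t_celsius + 273.15
    return t2 - 10.0, t2


def q10_from_ea(ea_kj_mol: float, t1: float, t2: float) -> float:
    """Arrhenius Q10 over [t1, t2] K implied by activation energy in kJ/mol.

    Q10 = exp[(Ea/R)(1/t1 − 1/t2)]; t1 < t2 required (a 10 K decade in the
    usual usage, though any ordered pair is accepted).
    """
    if not (0 < t1 < t2):
        raise ValueError(f"need 0 < t1 < t2, got t1={t1}, t2={t2}")
    return math.exp((ea_kj_mol * 1e3 / CONSTANTS.R) * (1.0 / t1 - 1.0 / t2))


def ea_from_q10(q10: float, t1: float, t2: float) -> float:
    """Activation energy (kJ/mol) implied by a Q10 over [t1, t2] K.

    Exact inverse of :func:`q10_from_ea`.
    """
    if q10 <= 0:
        raise ValueError(f"q10 must be > 0, got {q10}")
    if not (0 < t1 < t2):
        raise ValueError(f"need 0 < t1 < t2, got t1={t1}, t2={t2}")
    return CONSTANTS.R * math.log(q10) / (1.0 / t1 - 1.0 / t2) / 1e3


def energy_in_kbt(e_kj_mol: float, t: float = ROOM_TEMPERATURE_K) -> float:
    """Express a molar energy (kJ/mol) in thermal units kBT (= R·T per mole)."""
    if t <= 0:
        raise ValueError(f"temperature must be > 0, got {t}")
    return e_kj_mol * 1e3 / (CONSTANTS.R * t)


def kbt_in_kj(n_kbt: float, t: float = ROOM_TEMPERATURE_K) -> float:
    """Inverse of :func:`energy_in_kbt`: n kBT in kJ/mol at temperature t."""
    if t <= 0:
        raise ValueError(f"temperature must be > 0, got {t}")
    return n_kbt * CONSTANTS.R * t / 1e3


def mode_cutoff_frequency(t: float = ROOM_TEMPERATURE_K) -> float:
    """kB·T/h in Hz: vibrational modes near or below this frequency are
    thermally excited; substantially higher (local) modes are not."""
    if t <= 0:
        raise ValueError(f"temperature must be > 0, got {t}")
    return CONSTANTS.k_B * t / CONSTANTS.h


def vibrational_dof(n_atoms: int, linear: bool = False) -> int:
    """Vibrational degrees of freedom: 3N−6 (nonlinear) or 3N−5 (linear)."""
    if n_atoms < 2:
        raise ValueError(f"need at least 2 atoms, got {n_atoms}")
    return 3 * n_atoms - (5 if linear else 6)


def gating_cycle_count(
    firing_rate_hz: float, lifetime_s: float, n_domains: int = 1
) -> int:
    """Open/close events a channel must complete in its lifetime.

    rate × lifetime per channel, times ``n_domains`` for the total count of
    per-domain events (a tetrameric channel has four voltage sensors that
    must each reset correctly every cycle).
    """
    if firing_rate_hz < 0 or lifetime_s < 0 or n_domains < 0:
        raise ValueError("all arguments must be nonnegative")
    return round(firing_rate_hz * lifetime_s * n_domains)
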