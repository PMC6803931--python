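"""Physical constants (CODATA 2018) and the unit conventions used package-wide.

Molar convention
----------------
Thermal energies are carried in cal/mol throughout, so that the inverse
temperature variable ``beta = 1/(R*T)`` (mol/cal) multiplies the cal/mol
activation energies conventional in the empirical-kinetics literature.
Helpers are provided for J/mol, hartree and per-molecule conversions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhysicalConstants",
    "CONST",
    "beta_from_temperature",
    "temperature_from_beta",
    "wavenumber_to_kelvin",
    "wavenumber_to_cal_mol",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable CODATA-2018 constants; single source of truth for all modules."""

    kB: float = 1.380649e-23          # Boltzmann constant, J/K
    h: float = 6.62607015e-34         # Planck constant, J s
    N_A: float = 6.02214076e23        # Avogadro constant, 1/mol
    c_cm_s: float = 2.99792458e10     # speed of light, cm/s
    cal_to_J: float = 4.184           # thermochemical calorie
    amu_kg: float = 1.66053906660e-27  # atomic mass unit, kg
    hartree_J: float = 4.3597447222071e-18

    @property
    def hbar(self) -> float:
        return self.h / (2.0 * math.pi)

    @property
    def R_J(self) -> float:
        """Gas constant, J mol^-1 K^-1."""
        return self.kB * self.N_A

    @property
    def R_cal(self) -> float:
        """Gas constant, cal mol^-1 K^-1 (= 1.98720...)."""
        return self.R_J / self.cal_to_J

    @property
    def c2_cm_K(self) -> float:
        """Second radiation constant hc/kB in cm K; wavenumber -> temperature."""
        return self.h * self.c_cm_s / self.kB

    @property
    def kB_erg(self) -> float:
        """Boltzmann constant in erg/K for cgs (Stokes-Einstein) work."""
        return self.kB * 1.0e7

    @property
    def hartree_cal_mol(self) -> float:
        return self.hartree_J * self.N_A / self.cal_to_J


CONST = PhysicalConstants()


def beta_from_temperature(T):
    """beta = 1/(R*T) in mol/cal for temperatures in kelvin (scalar or array)."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0.0):
        raise ValueError("temperature must be strictly positive")
    return 1.0 / (CONST.R_cal * T)


def temperature_from_beta(beta):
    beta = np.asarray(beta, dtype=float)
    if np.any(beta <= 0.0):
        raise ValueError("beta must be strictly positive")
    return 1.0 / (CONST.R_cal * beta)


def wavenumber_to_kelvin(nu_cm1):
    """Vibrational temperature theta = c2 * nu for a wavenumber in cm^-1."""
    return CONST.c2_cm_K * np.asarray(nu_cm1, dtype=float)


def wavenumber_to_cal_mol(nu_cm1):
    """Molar photon energy h*c*nu*N_A of a wavenumber, in cal/mol."""
    return CONST.R_cal * CONST.c2_cm_K * np.asarray(nu_cm1, dtype=float)
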