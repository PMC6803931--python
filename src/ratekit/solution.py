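"""Solvent effects on rate constants: diffusion limits and friction.

Two classical formulations are provided:

* **Collins-Kimball** (bimolecular): the observed rate is the harmonic
  combination 1/k_obs = 1/k_TST + 1/k_D of the activated rate and the
  Smoluchowski diffusion-limited rate k_D = 4 pi r_AB D_AB, with
  Stokes-Einstein diffusion D_i = kB T / (6 pi eta r_i) and cage radii from
  the molar volumes, r_i = (3 V_i / 4 pi N_A)^(1/3).

* **Kramers** (unimolecular and pseudo-unimolecular): k_obs = kappa_Kr k_TST
  with the friction-dependent transmission

      kappa_Kr = (sqrt(mu^2/4 + omega^2) - mu/2) / omega,

  where omega = 2 pi c nu_dd is the magnitude of the transition state's
  imaginary angular frequency and the friction constant is the Stokes drag
  over the per-molecule mass, mu = 6 pi r_AB eta / (M/N_A), in s^-1 (the
  only dimensionally consistent reading; cgs units: r in cm, eta in Poise,
  mass in g).

Solvent viscosity follows a deformed-Arrhenius (super-Arrhenius) temperature
law, either in the direct form eta = eta0 (1 - T*/T)^p (water default:
eta0 = 2.7024e-4 Poise, T* = 213.0543 K, p = -2.75634) or in the generic
form eta = eta0 (1 - d eps/(R T))^(1/d) with eps in J/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import CONST
from .errors import DomainError, InputError

__all__ = [
    "SolventModel",
    "WATER",
    "DiffusionContext",
    "SolutionRateResult",
    "am_viscosity",
    "cage_radius_cm",
    "stokes_einstein_diffusion",
    "collins_kimball_rate",
    "kramers_rate",
]


@dataclass(frozen=True)
class SolventModel:
    """Viscosity-law parameters for one solvent.

    Exactly one parametrization is used: ``direct`` when ``T_star`` is set
    (eta = eta0 (1 - T*/T)^exponent) or the generic deformed form when
    ``eps_J_mol`` is set (eta = eta0 (1 - d eps/(R T))^(1/d)).
    """

    name: str
    eta0_poise: float
    T_star: float | None = None
    exponent: float | None = None
    eps_J_mol: float | None = None
    d_visc: float | None = None

    def __post_init__(self):
        if self.eta0_poise <= 0.0:
            raise InputError("eta0 must be positive")
        direct = self.T_star is not None
        generic = self.eps_J_mol is not None
        if direct == generic:
            raise InputError("set either (T_star, exponent) or (eps_J_mol, d_visc)")
        if direct and self.exponent is None:
            raise InputError("direct parametrization needs an exponent")
        if generic and self.d_visc is None:
            raise InputError("generic parametrization needs the deformation d_visc")


#: experimental-water parametrization of the deformed viscosity law
WATER = SolventModel("water", eta0_poise=2.7024e-4, T_star=213.0543, exponent=-2.75634)


def am_viscosity(solvent: SolventModel, T: float) -> float:
    """Solvent viscosity (Poise) at temperature T from the deformed law."""
    T = float(T)
    if T <= 0.0:
        raise DomainError("temperature must be strictly positive")
    if solvent.T_star is not None:
        base = 1.0 - solvent.T_star / T
        if base <= 0.0:
            raise DomainError(
                f"{solvent.name}: viscosity law valid only above T* = {solvent.T_star} K"
            )
        return solvent.eta0_poise * base ** solvent.exponent
    x = solvent.eps_J_mol / (CONST.R_J * T)
    d = solvent.d_visc
    if d == 0.0:
        return solvent.eta0_poise * math.exp(-x)
    base = 1.0 - d * x
    if base <= 0.0:
        raise DomainError(f"{solvent.name}: temperature outside the viscosity-law support")
    return solvent.eta0_poise * math.exp(math.log1p(-d * x) / d)


def cage_radius_cm(molar_volume_cm3: float) -> float:
    """Solvation-cage radius from a molar volume: r = (3V / 4 pi N_A)^(1/3)."""
    if molar_volume_cm3 <= 0.0:
        raise InputError("molar volume must be positive")
    return (3.0 * molar_volume_cm3 / (4.0 * math.pi * CONST.N_A)) ** (1.0 / 3.0)


def stokes_einstein_diffusion(radius_cm: float, eta_poise: float, T: float) -> float:
    """D = kB T / (6 pi eta r) in cm^2/s (cgs throughout)."""
    if radius_cm <= 0.0 or eta_poise <= 0.0 or T <= 0.0:
        raise InputError("radius, viscosity and temperature must be positive")
    return CONST.kB_erg * T / (6.0 * math.pi * eta_poise * radius_cm)


@dataclass(frozen=True)
class DiffusionContext:
    """Intermediate diffusion/friction quantities (cgs units)."""

    eta_poise: float
    r_A_cm: float | None = None
    r_B_cm: float | None = None
    r_AB_cm: float | None = None
    D_A_cm2_s: float | None = None
    D_B_cm2_s: float | None = None
    D_AB_cm2_s: float | None = None
    mu_s1: float | None = None
    omega_s1: float | None = None
    M_g_mol: float | None = None


@dataclass(frozen=True)
class SolutionRateResult:
    """Observed solution-phase rate with its ingredients.

    Collins-Kimball: ``k_obs <= min(k_tst, k_diff)`` always; Kramers:
    ``kappa_kr`` lies in (0, 1].  Units follow the molecularity: cm^3 mol^-1
    s^-1 for bimolecular Collins-Kimball input, the caller's k_tst units for
    Kramers.
    """

    k_tst: float
    k_obs: float
    units: str
    k_diff: float | None = None
    kappa_kr: float | None = None
    context: DiffusionContext | None = None


def collins_kimball_rate(
    k_tst_cm3_mol_s: float,
    volume_A_cm3_mol: float,
    volume_B_cm3_mol: float,
    solvent: SolventModel = WATER,
    T: float = 298.15,
) -> SolutionRateResult:
    """Diffusion-influenced bimolecular rate by the Collins-Kimball formula.

    ``k_tst_cm3_mol_s`` is the activated (TST, d-TST or tunneling-corrected)
    rate in cm^3 mol^-1 s^-1; the reactants' molar volumes give the cage
    radii.  Returns k_obs together with the Smoluchowski limit k_D and the
    diffusion coefficients.
    """
    if k_tst_cm3_mol_s <= 0.0:
        raise InputError("k_tst must be positive")
    eta = am_viscosity(solvent, T)
    r_A = cage_radius_cm(volume_A_cm3_mol)
    r_B = cage_radius_cm(volume_B_cm3_mol)
    D_A = stokes_einstein_diffusion(r_A, eta, T)
    D_B = stokes_einstein_diffusion(r_B, eta, T)
    D_AB = D_A + D_B
    r_AB = r_A + r_B
    k_diff = 4.0 * math.pi * r_AB * D_AB * CONST.N_A  # cm^3 mol^-1 s^-1
    k_obs = 1.0 / (1.0 / k_tst_cm3_mol_s + 1.0 / k_diff)
    return SolutionRateResult(
        k_tst=k_tst_cm3_mol_s,
        k_obs=k_obs,
        k_diff=k_diff,
        units="cm3 mol-1 s-1",
        context=DiffusionContext(
            eta_poise=eta,
            r_A_cm=r_A,
            r_B_cm=r_B,
            r_AB_cm=r_AB,
            D_A_cm2_s=D_A,
            D_B_cm2_s=D_B,
            D_AB_cm2_s=D_AB,
        ),
    )


def kramers_transmission(mu_s1: float, omega_s1: float) -> float:
    """kappa_Kr = (sqrt(mu^2/4 + omega^2) - mu/2)/omega, in (0, 1]."""
    if omega_s1 <= 0.0:
        raise InputError("omega must be positive")
    if mu_s1 < 0.0:
        raise InputError("friction constant must be non-negative")
    return (math.sqrt(0.25 * mu_s1 ** 2 + omega_s1 ** 2) - 0.5 * mu_s1) / omega_s1


def kramers_rate(
    k_tst: float,
    r_AB_cm: float,
    M_g_mol: float,
    nu_imag_cm1: float | None = None,
    omega_s1: float | None = None,
    solvent: SolventModel = WATER,
    T: float = 298.15,
    units: str = "s-1",
) -> SolutionRateResult:
    """Friction-damped rate k_obs = kappa_Kr k_TST (Kramers).

    ``r_AB_cm`` is the cage radius of the transition state (e.g. from its
    molar volume), ``M_g_mol`` its molar mass and either the imaginary-mode
    wavenumber or the angular frequency omega (s^-1) must be given.
    """
    if k_tst <= 0.0:
        raise InputError("k_tst must be positive")
    if M_g_mol <= 0.0 or r_AB_cm <= 0.0:
        raise InputError("cage radius and molar mass must be positive")
    if omega_s1 is None:
        if nu_imag_cm1 is None or nu_imag_cm1 <= 0.0:
            raise InputError("provide a positive nu_imag_cm1 or omega_s1")
        omega_s1 = 2.0 * math.pi * CONST.c_cm_s * nu_imag_cm1
    eta = am_viscosity(solvent, T)
    m_g = M_g_mol / CONST.N_A
    mu = 6.0 * math.pi * r_AB_cm * eta / m_g  # Stokes drag over mass, s^-1
    kappa = kramers_transmission(mu, omega_s1)
    return SolutionRateResult(
        k_tst=k_tst,
        k_obs=kappa * k_tst,
        kappa_kr=kappa,
        units=units,
        context=DiffusionContext(
            eta_poise=eta, r_AB_cm=r_AB_cm, mu_s1=mu, omega_s1=omega_s1, M_g_mol=M_g_mol
        ),
    )


def solvent_from_mapping(mapping: dict) -> SolventModel:
    """Build a SolventModel from a flat key-value mapping (see io module)."""
    data = {k: v for k, v in mapping.items()}
    name = data.pop("name", "solvent")
    try:
        return SolventModel(name=name, **{k: float(v) for k, v in data.items()})
    except TypeError as exc:
        raise InputError(f"unknown solvent parameter in {sorted(data)}") from exc
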