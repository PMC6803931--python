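"""Solvent effects on a bimolecular rate: diffusion limit vs friction.

Takes the toy bimolecular system's TST rate at 298.15 K in water (deformed
viscosity law), then applies the two solution-phase formulations: the
Collins-Kimball harmonic combination with the Smoluchowski diffusion limit
k_D = 4 pi r_AB D_AB N_A, and the Kramers friction damping kappa_Kr derived
from the Stokes drag on the transition state.
"""

from ratekit import (
    CONST,
    WATER,
    am_viscosity,
    cage_radius_cm,
    collins_kimball_rate,
    kramers_rate,
    tst_rate,
)
from ratekit.datasets import SystemTemplate, synth_reaction_system

system = synth_reaction_system(SystemTemplate.TOY_BIMOLECULAR)
T = 298.15
eta = am_viscosity(WATER, T)
k_tst = tst_rate(system, T) * CONST.N_A  # cm^3 mol^-1 s^-1
print(f"water viscosity at {T} K: {eta:.4e} Poise")
print(f"activated (TST) rate:    {k_tst:.4e} cm^3 mol^-1 s^-1")

ck = collins_kimball_rate(k_tst, *[r.molar_volume_cm3 for r in system.reactants], T=T)
print(f"\nCollins-Kimball: k_D = {ck.k_diff:.4e} cm^3 mol^-1 s^-1, "
      f"k_obs = {ck.k_obs:.4e}")
print(f"  diffusion coefficients D_A = {ck.context.D_A_cm2_s:.3e}, "
      f"D_B = {ck.context.D_B_cm2_s:.3e} cm^2/s")

kr = kramers_rate(k_tst, cage_radius_cm(system.ts.molar_volume_cm3),
                  system.ts.mass_amu, nu_imag_cm1=system.nu_imag_cm1, T=T,
                  units="cm3 mol-1 s-1")
print(f"\nKramers: friction mu = {kr.context.mu_s1:.3e} s^-1, "
      f"kappa_Kr = {kr.kappa_kr:.4f}, k_obs = {kr.k_obs:.4e}")
print("\n-> the reaction is far from diffusion control (k_tst << k_D), so both")
print("   formulations return k_obs close to the activated rate.")
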