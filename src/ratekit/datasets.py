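"""Deterministic synthetic-data generators and bundled benchmark parameters.

Everything here is a pure function of its spec (seed included): the same
SynthSpec always yields the identical series, so every other module is
testable without downloads.

``BENCHMARKS`` collects published fitted parameters for four well-studied
processes spanning the non-Arrhenius phenomenology — the deep-tunneling
keto-enol tautomerization of a methyl-benzoxazole (MeBO), the moderate-
tunneling OH + H2 abstraction, a super-Arrhenius enzymatic hydride transfer
(NAD+ reduction by the F147L mutant) and the anti-Arrhenius OH + HBr
reaction — together with realistic temperature windows.  Synthesizing
noise-free k(T) from these parameters and refitting is the package's
self-consistency benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import InputError
from .laws import RateLaw, RateLawParams, eval_rate_law
from .transitivity import RateSeries
from .tst import Geometry, ReactionSystem, Species

__all__ = [
    "SynthSpec",
    "synth_rate_series",
    "SystemTemplate",
    "synth_reaction_system",
    "synth_qc_log",
    "BENCHMARKS",
    "BENCHMARK_T_RANGES",
]


# ---------------------------------------------------------------------------
# benchmark parameter sets (energies cal/mol, temperatures K; A in the units
# of the source data for each process)

BENCHMARK_T_RANGES: dict[str, tuple[float, float]] = {
    "keto_enol": (100.0, 320.0),
    "oh_h2": (200.0, 1000.0),
    "enzymatic": (278.0, 338.0),   # 5-65 C
    "oh_hbr": (200.0, 420.0),
}

BENCHMARKS: dict[str, dict[RateLaw, RateLawParams]] = {
    "keto_enol": {
        RateLaw.ARRHENIUS: RateLawParams(RateLaw.ARRHENIUS, A=1.74e3, Ea=214.0),
        RateLaw.AM: RateLawParams(RateLaw.AM, A=3.32e6, eps_dd=318.06, d=-0.81),
        RateLaw.ASCC: RateLawParams(RateLaw.ASCC, A=2.33e4, eps_dd=2441.0, E_nu=429.0),
        RateLaw.NTS: RateLawParams(RateLaw.NTS, A=3.12e4, E0=1655.0, T0=168.0),
    },
    "oh_h2": {
        RateLaw.ARRHENIUS: RateLawParams(RateLaw.ARRHENIUS, A=2.16e-11, Ea=4891.0),
        RateLaw.AM: RateLawParams(RateLaw.AM, A=1.11e-10, eps_dd=9170.0, d=-0.086),
    },
    "enzymatic": {
        RateLaw.ARRHENIUS: RateLawParams(RateLaw.ARRHENIUS, A=1.52e11, Ea=14600.0),
        RateLaw.AM: RateLawParams(RateLaw.AM, A=1.91e4, eps_dd=2391.0, d=0.207),
        RateLaw.VFT: RateLawParams(RateLaw.VFT, A=1.25e5, B=-1298.0, T0=175.0),
    },
    "oh_hbr": {
        RateLaw.ARRHENIUS: RateLawParams(RateLaw.ARRHENIUS, A=1.66e-11, Ea=-94.6),
        RateLaw.AM: RateLawParams(RateLaw.AM, A=7.43e-14, eps_dd=-324.61, d=1.24),
    },
}


# ---------------------------------------------------------------------------
# synthetic rate tables

@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic rate table.

    ``noise_sigma`` is the log-standard-deviation of multiplicative lognormal
    noise (rates are positive and fits run in log space); 0 means noise-free.
    """

    params: RateLawParams
    T_min: float
    T_max: float
    n: int = 30
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.T_min < self.T_max):
            raise InputError("need 0 < T_min < T_max")
        if self.n < 2:
            raise InputError("need at least 2 points")
        if self.noise_sigma < 0.0:
            raise InputError("noise_sigma must be non-negative")


def synth_rate_series(spec: SynthSpec) -> RateSeries:
    """k(T) on a uniform grid from a rate law, with optional lognormal noise."""
    T = np.linspace(spec.T_min, spec.T_max, spec.n)
    k = eval_rate_law(spec.params, T)  # raises DomainError outside support
    if spec.noise_sigma > 0.0:
        rng = np.random.default_rng(spec.seed)
        k = k * np.exp(rng.normal(0.0, spec.noise_sigma, size=spec.n))
    return RateSeries(T=T, k=k, label=spec.params.law.value, units="arbitrary")


# ---------------------------------------------------------------------------
# toy reaction systems with hand-auditable partition functions

class SystemTemplate(str, Enum):
    TOY_UNIMOLECULAR = "toy_unimolecular"
    TOY_BIMOLECULAR = "toy_bimolecular"
    DEEP_TUNNEL = "deep_tunnel"


def synth_reaction_system(template: SystemTemplate | str) -> ReactionSystem:
    """Small closed-form systems (2-4 atoms, energies in cal/mol).

    ``TOY_UNIMOLECULAR`` has a transition state identical to its reactant
    except for a 5000 cal/mol energy offset, so the partition-function ratio
    is exactly 1 and k_TST = (kB T/h) exp(-eps/RT) by hand.  ``DEEP_TUNNEL``
    carries a 1500 cm^-1 imaginary mode, putting its crossover temperature
    near 687 K (deep tunneling at room temperature).
    """
    template = SystemTemplate(template)
    if template in (SystemTemplate.TOY_UNIMOLECULAR, SystemTemplate.DEEP_TUNNEL):
        reactant = Species(
            name="toy-reactant",
            mass_amu=28.0,
            geometry=Geometry.LINEAR,
            rotational_constants_cm1=(2.0,),
            frequencies_cm1=(500.0, 1500.0),
            electronic_energy=0.0,
            energy_unit="cal/mol",
        )
        ts = Species(
            name="toy-ts",
            mass_amu=28.0,
            geometry=Geometry.LINEAR,
            rotational_constants_cm1=(2.0,),
            frequencies_cm1=(500.0, 1500.0),
            electronic_energy=5000.0,
            energy_unit="cal/mol",
            molar_volume_cm3=35.0,
        )
        nu = 800.0 if template is SystemTemplate.TOY_UNIMOLECULAR else 1500.0
        return ReactionSystem(reactants=(reactant,), ts=ts, nu_imag_cm1=nu)

    atom = Species(
        name="toy-H",
        mass_amu=1.008,
        geometry=Geometry.ATOM,
        electronic_energy=0.0,
        energy_unit="cal/mol",
        degeneracy=2,
        molar_volume_cm3=8.0,
    )
    diatom = Species(
        name="toy-HX",
        mass_amu=36.46,
        geometry=Geometry.LINEAR,
        rotational_constants_cm1=(10.59,),
        frequencies_cm1=(2990.0,),
        electronic_energy=0.0,
        energy_unit="cal/mol",
        molar_volume_cm3=25.0,
    )
    ts = Species(
        name="toy-HXH",
        mass_amu=37.47,
        geometry=Geometry.LINEAR,
        rotational_constants_cm1=(3.0,),
        frequencies_cm1=(1500.0, 700.0, 700.0),
        electronic_energy=4000.0,
        energy_unit="cal/mol",
        degeneracy=2,
        molar_volume_cm3=33.0,
    )
    # product keeps the diatom's stretch so the ZPE-corrected reaction
    # enthalpy equals the electronic energy difference exactly (-5000)
    product = Species(
        name="toy-products",
        mass_amu=37.47,
        geometry=Geometry.LINEAR,
        rotational_constants_cm1=(5.0,),
        frequencies_cm1=(2990.0,),
        electronic_energy=-5000.0,
        energy_unit="cal/mol",
    )
    return ReactionSystem(
        reactants=(atom, diatom),
        ts=ts,
        products=(product,),
        nu_imag_cm1=1200.0,
        dH_cal_mol=-5000.0,
    )


# ---------------------------------------------------------------------------
# fabricated electronic-structure logs (the dialect the io module reads)

_GHZ_PER_CM1 = 29.9792458


def synth_qc_log(species: Species) -> str:
    """Minimal Gaussian-style frequency log for a Species.

    Contains exactly the blocks the log reader consumes (multiplicity,
    final energy, rotational constants in GHz, frequency lines with
    imaginary modes as negative entries, molecular mass, molar volume), so
    ``load_species(synth_qc_log(s))`` round-trips ``s``.
    """
    lines = [
        " Entering Gaussian System, fabricated log (ratekit synthetic fixture)",
        f" Charge =  0 Multiplicity = {species.degeneracy}",
    ]
    if species.electronic_energy is not None:
        if species.energy_unit.lower() != "hartree":
            raise InputError("synthetic logs carry energies in hartree")
        lines.append(
            f" SCF Done:  E(RMP2) = {species.electronic_energy:.12g}     A.U. after   10 cycles"
        )
    if species.geometry is not Geometry.ATOM:
        b = species.rotational_constants_cm1
        ghz = [x * _GHZ_PER_CM1 for x in b]
        if species.geometry is Geometry.LINEAR:
            ghz = [0.0, ghz[0], ghz[0]]
        lines.append(
            " Rotational constants (GHZ):"
            + "".join(f" {g:17.10f}" for g in ghz)
        )
        lines.append(f" Rotational symmetry number  {species.sigma}.")
        freqs = [-abs(f) for f in species.imaginary_cm1] + list(species.frequencies_cm1)
        for i in range(0, len(freqs), 3):
            chunk = freqs[i : i + 3]
            lines.append(" Frequencies --" + "".join(f" {f:12.4f}" for f in chunk))
    lines.append(f" Molecular mass: {species.mass_amu:12.5f} amu.")
    if species.molar_volume_cm3 is not None:
        bohr3 = species.molar_volume_cm3 / 0.14818471147  # cm^3 per bohr^3*N_A, cosmetic
        lines.append(
            f" Molar volume = {bohr3:10.3f} bohr**3/mol ({species.molar_volume_cm3:10.4f} cm**3/mol)"
        )
    lines.append(f" Stoichiometry    {species.name}")
    lines.append(" Normal termination of Gaussian (fabricated).")
    return "\n".join(lines) + "\n"
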