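"""Gas-phase rate constants from molecular descriptors.

Conventional transition-state theory in the rigid-rotor / harmonic-oscillator
/ ideal-gas factorization,

    k_TST(T) = (kB T / h) * (Q_ts / prod Q_reactants) * exp(-eps / R T),

where ``eps`` is the barrier height in cal/mol (transition-state energy minus
reactant energies, by default including the zero-point correction), plus the
deformed variant (d-TST)

    k_d(T) = (kB T / h) * (Q_ts / prod Q) * (1 - d eps / R T)^(1/d),
    d = -(1/3) (h nu_dd / 2 eps)^2,

in which the imaginary-mode magnitude nu_dd deforms the exponential barrier
factor to account uniformly for tunneling up to the moderate regime, and
three one-dimensional multiplicative tunneling corrections (Bell 1935, Bell
1958 truncated at one or two terms, Skodje-Truhlar).

Conventions
-----------
* Wherever the tunneling formulas involve the reduced quantum ``hbar nu``,
  it is taken literally as ``h nu / 2 pi``.
* The crossover temperature is ``Tc = h nu_dd / (pi kB)``; tunneling regimes
  are the four windows negligible (T >= 2 Tc), small (Tc <= T < 2 Tc),
  moderate (Tc/2 <= T < Tc) and deep (T < Tc/2).
* Symmetry numbers and electronic degeneracies are explicit Species fields
  (defaults 1), never inferred from geometry.
* Bimolecular rates are computed per molecule (cm^3 molecule^-1 s^-1); the
  molar value is N_A times that.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .constants import CONST
from .errors import DivergenceError, DomainError, InputError

__all__ = [
    "Geometry",
    "Species",
    "ReactionSystem",
    "PartitionSet",
    "Tunneling",
    "TunnelingContext",
    "Regime",
    "partition_functions",
    "tst_rate",
    "dtst_rate",
    "tunneling_kappa",
    "crossover_temperature",
    "crossover_and_regime",
    "corrected_rate",
]

_R = CONST.R_cal
_C2 = CONST.c2_cm_K


class Geometry(str, Enum):
    ATOM = "atom"
    LINEAR = "linear"
    NONLINEAR = "nonlinear"


@dataclass(frozen=True)
class Species:
    """One stationary point: masses, rotations, real vibrations, energy.

    ``rotational_constants_cm1`` holds one constant for a linear rotor and
    three for a nonlinear one; ``frequencies_cm1`` lists the *real* modes
    only (any imaginary-mode magnitudes extracted from an electronic-
    structure log are kept separately in ``imaginary_cm1``).  Energies may be
    declared in hartree, J/mol or cal/mol via ``energy_unit``.
    """

    name: str
    mass_amu: float
    geometry: Geometry
    rotational_constants_cm1: tuple[float, ...] | None = None
    sigma: int = 1
    frequencies_cm1: tuple[float, ...] = ()
    electronic_energy: float | None = None
    energy_unit: str = "hartree"
    degeneracy: int = 1
    molar_volume_cm3: float | None = None
    imaginary_cm1: tuple[float, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "geometry", Geometry(self.geometry))
        object.__setattr__(self, "frequencies_cm1", tuple(float(f) for f in self.frequencies_cm1))
        object.__setattr__(self, "imaginary_cm1", tuple(float(f) for f in self.imaginary_cm1))
        if self.rotational_constants_cm1 is not None:
            object.__setattr__(
                self,
                "rotational_constants_cm1",
                tuple(float(b) for b in self.rotational_constants_cm1),
            )
        if self.mass_amu <= 0.0:
            raise InputError(f"{self.name}: mass must be positive")
        if self.sigma < 1:
            raise InputError(f"{self.name}: symmetry number must be >= 1")
        if self.degeneracy < 1:
            raise InputError(f"{self.name}: electronic degeneracy must be >= 1")
        if any(f <= 0.0 for f in self.frequencies_cm1):
            raise InputError(f"{self.name}: real frequencies must be positive")
        geom = self.geometry
        if geom is Geometry.ATOM:
            if self.frequencies_cm1 or self.rotational_constants_cm1:
                raise InputError(f"{self.name}: an atom has no rotations or vibrations")
        else:
            n_rot = 1 if geom is Geometry.LINEAR else 3
            if (
                self.rotational_constants_cm1 is None
                or len(self.rotational_constants_cm1) != n_rot
                or any(b <= 0.0 for b in self.rotational_constants_cm1)
            ):
                raise InputError(
                    f"{self.name}: a {geom.value} rotor needs {n_rot} positive "
                    "rotational constant(s) in cm^-1"
                )

    @classmethod
    def from_moments(cls, *, moments_amu_A2, **kwargs) -> "Species":
        """Build from principal moments of inertia (amu A^2) instead of constants."""
        I_SI = np.asarray(moments_amu_A2, dtype=float) * CONST.amu_kg * 1e-20
        b = CONST.h / (8.0 * math.pi ** 2 * CONST.c_cm_s * I_SI)
        return cls(rotational_constants_cm1=tuple(b), **kwargs)

    def zpe_cal_mol(self) -> float:
        """Harmonic zero-point energy sum(h c nu / 2) N_A, cal/mol."""
        return 0.5 * _R * _C2 * sum(self.frequencies_cm1)

    def energy_cal_mol(self, override: float | None = None) -> float:
        """Electronic energy in cal/mol; ``override`` replaces the stored value
        (interpreted in this species' declared unit)."""
        value = override if override is not None else self.electronic_energy
        if value is None:
            raise InputError(f"{self.name}: electronic energy not set")
        unit = self.energy_unit.lower()
        if unit == "hartree":
            return value * CONST.hartree_cal_mol
        if unit in ("j/mol", "j_mol"):
            return value / CONST.cal_to_J
        if unit in ("cal/mol", "cal_mol"):
            return float(value)
        raise InputError(f"{self.name}: unknown energy unit {self.energy_unit!r}")


@dataclass(frozen=True)
class PartitionSet:
    """Per-stationary-point partition functions at one temperature.

    ``q_trans_per_volume`` is in m^-3; the others are dimensionless and
    strictly positive (``q_vib >= 1`` under the ZPE-referenced convention).
    """

    q_trans_per_volume: float
    q_rot: float
    q_vib: float
    g_elec: float

    def total_per_volume(self) -> float:
        return self.q_trans_per_volume * self.q_rot * self.q_vib * self.g_elec


def partition_functions(species: Species, T: float) -> PartitionSet:
    """Rigid-rotor / harmonic-oscillator / ideal-gas partition functions.

    q_trans/V = (2 pi m kB T / h^2)^(3/2); q_rot = 1 (atom), T/(sigma theta)
    (linear), (sqrt(pi)/sigma) sqrt(T^3/(thetaA thetaB thetaC)) (nonlinear);
    q_vib = prod 1/(1 - exp(-theta_i/T)) referenced to the ZPE level.
    """
    T = float(T)
    if T <= 0.0:
        raise DomainError("temperature must be strictly positive")
    m = species.mass_amu * CONST.amu_kg
    q_trans = (2.0 * math.pi * m * CONST.kB * T / CONST.h ** 2) ** 1.5

    geom = species.geometry
    if geom is Geometry.ATOM:
        q_rot = 1.0
    elif geom is Geometry.LINEAR:
        theta = _C2 * species.rotational_constants_cm1[0]
        q_rot = T / (species.sigma * theta)
    else:
        thetas = _C2 * np.asarray(species.rotational_constants_cm1)
        q_rot = math.sqrt(math.pi) / species.sigma * math.sqrt(T ** 3 / np.prod(thetas))

    q_vib = 1.0
    for nu in species.frequencies_cm1:
        q_vib /= 1.0 - math.exp(-_C2 * nu / T)

    return PartitionSet(
        q_trans_per_volume=q_trans, q_rot=q_rot, q_vib=q_vib, g_elec=float(species.degeneracy)
    )


@dataclass(frozen=True)
class ReactionSystem:
    """Reactants, transition state and (optionally) products of one step.

    ``nu_imag_cm1`` is the positive magnitude of the transition state's
    imaginary mode; ``dH_cal_mol`` is the reaction enthalpy required by the
    Skodje-Truhlar correction; ``energy_override`` maps species names to
    high-level electronic energies (in each species' own energy unit) that
    replace the stored ones.
    """

    reactants: tuple[Species, ...]
    ts: Species
    nu_imag_cm1: float
    products: tuple[Species, ...] | None = None
    dH_cal_mol: float | None = None
    energy_override: dict[str, float] | None = None

    def __post_init__(self):
        object.__setattr__(self, "reactants", tuple(self.reactants))
        if self.products is not None:
            object.__setattr__(self, "products", tuple(self.products))
        if len(self.reactants) not in (1, 2):
            raise InputError("molecularity must be 1 or 2")
        if self.nu_imag_cm1 <= 0.0:
            raise InputError("imaginary-mode magnitude nu_imag_cm1 must be positive")

    @property
    def molecularity(self) -> int:
        return len(self.reactants)

    def _energy(self, sp: Species) -> float:
        override = (self.energy_override or {}).get(sp.name)
        return sp.energy_cal_mol(override)

    def barrier_cal_mol(self, zpe_corrected: bool = True) -> float:
        """eps = E(TS) - sum E(reactants), optionally with the ZPE difference."""
        eps = self._energy(self.ts) - sum(self._energy(r) for r in self.reactants)
        if zpe_corrected:
            eps += self.ts.zpe_cal_mol() - sum(r.zpe_cal_mol() for r in self.reactants)
        return eps

    def reaction_enthalpy_cal_mol(self, zpe_corrected: bool = True) -> float:
        """0 K reaction enthalpy from the species energies (products required)."""
        if not self.products:
            raise InputError("reaction enthalpy needs product species")
        dh = sum(self._energy(p) for p in self.products) - sum(
            self._energy(r) for r in self.reactants
        )
        if zpe_corrected:
            dh += sum(p.zpe_cal_mol() for p in self.products) - sum(
                r.zpe_cal_mol() for r in self.reactants
            )
        return dh


class Tunneling(str, Enum):
    NONE = "none"
    DTST = "dtst"
    BELL35 = "bell35"
    BELL58_1T = "bell58"
    BELL58_2T = "bell58-2t"
    ST = "st"


class Regime(str, Enum):
    NEGLIGIBLE = "negligible"
    SMALL = "small"
    MODERATE = "moderate"
    DEEP = "deep"


@dataclass(frozen=True)
class TunnelingContext:
    """Derived tunneling quantities for one system.

    ``Tc = h nu_dd / (pi kB)`` exactly; ``c_beta`` is the paper-of-record
    inverse molar energy 1/(R Tc) = pi/(h nu_dd); ``d`` is the (non-positive)
    d-TST deformation when a positive barrier is available.
    """

    method: Tunneling
    Tc: float
    c_beta: float
    d: float | None = None


def crossover_temperature(nu_imag_cm1: float) -> float:
    """Tc = h c nu / (pi kB) = c2 nu / pi in kelvin."""
    if nu_imag_cm1 <= 0.0:
        raise InputError("nu_imag_cm1 must be positive")
    return _C2 * nu_imag_cm1 / math.pi


def crossover_and_regime(nu_imag_cm1: float, T: float) -> tuple[float, Regime]:
    """Crossover temperature and the tunneling-regime window containing T.

    Window boundaries are assigned to the milder-tunneling side, so the four
    windows partition the whole positive temperature axis exactly.
    """
    Tc = crossover_temperature(nu_imag_cm1)
    if T >= 2.0 * Tc:
        return Tc, Regime.NEGLIGIBLE
    if T >= Tc:
        return Tc, Regime.SMALL
    if T >= 0.5 * Tc:
        return Tc, Regime.MODERATE
    return Tc, Regime.DEEP


def _q_ratio(system: ReactionSystem, T: float) -> float:
    """Q_ts / prod Q_reactants; m^3 per molecule for bimolecular systems."""
    q_ts = partition_functions(system.ts, T).total_per_volume()
    q_r = 1.0
    for r in system.reactants:
        q_r *= partition_functions(r, T).total_per_volume()
    return q_ts / q_r


def _scalar_or_array(func, T):
    T_arr = np.asarray(T, dtype=float)
    if T_arr.ndim == 0:
        return func(float(T_arr))
    return np.array([func(float(t)) for t in T_arr])


def tst_rate(system: ReactionSystem, T, zpe_corrected: bool = True):
    """Conventional TST rate constant.

    Unimolecular: s^-1.  Bimolecular: cm^3 molecule^-1 s^-1 (multiply by
    N_A for cm^3 mol^-1 s^-1).
    """

    def one(t: float) -> float:
        if t <= 0.0:
            raise DomainError("temperature must be strictly positive")
        eps = system.barrier_cal_mol(zpe_corrected)
        k = CONST.kB * t / CONST.h * _q_ratio(system, t) * math.exp(-eps / (_R * t))
        if system.molecularity == 2:
            k *= 1.0e6  # m^3 -> cm^3 per molecule
        return k

    return _scalar_or_array(one, T)


def dtst_d(system: ReactionSystem, zpe_corrected: bool = True) -> float:
    """d-TST deformation d = -(1/3) (h nu_dd / 2 eps)^2 (<= 0)."""
    eps = system.barrier_cal_mol(zpe_corrected)
    if eps <= 0.0:
        raise DomainError("d-TST requires a positive barrier")
    hnu = _R * _C2 * system.nu_imag_cm1  # molar h*nu in cal/mol
    return -((hnu / (2.0 * eps)) ** 2) / 3.0


def dtst_rate(system: ReactionSystem, T, zpe_corrected: bool = True):
    """Deformed-TST rate constant and the deformation d.

    Replaces the exponential barrier factor with the deformed exponential
    (1 - d eps/(R T))^(1/d); recovers plain TST as nu_imag -> 0.
    """
    eps = system.barrier_cal_mol(zpe_corrected)
    d = dtst_d(system, zpe_corrected)

    def one(t: float) -> float:
        if t <= 0.0:
            raise DomainError("temperature must be strictly positive")
        x = eps / (_R * t)
        # d < 0 always, so the base 1 - d*x > 0 for positive barriers
        deformed = math.exp(math.log1p(-d * x) / d) if d != 0.0 else math.exp(-x)
        k = CONST.kB * t / CONST.h * _q_ratio(system, t) * deformed
        if system.molecularity == 2:
            k *= 1.0e6
        return k

    return _scalar_or_array(one, T), d


def _st_high_T(u: float, hbar_nu: float, RT: float, E: float) -> float:
    """Skodje-Truhlar branch for beta <= c (T >= Tc)."""
    return u / math.sin(u) - math.exp((1.0 / RT - 1.0 / hbar_nu) * E) / (RT / hbar_nu - 1.0)


def _st_low_T(hbar_nu: float, RT: float, E: float) -> float:
    """Skodje-Truhlar branch for beta >= c (T <= Tc).

    Standard 1981 sign convention kappa = [exp((1/kBT - 1/hbar nu)(eps - dH))
    - 1] / (1 - kBT/hbar nu), positive on the whole branch; the removable
    0/0 point at kBT = hbar nu (T = Tc/2) is evaluated by its analytic limit
    E/(kB T).
    """
    delta = 1.0 / RT - 1.0 / hbar_nu
    if abs(delta * hbar_nu) < 1e-10:
        return E / RT
    return math.expm1(delta * E) / (RT * delta)


def tunneling_kappa(
    method: Tunneling | str,
    nu_imag_cm1: float,
    eps_cal_mol: float,
    T: float,
    dH_cal_mol: float | None = None,
) -> float:
    """One-dimensional tunneling transmission coefficient kappa >= 0.

    ``eps_cal_mol`` is the (positive) barrier and ``dH_cal_mol`` the reaction
    enthalpy (required by ST; 0 is allowed).  Bell58 formulas have a genuine
    pole at T = Tc/2 = h nu / (2 pi kB); evaluation is refused nearby with a
    :class:`~ratekit.errors.DivergenceError` naming Tc.
    """
    method = Tunneling(method)
    if method is Tunneling.NONE:
        return 1.0
    if nu_imag_cm1 <= 0.0 or eps_cal_mol <= 0.0:
        raise InputError("tunneling corrections need nu_imag_cm1 > 0 and a positive barrier")
    if T <= 0.0:
        raise DomainError("temperature must be strictly positive")

    hnu = _R * _C2 * nu_imag_cm1       # molar h*nu, cal/mol
    hbar_nu = hnu / (2.0 * math.pi)    # molar hbar*nu, cal/mol
    RT = _R * T
    Tc = crossover_temperature(nu_imag_cm1)
    eps = float(eps_cal_mol)

    if method is Tunneling.BELL35:
        delta = 1.0 / hbar_nu - 1.0 / RT
        if abs(delta * hbar_nu) < 1e-8:
            return 1.0 + eps / hbar_nu  # analytic limit of the 0/0 point at T = Tc/2
        num = 1.0 / hbar_nu - math.exp(eps / RT - eps / hbar_nu) / RT
        return num / delta

    u = hnu / (2.0 * RT)
    if method in (Tunneling.BELL58_1T, Tunneling.BELL58_2T):
        if u >= math.pi - 1e-3:
            raise DivergenceError(
                f"Bell-1958 correction diverges at T = Tc/2 = {0.5 * Tc:.2f} K "
                f"(crossover temperature Tc = {Tc:.2f} K); requested T = {T:.2f} K"
            )
        kappa = u / math.sin(u)
        if method is Tunneling.BELL58_2T:
            kappa -= math.exp(eps / RT - eps / hbar_nu) / (RT / hbar_nu - 1.0)
        return kappa

    if method is Tunneling.ST:
        if dH_cal_mol is None:
            raise InputError("the Skodje-Truhlar correction requires the reaction enthalpy dH")
        E = eps - float(dH_cal_mol)
        c_beta = math.pi / hnu
        beta = 1.0 / RT
        if beta <= c_beta:  # T >= Tc
            return _st_high_T(u, hbar_nu, RT, E)
        return _st_low_T(hbar_nu, RT, E)

    raise InputError(f"unknown tunneling method {method!r}")


def corrected_rate(
    system: ReactionSystem,
    T,
    method: Tunneling | str = Tunneling.NONE,
    zpe_corrected: bool = True,
):
    """kappa(method) * k_TST; d-TST for method='dtst'; plain TST for 'none'."""
    method = Tunneling(method)
    if method is Tunneling.NONE:
        return tst_rate(system, T, zpe_corrected)
    if method is Tunneling.DTST:
        return dtst_rate(system, T, zpe_corrected)[0]
    eps = system.barrier_cal_mol(zpe_corrected)
    dH = system.dH_cal_mol
    if method is Tunneling.ST and dH is None and system.products:
        dH = system.reaction_enthalpy_cal_mol(zpe_corrected)

    def one(t: float) -> float:
        kappa = tunneling_kappa(method, system.nu_imag_cm1, eps, t, dH)
        return kappa * tst_rate(system, t, zpe_corrected)

    return _scalar_or_array(one, T)


def tunneling_context(
    system: ReactionSystem, method: Tunneling | str = Tunneling.NONE
) -> TunnelingContext:
    """Assemble the derived tunneling quantities for reporting."""
    method = Tunneling(method)
    Tc = crossover_temperature(system.nu_imag_cm1)
    hnu = _R * _C2 * system.nu_imag_cm1
    d = None
    try:
        d = dtst_d(system)
    except (DomainError, InputError):
        pass
    return TunnelingContext(method=method, Tc=Tc, c_beta=math.pi / hnu, d=d)


def check_enthalpy_consistency(
    system: ReactionSystem, tol_cal_mol: float = 100.0
) -> float:
    """Mismatch between the user-supplied dH and the one from species energies.

    Returns the difference (cal/mol) and warns when it exceeds ``tol_cal_mol``;
    requires both the dH field and product species.
    """
    if system.dH_cal_mol is None or not system.products:
        raise InputError("needs both a dH value and product species")
    diff = system.dH_cal_mol - system.reaction_enthalpy_cal_mol()
    if abs(diff) > tol_cal_mol:
        warnings.warn(
            f"supplied dH differs from species-energy value by {diff:.1f} cal/mol",
            stacklevel=2,
        )
    return diff
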