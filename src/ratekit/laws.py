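"""Phenomenological rate laws, their apparent activation energies and
transitivity functions.

Five empirical k(T) laws cover the phenomenology of curved Arrhenius plots:

==========  =============================================  =====================
law         k(T)                                           behaviour captured
==========  =============================================  =====================
ARRHENIUS   A exp(-Ea beta)                                straight Arrhenius plot
AM          A (1 - d eps beta)^(1/d)                       sub (d<0) / super (d>0)
ASCC        A (1 - d eps/(RT + E_nu))^(1/d),
            d = -(1/3) (E_nu / 2 eps)^2                    deep tunneling
NTS         A exp(-E0 / (R sqrt(T^2 + T0^2)))              deep tunneling
VFT         A exp(B / (T - T0))                            super-Arrhenius/glassy
==========  =============================================  =====================

with ``beta = 1/(R T)`` and all energies molar in cal/mol (temperatures in K,
``B`` and ``T0`` in K).  ``A`` carries the units of the source data opaquely.

The *apparent activation energy* is the local Arrhenius-plot slope
``Ea(beta) = -d ln k/d beta`` and the *transitivity function* is its
reciprocal ``gamma(beta) = 1/Ea(beta)``.  For the AM law gamma is exactly
affine, ``gamma = 1/eps - d beta``: plotting gamma against beta linearizes
deformed-Arrhenius data.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import Enum
from typing import Mapping

import numpy as np

from .constants import CONST, beta_from_temperature
from .errors import DomainError, InputError, SingularTransitivityError

__all__ = [
    "RateLaw",
    "RateLawParams",
    "BetaGrid",
    "LAW_PARAM_NAMES",
    "eval_rate_law",
    "apparent_ea_closed",
    "gamma_closed",
    "ascc_d",
    "params_to_dict",
    "params_from_dict",
]

_R = CONST.R_cal


class RateLaw(str, Enum):
    ARRHENIUS = "arrhenius"
    AM = "am"
    ASCC = "ascc"
    NTS = "nts"
    VFT = "vft"


#: free parameters of each law (ASCC's deformation d is always derived).
LAW_PARAM_NAMES: dict[RateLaw, tuple[str, ...]] = {
    RateLaw.ARRHENIUS: ("A", "Ea"),
    RateLaw.AM: ("A", "eps_dd", "d"),
    RateLaw.ASCC: ("A", "eps_dd", "E_nu"),
    RateLaw.NTS: ("A", "E0", "T0"),
    RateLaw.VFT: ("A", "B", "T0"),
}

_ALL_PARAM_NAMES = ("A", "Ea", "eps_dd", "d", "E_nu", "E0", "T0", "B")


@dataclass(frozen=True)
class RateLawParams:
    """Parameter record for one rate law.

    Only the fields belonging to ``law`` may be set; energies are molar in
    cal/mol, ``T0``/``B`` in kelvin.  Temperature support is validated at
    evaluation time, not here.
    """

    law: RateLaw
    A: float
    Ea: float | None = None
    eps_dd: float | None = None
    d: float | None = None
    E_nu: float | None = None
    E0: float | None = None
    T0: float | None = None
    B: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "law", RateLaw(self.law))
        needed = LAW_PARAM_NAMES[self.law]
        for name in _ALL_PARAM_NAMES:
            value = getattr(self, name)
            if name in needed:
                if value is None:
                    raise InputError(f"{self.law.value} law requires parameter {name!r}")
                object.__setattr__(self, name, float(value))
            elif value is not None:
                raise InputError(
                    f"parameter {name!r} does not belong to the {self.law.value} law"
                )
        if self.A <= 0.0:
            raise InputError("pre-exponential factor A must be positive")

    def free_values(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in LAW_PARAM_NAMES[self.law])


@dataclass(frozen=True)
class BetaGrid:
    """Aligned (T, beta) grids with beta = 1/(R T) in mol/cal."""

    T: np.ndarray
    beta: np.ndarray

    @classmethod
    def from_temperatures(cls, T) -> "BetaGrid":
        T = np.atleast_1d(np.asarray(T, dtype=float))
        if T.size and np.any(np.diff(T) <= 0.0):
            raise InputError("temperature grid must be strictly increasing")
        return cls(T=T, beta=np.asarray(beta_from_temperature(T)))

    def __post_init__(self):
        if len(self.T) != len(self.beta):
            raise InputError("T and beta grids must be aligned")


def ascc_d(eps_dd: float, E_nu: float) -> float:
    """Derived ASCC deformation d = -(1/3) (E_nu / (2 eps))^2 (always <= 0)."""
    if eps_dd == 0.0:
        raise DomainError("ASCC deformation undefined for eps_dd = 0")
    return -((E_nu / (2.0 * eps_dd)) ** 2) / 3.0


def _deformed_exp(x, d: float):
    """(1 - d x)^(1/d), the deformed exponential; equals exp(-x) at d = 0.

    Uses log1p for a smooth d -> 0 limit.  Raises DomainError where the base
    is non-positive (temperature outside the law's support).
    """
    x = np.asarray(x, dtype=float)
    if d == 0.0:
        return np.exp(-x)
    base = 1.0 - d * x
    if np.any(base <= 0.0):
        raise DomainError(
            "deformed-exponential base 1 - d*x is non-positive: "
            "temperature outside the law's support"
        )
    return np.exp(np.log1p(-d * x) / d)


def _check_T(T):
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0.0):
        raise DomainError("temperature must be strictly positive")
    return T


def eval_rate_law(params: RateLawParams, T):
    """Evaluate k(T) for the given law on a temperature grid (K).

    Returns an array in the units of ``params.A``.  Raises
    :class:`~ratekit.errors.DomainError` outside the law's support.
    """
    T = _check_T(T)
    beta = 1.0 / (_R * T)
    law = params.law
    # overflow to inf is acceptable here: fitting objectives map it to +inf
    with np.errstate(over="ignore"):
        if law is RateLaw.ARRHENIUS:
            return params.A * np.exp(-params.Ea * beta)
        if law is RateLaw.AM:
            return params.A * _deformed_exp(params.eps_dd * beta, params.d)
        if law is RateLaw.ASCC:
            denom = _R * T + params.E_nu
            if np.any(denom <= 0.0):
                raise DomainError("ASCC requires R*T + E_nu > 0")
            d = ascc_d(params.eps_dd, params.E_nu)
            return params.A * _deformed_exp(params.eps_dd / denom, d)
        if law is RateLaw.NTS:
            return params.A * np.exp(-params.E0 / (_R * np.sqrt(T * T + params.T0 ** 2)))
        if law is RateLaw.VFT:
            if np.any(T <= params.T0):
                raise DomainError("VFT law requires T > T0")
            return params.A * np.exp(params.B / (T - params.T0))
    raise InputError(f"unknown rate law {law!r}")


def apparent_ea_closed(params: RateLawParams, T):
    """Analytic apparent activation energy Ea(T) = -d ln k/d beta, cal/mol.

    Closed forms::

        ARRHENIUS  Ea
        AM         eps / (1 - d eps beta)
        ASCC       eps (RT)^2 / [(RT + E_nu)^2 (1 - d eps/(RT + E_nu))]
        NTS        E0 T^3 / (T^2 + T0^2)^(3/2)
        VFT        -B R T^2 / (T - T0)^2
    """
    T = _check_T(T)
    beta = 1.0 / (_R * T)
    law = params.law
    if law is RateLaw.ARRHENIUS:
        return np.full_like(T, params.Ea)
    if law is RateLaw.AM:
        base = 1.0 - params.d * params.eps_dd * beta
        if np.any(base <= 0.0):
            raise DomainError("temperature outside the AM law's support")
        return params.eps_dd / base
    if law is RateLaw.ASCC:
        denom = _R * T + params.E_nu
        if np.any(denom <= 0.0):
            raise DomainError("ASCC requires R*T + E_nu > 0")
        d = ascc_d(params.eps_dd, params.E_nu)
        base = 1.0 - d * params.eps_dd / denom
        if np.any(base <= 0.0):
            raise DomainError("temperature outside the ASCC law's support")
        return params.eps_dd * (_R * T) ** 2 / (denom ** 2 * base)
    if law is RateLaw.NTS:
        return params.E0 * T ** 3 / (T * T + params.T0 ** 2) ** 1.5
    if law is RateLaw.VFT:
        if np.any(T <= params.T0):
            raise DomainError("VFT law requires T > T0")
        return -params.B * _R * T * T / (T - params.T0) ** 2
    raise InputError(f"unknown rate law {law!r}")


def gamma_closed(params: RateLawParams, beta):
    """Transitivity gamma(beta) = 1/Ea(beta) in mol/cal.

    For the AM law the exact affine form ``1/eps - d beta`` is used.  Raises
    :class:`~ratekit.errors.SingularTransitivityError` where Ea = 0.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta <= 0.0):
        raise DomainError("beta must be strictly positive")
    if params.law is RateLaw.AM:
        if params.eps_dd == 0.0:
            raise SingularTransitivityError("AM with eps_dd = 0 has Ea = 0")
        return 1.0 / params.eps_dd - params.d * beta
    T = 1.0 / (_R * beta)
    ea = apparent_ea_closed(params, T)
    if np.any(ea == 0.0):
        raise SingularTransitivityError("apparent activation energy is zero")
    return 1.0 / ea


def params_to_dict(params: RateLawParams) -> dict:
    """Flat key-value form: law plus its own parameters only."""
    out = {"law": params.law.value}
    for name in LAW_PARAM_NAMES[params.law]:
        out[name] = getattr(params, name)
    return out


def params_from_dict(mapping: Mapping) -> RateLawParams:
    data = dict(mapping)
    try:
        law = RateLaw(str(data.pop("law")).lower())
    except (KeyError, ValueError) as exc:
        raise InputError(f"missing or unknown rate law in {mapping!r}") from exc
    known = {f.name for f in fields(RateLawParams)} - {"law"}
    bad = set(data) - known
    if bad:
        raise InputError(f"unknown rate-law parameters: {sorted(bad)}")
    return RateLawParams(law=law, **{k: float(v) for k, v in data.items()})
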