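"""Fit rate laws to (T, k) data by chi-square minimization with GSA.

Two fitting planes are supported:

* **Arrhenius plane** — minimize the mean squared residual of the rates in a
  chosen space (log10 by default) for any of the five laws.
* **Transitivity plane** — build the numerical transitivity series
  gamma(beta) from the data and minimize the squared gamma residual against
  the law's closed form; available for the Arrhenius, AM and VFT laws.  The
  pre-factor A does not enter gamma, so it is recovered afterwards as the
  mean log-offset of the data from the unit-A model.

The global GSA search is followed (optionally) by a bounded derivative-free
Nelder-Mead polish from the best point.  Formulas with more than two
parameters can admit multiple chi-square solutions; the fit reports the best
solution found for the given seed and bounds, nothing more — informative
bounds are the caller's tool for injecting prior knowledge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy.optimize import Bounds, minimize

from .constants import CONST
from .errors import DomainError, InputError, SingularTransitivityError
from .gsa import GSAConfig, ResidualSpace, chi_square, gsa_minimize
from .laws import (
    LAW_PARAM_NAMES,
    RateLaw,
    RateLawParams,
    eval_rate_law,
    gamma_closed,
)
from .transitivity import RateSeries, numerical_transitivity

__all__ = ["FitPlane", "FitResult", "fit_rate_data", "default_bounds", "TRANSITIVITY_LAWS"]

_R = CONST.R_cal

#: laws with a closed-form gamma simple enough for transitivity-plane fitting
TRANSITIVITY_LAWS = frozenset({RateLaw.ARRHENIUS, RateLaw.AM, RateLaw.VFT})

#: shape (non-prefactor) parameters per law, in vector order
_SHAPE_NAMES: dict[RateLaw, tuple[str, ...]] = {
    law: tuple(n for n in names if n != "A") for law, names in LAW_PARAM_NAMES.items()
}


class FitPlane(str, Enum):
    ARRHENIUS = "arrhenius"
    TRANSITIVITY = "transitivity"


@dataclass
class FitResult:
    law: RateLaw
    params: RateLawParams
    chi2: float
    n_eval: int
    seed: int
    plane: FitPlane
    space: str
    converged: bool
    bounds: dict[str, tuple[float, float]]
    trace: np.ndarray | None = None

    def residuals(self, series: RateSeries) -> np.ndarray:
        """Per-point log10 residuals of the fitted model on a series."""
        model = eval_rate_law(self.params, series.T)
        return np.log10(series.k) - np.log10(model)


def _free_names(law: RateLaw, plane: FitPlane) -> tuple[str, ...]:
    shape = _SHAPE_NAMES[law]
    return shape if plane is FitPlane.TRANSITIVITY else ("log10_A",) + shape


def _params_from_vector(law: RateLaw, names, x, A: float | None = None) -> RateLawParams:
    kwargs: dict[str, float] = {}
    for name, value in zip(names, x):
        if name == "log10_A":
            A = 10.0 ** value
        else:
            kwargs[name] = value
    return RateLawParams(law=law, A=1.0 if A is None else A, **kwargs)


def default_bounds(series: RateSeries, law: RateLaw, plane: FitPlane = FitPlane.ARRHENIUS) -> dict:
    """Data-driven search windows for each free parameter.

    A straight-line least-squares Arrhenius fit of (beta, ln k) anchors the
    scales: the window for A spans +-8 decades around the intercept (for
    strongly curved data the law's pre-factor can sit several decades off
    the straight-line intercept), energy parameters span +-(5|Ea0| + 2000)
    cal/mol, the AM deformation lies in [-3, 3], and T0 is kept below the
    data range for VFT (support) and below 1.5 Tmax for NTS.
    """
    beta = 1.0 / (_R * series.T)
    lnk = np.log(series.k)
    slope, intercept = np.polyfit(beta, lnk, 1)
    Ea0 = -slope
    log10_A0 = intercept / math.log(10.0)
    Tmin, Tmax = float(series.T.min()), float(series.T.max())
    Escale = 5.0 * abs(Ea0) + 2000.0

    windows: dict[str, tuple[float, float]] = {
        "log10_A": (log10_A0 - 8.0, log10_A0 + 8.0),
        "Ea": (Ea0 - Escale, Ea0 + Escale),
        "eps_dd": (-Escale, Escale),
        "d": (-3.0, 3.0),
        "E_nu": (0.0, 5.0 * _R * Tmax),
        "E0": (-Escale, Escale),
        "B": (-Escale / _R, Escale / _R),
    }
    if law is RateLaw.VFT:
        windows["T0"] = (0.0, 0.98 * Tmin)
    else:
        windows["T0"] = (0.0, 1.5 * Tmax)
    return {name: windows[name] for name in _free_names(law, plane)}


def _anchored_start(series: RateSeries, law: RateLaw, names, bounds) -> np.ndarray:
    """Deterministic data-driven starting vector.

    Maps the straight-line Arrhenius estimate (slope Ea0, intercept A0) into
    each law's parameters: curvature parameters start at their neutral values
    (d = 0, T0 at the window edge), so the start always lies in the global
    basin for weakly curved data and is at worst a sane interior point.
    """
    beta = 1.0 / (_R * series.T)
    slope, intercept = np.polyfit(beta, np.log(series.k), 1)
    Ea0 = -slope
    anchor = {
        "log10_A": intercept / math.log(10.0),
        "Ea": Ea0,
        "eps_dd": Ea0 if Ea0 != 0.0 else 1.0,
        "d": 0.0,
        "E_nu": 0.0,
        "E0": Ea0,
        "T0": 0.0,
        "B": -Ea0 / _R,
    }
    x0 = np.array([anchor[n] for n in names], dtype=float)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    # nudge strictly inside the box so support checks cannot pin the start
    width = hi - lo
    return np.clip(x0, lo + 1e-6 * width, hi - 1e-6 * width)


def _recover_prefactor(series: RateSeries, law: RateLaw, shape_kwargs: dict) -> float:
    """ln A as the mean log-offset from the unit-A model (transitivity plane)."""
    unit = RateLawParams(law=law, A=1.0, **shape_kwargs)
    lnk_model = np.log(eval_rate_law(unit, series.T))
    return float(np.exp(np.mean(np.log(series.k) - lnk_model)))


def fit_rate_data(
    series: RateSeries,
    law: RateLaw | str,
    guess: RateLawParams | None = None,
    config: GSAConfig | None = None,
    plane: FitPlane | str = FitPlane.ARRHENIUS,
    space: ResidualSpace | str = ResidualSpace.LOG10,
    polish: bool = True,
) -> FitResult:
    """Fit one rate law to a RateSeries and return the optimized parameters.

    Support violations encountered during the search are treated as +inf
    objective values.  A fixed ``config.seed`` makes the whole fit (GSA and
    polish) deterministic.
    """
    law = RateLaw(law)
    plane = FitPlane(plane)
    space = ResidualSpace(space)
    if plane is FitPlane.TRANSITIVITY and law not in TRANSITIVITY_LAWS:
        raise InputError(
            f"transitivity-plane fitting supports "
            f"{sorted(l.value for l in TRANSITIVITY_LAWS)}, not {law.value!r}"
        )
    config = config if config is not None else GSAConfig()
    names = _free_names(law, plane)

    if config.bounds is None:
        bound_map = default_bounds(series, law, plane)
        config = replace(config, bounds=[bound_map[n] for n in names])
    else:
        if len(config.bounds) != len(names):
            raise InputError(
                f"{law.value}/{plane.value} fit needs {len(names)} bounds "
                f"(parameters {names}), got {len(config.bounds)}"
            )
        bound_map = dict(zip(names, [tuple(map(float, b)) for b in config.bounds]))

    if plane is FitPlane.ARRHENIUS:
        T_obs, k_obs = series.T, series.k

        def objective(x: np.ndarray) -> float:
            try:
                p = _params_from_vector(law, names, x)
                model = eval_rate_law(p, T_obs)
                return chi_square(k_obs, model, space)
            except (DomainError, OverflowError):
                return math.inf

        space_label = space.value
    else:
        ts = numerical_transitivity(series)
        mask = ts.interior() & ts.gamma_defined
        if mask.sum() < 2:
            raise InputError("too few interior transitivity points to fit")
        beta_obs, gamma_obs = ts.beta[mask], ts.gamma[mask]

        def objective(x: np.ndarray) -> float:
            try:
                p = _params_from_vector(law, names, x)
                gamma_model = gamma_closed(p, beta_obs)
                resid = gamma_obs - gamma_model
                return float(np.mean(resid * resid))
            except (DomainError, SingularTransitivityError, OverflowError):
                return math.inf

        space_label = "gamma"

    if guess is not None:
        if guess.law is not law:
            raise InputError("guess parameters belong to a different law")
        vec = []
        for n in names:
            vec.append(math.log10(guess.A) if n == "log10_A" else getattr(guess, n))
        x0 = np.asarray(vec, dtype=float)
    else:
        x0 = _anchored_start(series, law, names, config.bounds)

    result = gsa_minimize(objective, config, x0=x0)
    x_best, f_best, n_eval = result.x, result.fun, result.n_eval

    if polish and math.isfinite(f_best):
        lo = [b[0] for b in config.bounds]
        hi = [b[1] for b in config.bounds]
        # polish both the annealing optimum and the anchored start: the
        # better simplex limit wins (GSA can end on a support cliff where
        # the simplex cannot move)
        starts = [x_best] if np.allclose(x_best, x0) else [x_best, x0]
        for start in starts:
            xs = np.asarray(start, dtype=float)
            for _ in range(2):  # second pass restarts the simplex at its own optimum
                res = minimize(
                    objective,
                    xs,
                    method="Nelder-Mead",
                    bounds=Bounds(lo, hi),
                    options={"xatol": 1e-12, "fatol": 1e-16, "maxfev": 20_000},
                )
                n_eval += res.nfev
                xs = np.asarray(res.x)
                if res.fun < f_best:
                    x_best, f_best = xs, float(res.fun)

    if plane is FitPlane.TRANSITIVITY:
        shape_kwargs = dict(zip(names, x_best))
        A = _recover_prefactor(series, law, shape_kwargs)
        params = RateLawParams(law=law, A=A, **shape_kwargs)
    else:
        params = _params_from_vector(law, names, x_best)

    return FitResult(
        law=law,
        params=params,
        chi2=f_best,
        n_eval=n_eval,
        seed=config.seed,
        plane=plane,
        space=space_label,
        converged=math.isfinite(f_best),
        bounds=bound_map,
        trace=result.trace,
    )
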