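"""Generalized Simulated Annealing (Tsallis statistics) and the chi-square
objective used for rate-law fitting.

GSA generalizes classical simulated annealing with a heavy-tailed
*visiting distribution* (Tsallis q-Gaussian, index ``qv``) and a
*generalized Metropolis* acceptance rule (index ``qa``).  The visiting
temperature follows the schedule

    T_qv(t) = T_qv(1) * (2^(qv-1) - 1) / ((1 + t)^(qv-1) - 1),

whose heavy tails let the walker escape local basins early while the
acceptance temperature ``T_qv(t)/t`` cools faster.  The q-Gaussian visiting
deviate is generated exactly as a scaled Student-t variate with
``nu = (3 - qv)/(qv - 1)`` degrees of freedom (the two families coincide for
1 < qv < 3).  Each annealing step proposes one joint move of all coordinates
followed by one move per coordinate, reflected into the bound box; the
characteristic step width scales as ``T_qv^(1/(3-qv))`` (capped at the box
size), while the distribution's power-law tail keeps rare box-scale jumps
alive throughout the schedule.

The implementation is deterministic for a fixed seed: identical seeds yield
bitwise-identical traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np

from .errors import DomainError, InputError, KineticsError

__all__ = ["ResidualSpace", "chi_square", "GSAConfig", "GSAResult", "gsa_minimize"]


class ResidualSpace(str, Enum):
    LOG10 = "log10"
    LN = "ln"
    LINEAR = "linear"
    RELATIVE = "relative"


def chi_square(observed, model, space: ResidualSpace | str = ResidualSpace.LOG10) -> float:
    """Mean squared residual between observed and model rates in a chosen space.

    ``LOG10``/``LN`` require strictly positive values and are the natural
    choice for rate constants spanning many decades; ``RELATIVE`` divides the
    residual by the observation.
    """
    space = ResidualSpace(space)
    observed = np.asarray(observed, dtype=float)
    model = np.asarray(model, dtype=float)
    if observed.shape != model.shape:
        raise InputError("observed and model arrays must have equal length")
    if observed.size == 0:
        raise InputError("empty arrays")
    if space in (ResidualSpace.LOG10, ResidualSpace.LN):
        if np.any(observed <= 0.0) or np.any(model <= 0.0):
            raise DomainError("non-positive rate constant in a logarithmic residual space")
        resid = np.log(observed) - np.log(model)
        if space is ResidualSpace.LOG10:
            resid = resid / math.log(10.0)
    elif space is ResidualSpace.LINEAR:
        resid = observed - model
    else:  # RELATIVE
        if np.any(observed == 0.0):
            raise InputError("relative residuals undefined for zero observations")
        resid = (observed - model) / observed
    return float(np.mean(resid * resid))


@dataclass
class GSAConfig:
    """Annealing-schedule and search-box configuration.

    ``bounds`` is a sequence of finite (low, high) intervals, one per
    parameter.  ``T_qv_initial`` follows common GSA practice (a fixed 5230,
    independent of the objective's units, so the visiting-step geometry does
    not depend on how the objective is scaled).  ``1 < qv < 3`` is required
    by the Tsallis visiting distribution.
    """

    bounds: Sequence[tuple[float, float]] | None = None
    qv: float = 2.62
    qa: float = -5.0
    T_qv_initial: float = 5230.0
    max_iter: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not (1.0 < self.qv < 3.0):
            raise InputError("GSA requires 1 < qv < 3")
        if self.max_iter < 1:
            raise InputError("max_iter must be >= 1")
        if self.bounds is not None:
            b = np.asarray(self.bounds, dtype=float)
            if b.ndim != 2 or b.shape[1] != 2 or b.shape[0] == 0:
                raise InputError("bounds must be a nonempty sequence of (low, high) pairs")
            if not np.all(np.isfinite(b)) or np.any(b[:, 1] <= b[:, 0]):
                raise InputError("bounds must be finite with high > low")


@dataclass
class GSAResult:
    x: np.ndarray
    fun: float
    trace: np.ndarray = field(repr=False)
    n_eval: int = 0


def _reflect(v: float, lo: float, hi: float) -> float:
    """Fold a proposal back into [lo, hi] by mirror reflection."""
    span = hi - lo
    if span <= 0.0:
        return lo
    if not math.isfinite(v):
        return lo + 0.5 * span
    z = math.fmod(v - lo, 2.0 * span)
    if z < 0.0:
        z += 2.0 * span
    return lo + (2.0 * span - z if z > span else z)


def gsa_minimize(
    objective: Callable[[np.ndarray], float],
    config: GSAConfig,
    x0: np.ndarray | None = None,
) -> GSAResult:
    """Minimize a scalar function over a bounded box by GSA.

    Non-finite objective values (and exceptions mapped to them by the caller)
    are treated as +inf.  Returns the best-ever point, its value, the
    non-increasing best-so-far trace and the evaluation count.  Ties keep the
    earlier-found point, so the run is fully deterministic for a given seed.
    """
    if config.bounds is None:
        raise InputError("gsa_minimize requires bounds")
    bounds = np.asarray(config.bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    dim = len(bounds)
    rng = np.random.default_rng(config.seed)

    n_eval = 0

    def safe_f(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        val = objective(x)
        val = float(val)
        return val if math.isfinite(val) else math.inf

    if x0 is not None:
        x = np.clip(np.asarray(x0, dtype=float), lo, hi)
        f = safe_f(x)
    else:
        f = math.inf
        x = lo + rng.random(dim) * span
        f = safe_f(x)
    tries = 0
    while not math.isfinite(f):
        if tries >= 100:
            raise KineticsError("objective is non-finite at every sampled point")
        x = lo + rng.random(dim) * span
        f = safe_f(x)
        tries += 1

    qv, qa = config.qv, config.qa
    T1 = config.T_qv_initial
    nu = (3.0 - qv) / (qv - 1.0)
    step_norm = 1.0 / math.sqrt(3.0 - qv)
    pow_v = 1.0 / (3.0 - qv)
    c_qv = 2.0 ** (qv - 1.0) - 1.0

    x_best = x.copy()
    f_best = f
    trace = np.empty(config.max_iter)

    def metropolis(fy: float, f: float, Ta: float) -> bool:
        if fy <= f:
            return True
        if not math.isfinite(fy):
            rng.random()  # keep the stream aligned regardless of branch
            return False
        base = 1.0 - (1.0 - qa) * (fy - f) / Ta
        if base <= 0.0:
            rng.random()
            return False
        return rng.random() < base ** (1.0 / (1.0 - qa))

    for t in range(1, config.max_iter + 1):
        Tv = T1 * c_qv / ((1.0 + t) ** (qv - 1.0) - 1.0)
        Ta = Tv / t
        width = min(Tv ** pow_v, 1.0)  # characteristic step, box units
        # one joint move of all coordinates, then one move per coordinate
        proposals = [None] + list(range(dim))
        for which in proposals:
            y = x.copy()
            if which is None:
                for j in range(dim):
                    dx = span[j] * width * step_norm * rng.standard_t(nu)
                    y[j] = _reflect(x[j] + dx, lo[j], hi[j])
            else:
                dx = span[which] * width * step_norm * rng.standard_t(nu)
                y[which] = _reflect(x[which] + dx, lo[which], hi[which])
            fy = safe_f(y)
            if metropolis(fy, f, Ta):
                x, f = y, fy
                if f < f_best:  # strict: ties keep the earlier point
                    x_best, f_best = y.copy(), f
        trace[t - 1] = f_best

    return GSAResult(x=x_best, fun=f_best, trace=trace, n_eval=n_eval)
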