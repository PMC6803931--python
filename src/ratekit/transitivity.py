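"""Numerical construction of the transitivity plot from tabulated (T, k) data.

The apparent activation energy is the beta-derivative of ln k (beta = 1/(R T)),
estimated here by second-order finite differences on the (beta, ln k) point
set; the transitivity function is its reciprocal, gamma = 1/Ea.  Noisy data
can be smoothed with a Savitzky-Golay filter applied to ln k *before*
differencing (differentiating raw noisy k amplifies noise multiplicatively).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .constants import CONST
from .errors import InputError

__all__ = ["RateSeries", "TransitivitySeries", "numerical_transitivity", "savgol_smooth"]

_R = CONST.R_cal


@dataclass
class RateSeries:
    """(T, k) observations: temperatures in K, positive rate constants.

    Sorted by temperature on construction; duplicate temperatures are kept
    (they are averaged in ln k by :func:`numerical_transitivity`).
    """

    T: np.ndarray
    k: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""
    units: str = "arbitrary"

    def __post_init__(self):
        T = np.atleast_1d(np.asarray(self.T, dtype=float))
        k = np.atleast_1d(np.asarray(self.k, dtype=float))
        if T.shape != k.shape or T.ndim != 1:
            raise InputError("T and k must be 1-D arrays of equal length")
        if np.any(T <= 0.0):
            raise InputError("temperatures must be strictly positive")
        if np.any(k <= 0.0):
            raise InputError("rate constants must be strictly positive")
        order = np.argsort(T, kind="stable")
        self.T = T[order]
        self.k = k[order]
        if self.sigma is not None:
            sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
            if sigma.shape != T.shape:
                raise InputError("sigma must match T in length")
            self.sigma = sigma[order]

    def __len__(self) -> int:
        return len(self.T)


@dataclass
class TransitivitySeries:
    """Aligned transitivity-plane grids.

    ``gamma[i] * Ea[i] == 1`` wherever ``gamma_defined[i]``; ``endpoint``
    marks the one-sided (lower-accuracy) estimates at the grid edges.
    """

    T: np.ndarray
    beta: np.ndarray
    Ea: np.ndarray
    gamma: np.ndarray
    smoothed: bool = False
    endpoint: np.ndarray = field(default=None)
    gamma_defined: np.ndarray = field(default=None)

    def interior(self) -> np.ndarray:
        """Boolean mask of interior (centered-difference) points."""
        return ~self.endpoint

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"T": self.T, "beta": self.beta, "Ea": self.Ea, "gamma": self.gamma}
        )


def savgol_smooth(y, window: int, order: int):
    """Savitzky-Golay least-squares local-polynomial smoothing.

    Polynomials of degree <= ``order`` are reproduced exactly.  ``window``
    must be odd, larger than ``order`` and no longer than the sequence.
    """
    y = np.asarray(y, dtype=float)
    if window % 2 == 0:
        raise InputError("Savitzky-Golay window must be odd")
    if window <= order:
        raise InputError("Savitzky-Golay window must exceed the polynomial order")
    if window > len(y):
        raise InputError("Savitzky-Golay window longer than the data")
    return savgol_filter(y, window_length=window, polyorder=order)


def _resolve_smooth(smooth) -> tuple[int, int] | None:
    if smooth is None or smooth is False:
        return None
    if smooth is True:
        return (7, 2)  # default window/order
    if isinstance(smooth, dict):
        return (int(smooth.get("window", 7)), int(smooth.get("order", 2)))
    window, order = smooth
    return (int(window), int(order))


def numerical_transitivity(series: RateSeries, smooth=None) -> TransitivitySeries:
    """Apparent activation energy and transitivity by numerical differentiation.

    Parameters
    ----------
    series
        Rate-constant observations (>= 3 distinct temperatures).
    smooth
        ``None`` for raw differencing, ``True`` for the default
        Savitzky-Golay window (7, 2), or an explicit ``(window, order)``.

    Ea is obtained as ``-d ln k/d beta`` with the standard three-point
    unequal-spacing stencil at interior points and one-sided differences at
    the endpoints (flagged lower-accuracy).  Points with Ea = 0 are flagged
    (gamma set to NaN) rather than fatal.
    """
    # collapse duplicate temperatures by averaging ln k
    T_unique, inverse = np.unique(series.T, return_inverse=True)
    lnk = np.zeros_like(T_unique)
    counts = np.bincount(inverse)
    np.add.at(lnk, inverse, np.log(series.k))
    lnk /= counts

    if len(T_unique) < 3:
        raise InputError("numerical transitivity needs at least 3 distinct temperatures")

    cfg = _resolve_smooth(smooth)
    if cfg is not None:
        lnk = savgol_smooth(lnk, *cfg)

    beta = 1.0 / (_R * T_unique)
    # np.gradient implements the 3-point unequal-spacing interior stencil;
    # edge_order=2 gives the matching one-sided endpoint formulas.
    dlnk_dbeta = np.gradient(lnk, beta, edge_order=2)
    Ea = -dlnk_dbeta
    defined = Ea != 0.0
    with np.errstate(divide="ignore"):
        gamma = np.where(defined, 1.0 / np.where(defined, Ea, 1.0), np.nan)

    endpoint = np.zeros(len(T_unique), dtype=bool)
    endpoint[0] = endpoint[-1] = True
    return TransitivitySeries(
        T=T_unique,
        beta=beta,
        Ea=Ea,
        gamma=gamma,
        smoothed=cfg is not None,
        endpoint=endpoint,
        gamma_defined=defined,
    )
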