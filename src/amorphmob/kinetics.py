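"""Mobility coefficients and activation energies from displacement series.

The mobility coefficient comes from the simplified Einstein relation
applied to the fitted slope k of the linear portion of a displacement
series: D = |k| / 6.  Fitting the spread-RMSD series (linear units, Å)
gives D in Å/ps — the "mobility coefficient" of the analysis, a length
per time, not a true diffusion constant; fitting a from-origin MSD series
(Å^2) gives a genuine diffusion coefficient in Å^2/ps.  Both routes share
the same fit-and-divide machinery.

Activation energies follow from Arrhenius regression,
ln D = ln D0 - Ea/(R T), by ordinary least squares of ln D on 1/T.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError

#: universal gas constant, J/(mol K)
R_GAS = 8.314

#: default linear-fit window (ps): the rapid-rise regime before the plateau
DEFAULT_FIT_WINDOW = (0.0, 20.0)


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least squares y = k x + b over a time window."""

    k: float
    b: float
    r_squared: float
    window: tuple[float, float]
    n_points: int

    def __post_init__(self):
        if self.n_points < 2:
            raise DomainError("a linear fit needs at least 2 points")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise DomainError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class MobilityResult:
    """Mobility coefficient D = |k|/6 with its source fit."""

    D: float
    source_fit: LinearFit
    species: str = "total"

    def __post_init__(self):
        if self.D < 0:
            raise DomainError("mobility coefficient must be non-negative")


@dataclass(frozen=True)
class ArrheniusResult:
    """Arrhenius parameters from ln D vs 1/T regression.

    Ea is in kJ/mol; D0 has the units of the input D values.
    """

    D0: float
    Ea: float
    r_squared: float
    n_points: int
    gas_constant: float = R_GAS


def fit_linear_window(series, t_min: float | None = None,
                      t_max: float | None = None) -> LinearFit:
    """OLS fit of series values vs time restricted to [t_min, t_max].

    ``series`` is anything with ``times`` and ``values`` arrays
    (SpreadSeries, MSDSeries, ...).  Defaults to the 0–20 ps rapid-rise
    window.
    """
    if t_min is None:
        t_min = DEFAULT_FIT_WINDOW[0]
    if t_max is None:
        t_max = DEFAULT_FIT_WINDOW[1]
    t = np.asarray(series.times, dtype=float)
    y = np.asarray(series.values, dtype=float)
    sel = (t >= t_min) & (t <= t_max) & np.isfinite(y)
    t, y = t[sel], y[sel]
    if t.size < 2:
        raise DomainError(
            f"fit window [{t_min}, {t_max}] ps contains {t.size} points; "
            "need at least 2")
    if np.ptp(t) == 0:
        raise DomainError("fit window has zero time variance")
    res = stats.linregress(t, y)
    r2 = res.rvalue ** 2 if np.isfinite(res.rvalue) else 1.0
    return LinearFit(k=float(res.slope), b=float(res.intercept),
                     r_squared=float(min(r2, 1.0)),
                     window=(float(t_min), float(t_max)), n_points=int(t.size))


def mobility_coefficient(fit: LinearFit, species: str = "total"
                         ) -> MobilityResult:
    """Simplified Einstein relation D = |k| / 6.

    The magnitude convention: a contracting series (negative k, as in the
    clustering phase) still yields a positive mobility coefficient; the
    sign of k is kept on the fit itself.
    """
    return MobilityResult(D=abs(fit.k) / 6.0, source_fit=fit, species=species)


def arrhenius_fit(points) -> ArrheniusResult:
    """Least squares of ln D on 1/T; Ea = -slope * R in kJ/mol.

    ``points`` is a sequence of (temperature_K, D) pairs with D > 0 and at
    least two distinct temperatures.  Natural logarithm throughout.
    """
    pts = [(float(T), float(D)) for T, D in points]
    if len(pts) < 2:
        raise DomainError("Arrhenius fit needs at least 2 points")
    T = np.array([p[0] for p in pts])
    D = np.array([p[1] for p in pts])
    if np.any(T <= 0):
        raise DomainError("temperatures must be positive")
    if np.any(D <= 0):
        raise DomainError("all mobility coefficients must be positive")
    if np.unique(T).size < 2:
        raise DomainError("Arrhenius fit needs at least 2 distinct temperatures")
    x = 1.0 / T
    y = np.log(D)
    res = stats.linregress(x, y)
    r2 = res.rvalue ** 2 if np.isfinite(res.rvalue) else 1.0
    return ArrheniusResult(D0=float(np.exp(res.intercept)),
                           Ea=float(-res.slope * R_GAS / 1000.0),
                           r_squared=float(min(r2, 1.0)), n_points=len(pts))


def mobility_to_cm2_per_s(D_A2_per_ps: float) -> float:
    """Convert a diffusion coefficient from Å^2/ps to cm^2/s.

    1 Å^2/ps = 1e-16 cm^2 / 1e-12 s = 1e-4 cm^2/s.  Only meaningful for
    true MSD-slope diffusion constants, not for the Å/ps spread-slope
    mobility coefficient.
    """
    return D_A2_per_ps * 1e-4
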