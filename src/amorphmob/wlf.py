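"""WLF relaxation kinetics, the Strength parameter, and timescale translation.

Above the glass transition the relaxation time follows the
Williams–Landel–Ferry law

    log10(tau / tau_g) = -C1 (T - Tg) / (C2 + (T - Tg)),

with material-specific constants C1 (dimensionless) and C2 (K).  The
Strength parameter S is the temperature rise above Tg at which flow
drops by a critical number of decades d_s (d_s = 4 for carbohydrate
systems):

    S = d_s C2 / (C1 - d_s),

the unique closed form solving the WLF law for a d_s-decade drop;
C1 > d_s is required for a finite positive S.

Cell-scale relaxation times can be rescaled to laboratory timescales
with an explicit conversion factor; a per-gram convention
(Avogadro / molar mass) / n_cell is provided as one documented reading —
the literature arithmetic behind such translations is not unique, so the
factor is always an explicit input, never an implicit constant.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError

AVOGADRO = 6.022e23
LACTOSE_MOLAR_MASS = 342.3  # g/mol


@dataclass(frozen=True)
class WLFParams:
    """WLF constants plus the reference relaxation time at Tg."""

    C1: float
    C2: float
    Tg: float = 0.0
    tau_g: float = 100.0
    ds: float = 4.0

    def __post_init__(self):
        if not self.C2 > 0:
            raise DomainError("C2 must be positive")
        if not self.ds > 0:
            raise DomainError("ds must be positive")
        if self.tau_g <= 0:
            raise DomainError("tau_g must be positive")


@dataclass(frozen=True)
class StrengthResult:
    """The critical temperature rise S (K) for a ds-decade flow drop."""

    S: float
    ds: float
    params: WLFParams


def wlf_log_shift(T_minus_Tg: float, params: WLFParams) -> float:
    """log10(tau/tau_g) at a temperature T - Tg above the glass transition.

    Defined for T - Tg > -C2 (the WLF pole); returns 0 at T = Tg and
    tends to -C1 as T - Tg grows.
    """
    if T_minus_Tg <= -params.C2:
        raise DomainError(
            f"T - Tg must exceed -C2 = {-params.C2} K (WLF pole)")
    return -params.C1 * T_minus_Tg / (params.C2 + T_minus_Tg)


def strength(params: WLFParams) -> StrengthResult:
    """Closed-form Strength parameter S = ds*C2/(C1 - ds).

    S solves wlf_log_shift(S) = -ds exactly; it exists (finite, positive)
    only when C1 > ds.
    """
    if params.C1 <= params.ds:
        raise DomainError(
            f"no finite positive S: C1 = {params.C1} must exceed "
            f"ds = {params.ds}")
    s = params.ds * params.C2 / (params.C1 - params.ds)
    return StrengthResult(S=s, ds=params.ds, params=params)


def relaxation_time(T_minus_Tg: float, params: WLFParams) -> float:
    """tau(T) = tau_g * 10**wlf_log_shift(T - Tg), in the units of tau_g."""
    return params.tau_g * 10.0 ** wlf_log_shift(T_minus_Tg, params)


def translate_timescale(tau_cell: float, conversion_factor: float) -> float:
    """Rescale a cell-scale relaxation time by an explicit factor."""
    if tau_cell <= 0:
        raise DomainError("tau_cell must be positive")
    if conversion_factor <= 0:
        raise DomainError("conversion_factor must be positive")
    return tau_cell * conversion_factor


def per_gram_conversion_factor(molar_mass_g: float = LACTOSE_MOLAR_MASS,
                               n_cell: int = 10_000) -> float:
    """ONE documented reading of cell-to-real timescale conversion.

    Molecules per gram of material divided by molecules per simulated
    cell: (Avogadro / molar_mass_g) / n_cell.  Interpret with care — it
    is a convention, not a derived physical law.
    """
    if molar_mass_g <= 0 or n_cell <= 0:
        raise DomainError("molar mass and cell size must be positive")
    return (AVOGADRO / molar_mass_g) / n_cell
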