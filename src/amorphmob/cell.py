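"""Simulant lactose/water cells and coarse-grained Brownian trajectories.

A cell is a cubic periodic box holding M lactose and N water molecules,
each represented by a single tracking point (the oxygen nearest the
molecule's geometric center).  Composition and box size at the four
studied water activities follow the reference composition table for
100-molecule cells at 0.5 g/cm^3; other sizes scale the box side as
(n_total/100)^(1/3) at fixed density, and other activities interpolate
the composition linearly between the bracketing studied activities.

Dynamics are deliberately minimal: each molecule performs overdamped
Brownian motion with a species-specific, temperature-activated,
water-plasticized step variance, wrapped into the periodic box.  An
optional equilibrium-clustering phase adds a drift toward the
instantaneous all-molecule centroid after ``t_cluster``, which makes the
spread statistic contract — the two-phase (plasticized expansion, then
cluster-driven contraction) mobility pathway the analysis layer is built
to detect.  This generator replaces a full force-field MD engine: the
downstream statistics consume only the tracked points, so the stand-in
only needs to get their statistical structure right.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datamodel import LACTOSE, WATER, Trajectory, trajectory_from_array
from .errors import DomainError

#: universal gas constant, J/(mol K)
R_GAS = 8.314

#: studied water-activity grid -> (lactose count, water count) per 100 molecules
STUDIED_RATIOS = {
    0.11: (68, 32),
    0.22: (57, 43),
    0.33: (52, 48),
    0.44: (38, 62),
}

#: studied water-activity grid -> cubic box side (Å) for 100-molecule cells
STUDIED_BOX_SIDES = {0.11: 42.9, 0.22: 40.7, 0.33: 39.6, 0.44: 36.0}

#: experimental calorimetric-onset glass transition temperatures (K)
STUDIED_TG = {0.11: 338.0, 0.22: 313.0, 0.33: 303.0, 0.44: 286.0}

#: reference cell density, g/cm^3
DEFAULT_DENSITY = 0.5


@dataclass(frozen=True)
class CellSpec:
    """Composition and geometry of one simulant cell.

    a_w is the mimic water activity the cell represents; it drives both
    the lactose:water ratio and (in the dynamics) the plasticization
    factor.  ``interpolated`` flags compositions obtained by linear
    interpolation between the studied activities.
    """

    a_w: float
    n_lactose: int
    n_water: int
    box_side: float
    density: float = DEFAULT_DENSITY
    T_g: float | None = None
    interpolated: bool = False

    def __post_init__(self):
        if not 0.0 <= self.a_w <= 1.0:
            raise DomainError("a_w must lie in [0, 1]")
        if self.n_lactose < 0 or self.n_water < 0:
            raise DomainError("molecule counts must be non-negative")
        if self.n_lactose + self.n_water < 1:
            raise DomainError("cell must contain at least one molecule")
        if not self.box_side > 0:
            raise DomainError("box_side must be positive")

    @property
    def n_total(self) -> int:
        return self.n_lactose + self.n_water


@dataclass(frozen=True)
class DynamicsParams:
    """Knobs of the Brownian stand-in dynamics.

    Per-species instantaneous mobility at temperature T and activity a_w:

        D_sp(T, a_w) = D0_sp * exp(-Ea_sp / (R T)) * (1 + plasticization_slope * a_w)

    in Å^2/ps with Ea in kJ/mol.  Defaults put the activation energies in
    the 7–13 kJ/mol range typical of plasticized amorphous carbohydrate
    matrices and the resulting D(T) one to two orders of magnitude below
    bulk-water self-diffusion (0.23 Å^2/ps), i.e. a viscous glass-former
    just above Tg.  ``kappa_cluster`` > 0 switches on centroid-directed
    drift after ``t_cluster`` (equilibrium clustering); ``init_spread`` is
    the per-axis standard deviation (Å) of the initial compact Gaussian
    placement about the box center (None -> box_side / 8), emulating a
    pre-equilibration configuration that then expands.
    """

    D0_water: float = 3.0
    D0_lactose: float = 1.2
    Ea_water: float = 11.0
    Ea_lactose: float = 13.0
    plasticization_slope: float = 1.0
    t_cluster: float = 20.0
    kappa_cluster: float = 0.05
    dt_record: float = 1.0
    t_total: float = 100.0
    init_spread: float | None = None

    def __post_init__(self):
        for name in ("D0_water", "D0_lactose", "Ea_water", "Ea_lactose",
                     "plasticization_slope", "t_cluster", "kappa_cluster",
                     "dt_record", "t_total"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if self.dt_record <= 0:
            raise DomainError("dt_record must be positive")
        if self.t_cluster > self.t_total:
            raise DomainError("t_cluster must not exceed t_total")

    def mobility(self, species: str, temperature: float, a_w: float) -> float:
        """Expected instantaneous mobility D_sp(T, a_w) in Å^2/ps."""
        if temperature <= 0:
            raise DomainError("temperature must be positive")
        if species == WATER:
            d0, ea = self.D0_water, self.Ea_water
        elif species == LACTOSE:
            d0, ea = self.D0_lactose, self.Ea_lactose
        else:
            raise DomainError(f"unknown species {species!r}")
        boltz = np.exp(-ea * 1000.0 / (R_GAS * temperature))
        return d0 * boltz * (1.0 + self.plasticization_slope * a_w)


def _interp(a_w: float, table: dict[float, float]) -> float:
    """Piecewise-linear interpolation over the studied activity grid,
    clamped to the nearest studied value outside the grid."""
    grid = sorted(table)
    return float(np.interp(a_w, grid, [table[g] for g in grid]))


def build_cell(a_w: float, n_total: int = 100,
               density: float = DEFAULT_DENSITY) -> CellSpec:
    """Build the simulant-cell spec for a mimic water activity.

    For the studied activities {0.11, 0.22, 0.33, 0.44} the composition
    is the reference lactose:water ratio scaled to ``n_total`` (lactose
    count rounded, water takes the remainder) and the box side is the
    reference side scaled by (n_total/100)^(1/3) at fixed density.
    Other activities interpolate linearly between the bracketing studied
    ratios and are flagged ``interpolated``.
    """
    if not 0.0 <= a_w <= 1.0:
        raise DomainError("a_w must lie in [0, 1]")
    if n_total < 1:
        raise DomainError("n_total must be at least 1")
    studied = a_w in STUDIED_RATIOS
    if studied:
        ref_l, ref_w = STUDIED_RATIOS[a_w]
        frac_l = ref_l / (ref_l + ref_w)
        side100 = STUDIED_BOX_SIDES[a_w]
        tg = STUDIED_TG[a_w]
    else:
        frac_l = _interp(a_w, {g: l / (l + w)
                               for g, (l, w) in STUDIED_RATIOS.items()})
        side100 = _interp(a_w, STUDIED_BOX_SIDES)
        tg = _interp(a_w, STUDIED_TG)
    n_lactose = int(round(frac_l * n_total))
    n_water = n_total - n_lactose
    scale = (n_total / 100.0) ** (1.0 / 3.0)
    side = side100 * scale * (DEFAULT_DENSITY / density) ** (1.0 / 3.0)
    return CellSpec(a_w=a_w, n_lactose=n_lactose, n_water=n_water,
                    box_side=side, density=density, T_g=tg,
                    interpolated=not studied)


def simulate(cell: CellSpec, dyn: DynamicsParams, temperature: float,
             seed: int) -> Trajectory:
    """Generate a Brownian trajectory for one cell at one temperature.

    Molecules start in a compact Gaussian blob about the box center
    (per-axis sd ``dyn.init_spread``), take per-frame Gaussian steps of
    per-coordinate variance 2 * D_sp * dt_record, and — once t exceeds
    ``dyn.t_cluster`` and if ``dyn.kappa_cluster`` > 0 — drift toward the
    instantaneous all-molecule centroid at rate kappa.  All recorded
    coordinates are wrapped into [0, box_side).  Identical inputs and
    seed reproduce the trajectory bit for bit.
    """
    if temperature <= 0:
        raise DomainError("temperature must be positive")
    rng = np.random.default_rng(seed)
    L = cell.box_side
    n = cell.n_total
    species = np.array([LACTOSE] * cell.n_lactose + [WATER] * cell.n_water,
                       dtype=object)
    # per-molecule step sd, shape (n, 1) for broadcasting over xyz
    d_by_species = {sp: dyn.mobility(sp, temperature, cell.a_w)
                    for sp in (WATER, LACTOSE)}
    step_sd = np.array([np.sqrt(2.0 * d_by_species[sp] * dyn.dt_record)
                        for sp in species])[:, None]

    spread0 = dyn.init_spread if dyn.init_spread is not None else L / 8.0
    pos = L / 2.0 + rng.normal(scale=spread0, size=(n, 3)) if spread0 > 0 \
        else np.full((n, 3), L / 2.0)
    pos %= L

    n_frames = int(round(dyn.t_total / dyn.dt_record)) + 1
    times = np.arange(n_frames) * dyn.dt_record
    out = np.empty((n_frames, n, 3))
    out[0] = pos
    for k in range(1, n_frames):
        pos = pos + rng.normal(size=(n, 3)) * step_sd
        if dyn.kappa_cluster > 0 and times[k] > dyn.t_cluster:
            centroid = pos.mean(axis=0)
            pos = pos - dyn.kappa_cluster * (pos - centroid) * dyn.dt_record
        pos %= L
        out[k] = pos
    return trajectory_from_array(times, out, species, L,
                                 dt_record=dyn.dt_record,
                                 temperature=temperature, cell=cell)


def without_clustering(dyn: DynamicsParams) -> DynamicsParams:
    """Convenience: the same dynamics with the clustering phase disabled."""
    return replace(dyn, kappa_cluster=0.0)
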