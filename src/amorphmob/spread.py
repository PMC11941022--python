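"""Species-decomposed spread-RMSD statistic and displacement series.

The central statistic measures the instantaneous *spread* of a binary
lactose/water cell about its mixture centroid.  With N water tracking
points w_i(t), M lactose points l_j(t) and centroid

    mu(t) = (sum_i w_i + sum_j l_j) / (N + M),

per-molecule deviations are

    delta_i(t) = w_i(t) - mu(t)                (water, unscaled)
    delta_j(t) = (l_j(t) - mu(t)) / r          (lactose, size-scaled)

with r the lactose/water molecular size ratio (default 9.08 = 1.18/0.13),
and the spread statistic is

    RMSD(t) = sqrt[ (sum_i |delta_i|^2 + sum_j |delta_j|^2) / (N + M) ].

Note this is a spread about the *instantaneous* centroid, not a
displacement from the t = 0 configuration: its series can decrease when
molecules cluster, which is exactly the signature the two-phase mobility
pathway predicts.  A conventional from-origin mean squared displacement
is provided separately (:func:`msd_from_origin`) for Einstein-relation
diffusion estimates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import LACTOSE, WATER, Frame, Trajectory, trajectory_from_array
from .errors import DomainError

#: molecular sizes used for the default lactose/water size ratio
LACTOSE_SIZE = 1.18
WATER_SIZE = 0.13


def size_ratio(lactose_size: float = LACTOSE_SIZE,
               water_size: float = WATER_SIZE) -> float:
    """Lactose/water molecular size ratio r (default 1.18/0.13 ≈ 9.08)."""
    if lactose_size <= 0 or water_size <= 0:
        raise DomainError("molecular sizes must be positive")
    return lactose_size / water_size


@dataclass(frozen=True)
class AnalysisParams:
    """Parameters of the spread statistic."""

    r: float = 9.08
    unwrap: bool = False

    def __post_init__(self):
        if not self.r > 0:
            raise DomainError("size ratio r must be positive")


@dataclass
class SpreadSeries:
    """The spread statistic (Å) per frame, with the cell composition."""

    times: np.ndarray
    values: np.ndarray
    n_water: int
    n_lactose: int
    species: str = "total"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise DomainError("times and values must have the same length")
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite < 0):
            raise DomainError("spread values must be non-negative")

    @property
    def defined(self) -> bool:
        """False when the requested species is absent from the cell."""
        return bool(np.all(np.isfinite(self.values)))


def mean_position(frame: Frame) -> np.ndarray:
    """Centroid mu(t) of all N + M tracking points of one frame."""
    if frame.n_molecules < 1:
        raise DomainError("mean_position needs at least one molecule")
    return frame.positions.mean(axis=0)


def scaled_deviations(frame: Frame, mu: np.ndarray,
                      params: AnalysisParams = AnalysisParams()) -> np.ndarray:
    """Per-molecule deviations from mu, lactose rows divided by r."""
    if not params.r > 0:
        raise DomainError("size ratio r must be positive")
    dev = frame.positions - np.asarray(mu, dtype=float)
    lactose = frame.species == LACTOSE
    dev[lactose] /= params.r
    return dev


def unwrap_trajectory(traj: Trajectory) -> Trajectory:
    """Remove periodic-image jumps by minimum-image continuity.

    Consecutive-frame differences are mapped into (-L/2, L/2] per axis and
    accumulated, so each molecule's path is continuous; coordinates may
    leave [0, L) afterwards.  Valid while no molecule moves more than half
    a box side between recorded frames.
    """
    L = traj.box_side
    pos = traj.positions_array()
    diffs = np.diff(pos, axis=0)
    diffs -= L * np.round(diffs / L)
    unwrapped = np.concatenate(
        [pos[:1], pos[:1] + np.cumsum(diffs, axis=0)], axis=0)
    return trajectory_from_array(traj.times, unwrapped, traj.species, L,
                                 dt_record=traj.dt_record,
                                 temperature=traj.temperature, cell=traj.cell)


def _spread_values(pos: np.ndarray, water_mask: np.ndarray, r: float,
                   restrict: str | None) -> np.ndarray:
    """Vectorised spread over an (n_frames, n, 3) array."""
    mu = pos.mean(axis=1, keepdims=True)
    dev = pos - mu
    sq = np.einsum("fnd,fnd->fn", dev, dev)
    if restrict is None:
        w = np.where(water_mask, 1.0, 1.0 / r**2)
        return np.sqrt((sq * w).sum(axis=1) / pos.shape[1])
    mask = water_mask if restrict == WATER else ~water_mask
    n_sp = int(mask.sum())
    if n_sp == 0:
        return np.full(pos.shape[0], np.nan)
    scale = 1.0 if restrict == WATER else 1.0 / r**2
    return np.sqrt((sq[:, mask] * scale).sum(axis=1) / n_sp)


def total_rmsd(traj: Trajectory,
               params: AnalysisParams = AnalysisParams()) -> SpreadSeries:
    """The spread statistic of every frame of a trajectory.

    With ``params.unwrap`` the trajectory is first made continuous across
    periodic images; by default wrapped coordinates are used as recorded.
    The series is invariant under any rigid translation of a whole frame.
    """
    if traj.n_molecules < 1:
        raise DomainError("trajectory has no molecules")
    work = unwrap_trajectory(traj) if params.unwrap else traj
    pos = work.positions_array()
    water_mask = work.species == WATER
    values = _spread_values(pos, water_mask, params.r, None)
    return SpreadSeries(times=work.times, values=values,
                        n_water=int(water_mask.sum()),
                        n_lactose=int((~water_mask).sum()))


def per_species_rmsd(traj: Trajectory,
                     params: AnalysisParams = AnalysisParams()
                     ) -> tuple[SpreadSeries, SpreadSeries]:
    """Water-only and lactose-only spread series (same deviations as the
    total statistic, sum and normalisation restricted to one species).

    An absent species yields a series of NaNs with ``defined == False``,
    never silent zeros.
    """
    work = unwrap_trajectory(traj) if params.unwrap else traj
    pos = work.positions_array()
    water_mask = work.species == WATER
    n_w = int(water_mask.sum())
    n_l = int((~water_mask).sum())
    out = []
    for sp in (WATER, LACTOSE):
        values = _spread_values(pos, water_mask, params.r, sp)
        out.append(SpreadSeries(times=work.times, values=values,
                                n_water=n_w, n_lactose=n_l, species=sp))
    return out[0], out[1]


@dataclass
class MSDSeries:
    """From-origin mean squared displacement (Å^2) per frame."""

    times: np.ndarray
    values: np.ndarray
    species: str = "total"


def msd_from_origin(traj: Trajectory, species: str | None = None,
                    unwrap: bool = True) -> MSDSeries:
    """Conventional MSD from the t = 0 configuration.

    ``<|x(t) - x(0)|^2>`` averaged over molecules (optionally one
    species), with periodic unwrapping on by default — the quantity the
    Einstein relation D = slope/6 applies to directly.  No size-ratio
    scaling is applied.
    """
    work = unwrap_trajectory(traj) if unwrap else traj
    pos = work.positions_array()
    if species is not None:
        mask = work.frames[0].mask(species)
        if not mask.any():
            raise DomainError(f"no {species} molecules in trajectory")
        pos = pos[:, mask]
    disp = pos - pos[:1]
    values = np.einsum("fnd,fnd->f", disp, disp) / pos.shape[1]
    return MSDSeries(times=work.times, values=values,
                     species=species or "total")
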