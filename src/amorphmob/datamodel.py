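"""Core containers: per-frame tracking coordinates and trajectories.

The analysis layer works on one tracking point per molecule (the oxygen
atom nearest the molecule's geometric center), so a frame is just an
(n, 3) coordinate array, a parallel species-label array, a cubic box side
and a time stamp.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import DomainError

#: canonical species labels
WATER = "water"
LACTOSE = "lactose"
SPECIES = (WATER, LACTOSE)

#: file tags used in extended-XYZ records
SPECIES_TAG = {WATER: "W", LACTOSE: "L"}
TAG_SPECIES = {v: k for k, v in SPECIES_TAG.items()}


@dataclass
class Frame:
    """Tracking coordinates of every molecule at one time point.

    positions are in Å inside a cubic periodic box of side ``box_side``;
    ``species`` is a parallel array of ``"water"`` / ``"lactose"`` labels.
    """

    time: float
    positions: np.ndarray
    species: np.ndarray
    box_side: float
    _allow_empty: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.species = np.asarray(self.species, dtype=object)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise DomainError("positions must be an (n, 3) array")
        if self.positions.shape[0] != self.species.shape[0]:
            raise DomainError("positions and species must have equal length")
        if self.positions.shape[0] < 1 and not self._allow_empty:
            raise DomainError("a frame must contain at least one molecule")
        if not np.all(np.isfinite(self.positions)):
            raise DomainError("coordinates must be finite")
        if not self.box_side > 0:
            raise DomainError("box_side must be positive")
        unknown = set(self.species) - set(SPECIES)
        if unknown:
            raise DomainError(f"unknown species labels: {sorted(unknown)}")

    @classmethod
    def empty(cls, box_side: float, time: float = 0.0) -> "Frame":
        """Dedicated constructor for a molecule-free box (degenerate fixture)."""
        return cls(time=time, positions=np.empty((0, 3)),
                   species=np.empty(0, dtype=object), box_side=box_side,
                   _allow_empty=True)

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[0]

    def mask(self, species: str) -> np.ndarray:
        if species not in SPECIES:
            raise DomainError(f"unknown species {species!r}")
        return self.species == species


@dataclass
class Trajectory:
    """An ordered sequence of frames sharing molecule count, labels and box."""

    frames: list[Frame]
    dt_record: float | None = None
    temperature: float | None = None
    cell: "object | None" = None  # CellSpec, kept loose to avoid a cycle

    def __post_init__(self):
        if len(self.frames) < 1:
            raise DomainError("a trajectory must contain at least one frame")
        ref = self.frames[0]
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise DomainError("frame times must be strictly increasing")
        for i, f in enumerate(self.frames):
            if f.n_molecules != ref.n_molecules:
                raise DomainError(
                    f"frame {i} has {f.n_molecules} molecules, "
                    f"frame 0 has {ref.n_molecules}")
            if not np.array_equal(f.species, ref.species):
                raise DomainError(f"frame {i} species labels differ from frame 0")
            if f.box_side != ref.box_side:
                raise DomainError(f"frame {i} box side differs from frame 0")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def box_side(self) -> float:
        return self.frames[0].box_side

    @property
    def species(self) -> np.ndarray:
        return self.frames[0].species

    @property
    def n_molecules(self) -> int:
        return self.frames[0].n_molecules

    def positions_array(self) -> np.ndarray:
        """All coordinates as an (n_frames, n_molecules, 3) array."""
        return np.stack([f.positions for f in self.frames])


def trajectory_from_array(times: Sequence[float], positions: np.ndarray,
                          species: Sequence[str], box_side: float,
                          **kwargs) -> Trajectory:
    """Build a Trajectory from an (n_frames, n_molecules, 3) array."""
    positions = np.asarray(positions, dtype=float)
    species = np.asarray(species, dtype=object)
    frames = [Frame(time=float(t), positions=positions[i], species=species,
                    box_side=box_side) for i, t in enumerate(times)]
    return Trajectory(frames=frames, **kwargs)
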