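"""Core containers: residue topology, Cα trajectories and residue selections.

Everything in this package works on a Cα-per-residue representation: the
statistics computed downstream (fluctuation correlations, virtual-bond
autocorrelations, RMSD, clustering, PCA) are residue-level quantities, and
the virtual backbone bond vectors are defined between successive Cα atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Residue", "Topology", "Trajectory", "SelectionMask", "join_trajectories"]


@dataclass(frozen=True)
class Residue:
    """One residue: chain identifier, author residue number, 3-letter name."""

    chain_id: str
    number: int
    name: str = "ALA"

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.number}"


class Topology:
    """Ordered list of residues (one Cα each) shared by every frame.

    Residue order is fixed; each chain occupies one contiguous index range
    and ``(chain_id, number)`` pairs are unique.  Internal indexing is
    0-based and contiguous regardless of author residue numbering (which may
    be negative, as in the SUMO N-terminal tail).
    """

    def __init__(self, residues: Sequence[Residue]):
        residues = list(residues)
        if not residues:
            raise ValueError("a topology needs at least one residue")
        seen = set()
        for r in residues:
            key = (r.chain_id, r.number)
            if key in seen:
                raise ValueError(f"duplicate residue {r.label}")
            seen.add(key)
        offsets: dict[str, tuple[int, int]] = {}
        start = 0
        for i, r in enumerate(residues):
            if r.chain_id not in offsets:
                offsets[r.chain_id] = (i, i + 1)
                start = i
            else:
                lo, hi = offsets[r.chain_id]
                if hi != i:
                    raise ValueError(
                        f"chain {r.chain_id!r} is not contiguous in residue order"
                    )
                offsets[r.chain_id] = (lo, i + 1)
        self.residues: tuple[Residue, ...] = tuple(residues)
        self.chain_offsets: dict[str, tuple[int, int]] = offsets
        self._index = {(r.chain_id, r.number): i for i, r in enumerate(residues)}

    def __len__(self) -> int:
        return len(self.residues)

    def __eq__(self, other) -> bool:
        return isinstance(other, Topology) and self.residues == other.residues

    def __hash__(self):
        return hash(self.residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chain_offsets)

    @property
    def labels(self) -> list[str]:
        """``chain:resnum`` labels in residue order (row/column labels)."""
        return [r.label for r in self.residues]

    def index_of(self, chain_id: str, number: int) -> int:
        try:
            return self._index[(chain_id, number)]
        except KeyError:
            raise KeyError(f"no residue {chain_id}:{number} in topology") from None

    def chain_indices(self, chain_id: str) -> np.ndarray:
        if chain_id not in self.chain_offsets:
            raise KeyError(f"no chain {chain_id!r} in topology")
        lo, hi = self.chain_offsets[chain_id]
        return np.arange(lo, hi)


class SelectionMask:
    """Sorted, duplicate-free residue indices into a topology.

    Build from chains, author residue-number ranges, or explicit indices;
    masks support union and difference so alignment selections can exclude
    flexible regions (e.g. a disordered terminal tail).
    """

    def __init__(self, topology: Topology, indices: Iterable[int]):
        idx = np.unique(np.asarray(list(indices), dtype=np.intp))
        if idx.size and (idx[0] < 0 or idx[-1] >= len(topology)):
            raise IndexError("selection index out of topology range")
        self.topology = topology
        self.indices = idx

    # -- constructors -------------------------------------------------
    @classmethod
    def all(cls, topology: Topology) -> "SelectionMask":
        return cls(topology, range(len(topology)))

    @classmethod
    def from_chain(cls, topology: Topology, *chain_ids: str) -> "SelectionMask":
        idx: list[int] = []
        for c in chain_ids:
            idx.extend(topology.chain_indices(c))
        return cls(topology, idx)

    @classmethod
    def from_residue_range(
        cls, topology: Topology, chain_id: str, first: int, last: int
    ) -> "SelectionMask":
        """Residues of ``chain_id`` with author numbers in [first, last]."""
        idx = [
            i
            for i in topology.chain_indices(chain_id)
            if first <= topology.residues[i].number <= last
        ]
        if not idx:
            raise ValueError(f"empty range {chain_id}:{first}-{last}")
        return cls(topology, idx)

    @classmethod
    def from_residues(
        cls, topology: Topology, residues: Iterable[tuple[str, int]]
    ) -> "SelectionMask":
        return cls(topology, [topology.index_of(c, n) for c, n in residues])

    # -- set algebra --------------------------------------------------
    def union(self, other: "SelectionMask") -> "SelectionMask":
        return SelectionMask(self.topology, np.union1d(self.indices, other.indices))

    def minus(self, other: "SelectionMask | None") -> "SelectionMask":
        if other is None:
            return self
        return SelectionMask(self.topology, np.setdiff1d(self.indices, other.indices))

    def __len__(self) -> int:
        return int(self.indices.size)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SelectionMask)
            and self.topology == other.topology
            and np.array_equal(self.indices, other.indices)
        )

    @property
    def labels(self) -> list[str]:
        return [self.topology.residues[i].label for i in self.indices]


@dataclass
class Trajectory:
    """frames × residues × 3 Cα coordinates (Å) with frame times (ns).

    ``equilibration_end`` marks the equilibration period: frames at or
    before that time are flagged, never deleted, so one trajectory serves
    both full and equilibrated analyses.  Frame times start at one frame
    interval (the first recorded snapshot follows the first integration
    block), so the default marker of 0 ns flags nothing.
    """

    topology: Topology
    coordinates: np.ndarray
    frame_times: np.ndarray
    equilibration_end: float = 0.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, residues, 3)")
        if self.coordinates.shape[1] != len(self.topology):
            raise ValueError(
                f"coordinate residue axis ({self.coordinates.shape[1]}) does not "
                f"match topology ({len(self.topology)} residues)"
            )
        if self.coordinates.shape[0] == 0:
            raise ValueError("trajectory has no frames")
        if self.frame_times.shape != (self.coordinates.shape[0],):
            raise ValueError("frame_times length must equal frame count")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.equilibration_end < 0:
            raise ValueError("equilibration_end must be >= 0")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return int(self.coordinates.shape[0])

    @property
    def n_residues(self) -> int:
        return int(self.coordinates.shape[1])

    def usable(self, exclude_equilibration: bool = True) -> np.ndarray:
        """Boolean mask of frames usable for statistics."""
        if not exclude_equilibration:
            return np.ones(self.n_frames, dtype=bool)
        return self.frame_times > self.equilibration_end

    def usable_coordinates(self, exclude_equilibration: bool = True) -> np.ndarray:
        return self.coordinates[self.usable(exclude_equilibration)]

    def frame_interval(self) -> float:
        """Common frame spacing in ns; raises if spacing is non-uniform."""
        dt = np.diff(self.frame_times)
        if dt.size == 0:
            raise ValueError("single-frame trajectory has no frame interval")
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("frame times are not uniformly spaced")
        return float(dt[0])

    def with_coordinates(self, coordinates: np.ndarray) -> "Trajectory":
        return Trajectory(
            self.topology, coordinates, self.frame_times.copy(), self.equilibration_end
        )


def join_trajectories(first: Trajectory, second: Trajectory) -> Trajectory:
    """Concatenate two same-topology trajectories into one continuous one.

    The second segment's times are shifted so the joined time axis keeps the
    first segment's spacing; the equilibration marker of the first segment
    is retained.  Useful for composing piecewise-stationary scenarios such
    as a correlation structure that switches mid-run.
    """
    if first.topology != second.topology:
        raise ValueError("trajectories must share a topology")
    dt = first.frame_interval()
    shifted = second.frame_times - second.frame_times[0] + first.frame_times[-1] + dt
    return Trajectory(
        first.topology,
        np.concatenate([first.coordinates, second.coordinates]),
        np.concatenate([first.frame_times, shifted]),
        first.equilibration_end,
    )
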