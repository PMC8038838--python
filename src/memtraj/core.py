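"""Core data model: atoms, systems, frames and trajectories.

All coordinates are in nanometres and all times in picoseconds,
matching the native units of the GRO/XTC family of formats and every
analysis threshold used downstream (contact cutoff 0.4 nm, hydrogen-bond
distance 0.35 nm, frame interval 10 ps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "GroupRole",
    "Atom",
    "MolecularSystem",
    "Frame",
    "Trajectory",
    "PROTEIN_RESNAMES",
]


class GroupRole(str, Enum):
    """Particle-group classification used by every contact statistic.

    The roles mirror the components of a membrane-protein simulation box:
    the protein itself, water, the aliphatic carbons of the lipid tails,
    the remaining (head-group) lipid atoms, monatomic ions, a free
    small-molecule ligand (e.g. L-alanine), and everything else.
    """

    PROTEIN = "protein"
    WATER = "water"
    LIPID_TAIL = "lipid_tail"
    LIPID_OTHER = "lipid_other"
    ION = "ion"
    LIGAND = "ligand"
    OTHER = "other"


#: Three-letter codes treated as amino acids when partitioning the system.
PROTEIN_RESNAMES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS HSD HSE HSP ILE LEU LYS MET
       PHE PRO SER THR TRP TYR VAL MSE""".split()
)


@dataclass(frozen=True)
class Atom:
    """Lightweight per-atom view into a :class:`MolecularSystem`."""

    index: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    residue_seq: int
    group_role: GroupRole


class MolecularSystem:
    """Topology-level description of the simulated system.

    Stores per-atom attributes as flat numpy arrays (the natural layout
    for the vectorised distance machinery) and a derived residue table.
    """

    def __init__(
        self,
        names: Sequence[str],
        elements: Sequence[str],
        residue_indices: Sequence[int],
        residue_names: Sequence[str],
        residue_seqs: Sequence[int],
        residue_icodes: Sequence[str] | None = None,
        chain_ids: Sequence[str] | None = None,
        roles: Sequence[str] | None = None,
        source_path: str | None = None,
    ) -> None:
        n = len(names)
        if n == 0:
            raise ValueError("a MolecularSystem must contain at least one atom")
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.residue_indices = np.asarray(residue_indices, dtype=np.int64)
        if len(self.residue_indices) != n:
            raise ValueError("residue_indices length mismatch")
        if np.any(np.diff(self.residue_indices) < 0):
            raise ValueError("residue_index must be non-decreasing in atom order")
        nres = int(self.residue_indices.max()) + 1
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_seqs = np.asarray(residue_seqs, dtype=np.int64)
        if len(self.residue_names) != nres or len(self.residue_seqs) != nres:
            raise ValueError("residue table length mismatch")
        self.residue_icodes = (
            np.asarray(residue_icodes, dtype=object)
            if residue_icodes is not None
            else np.full(nres, "", dtype=object)
        )
        self.chain_ids = (
            np.asarray(chain_ids, dtype=object)
            if chain_ids is not None
            else np.full(nres, "A", dtype=object)
        )
        if roles is None:
            roles = [GroupRole.OTHER.value] * n
        self.roles = np.asarray([GroupRole(r).value for r in roles], dtype=object)
        self.source_path = source_path
        # residue → [first, last) atom span; atoms of a residue are contiguous
        starts = np.flatnonzero(np.r_[True, np.diff(self.residue_indices) != 0])
        if len(starts) != nres:
            raise ValueError("atoms of each residue must be contiguous in file order")
        self.residue_starts = starts
        self.residue_ends = np.r_[starts[1:], n]

    # -- basic introspection ------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    def atom(self, i: int) -> Atom:
        ri = int(self.residue_indices[i])
        return Atom(
            index=i,
            name=str(self.names[i]),
            element=str(self.elements[i]),
            residue_index=ri,
            residue_name=str(self.residue_names[ri]),
            residue_seq=int(self.residue_seqs[ri]),
            group_role=GroupRole(self.roles[i]),
        )

    def __iter__(self) -> Iterator[Atom]:
        return (self.atom(i) for i in range(self.n_atoms))

    def __len__(self) -> int:
        return self.n_atoms

    def residue_atoms(self, residue_index: int) -> np.ndarray:
        """Atom indices of one residue (contiguous span)."""
        return np.arange(
            self.residue_starts[residue_index], self.residue_ends[residue_index]
        )

    # -- group bookkeeping --------------------------------------------------

    def group_atoms(self, role: GroupRole | str, heavy_only: bool = False) -> np.ndarray:
        """Atom indices carrying a given group role.

        With ``heavy_only`` hydrogens are dropped, for distance
        definitions restricted to heavy atoms.
        """
        role = GroupRole(role).value
        mask = self.roles == role
        if heavy_only:
            mask &= self.elements != "H"
        return np.flatnonzero(mask)

    def residue_role(self, residue_index: int) -> GroupRole:
        """Majority role of a residue's atoms (they are uniform in practice)."""
        span = self.residue_atoms(residue_index)
        vals, counts = np.unique(self.roles[span].astype(str), return_counts=True)
        return GroupRole(vals[np.argmax(counts)])

    @property
    def protein_residues(self) -> np.ndarray:
        """Residue indices whose atoms are classified as protein."""
        res = self.residue_indices[self.roles == GroupRole.PROTEIN.value]
        return np.unique(res)

    @property
    def n_protein_residues(self) -> int:
        return len(self.protein_residues)

    def find_atom(self, residue_index: int, name: str) -> int | None:
        """Index of the atom called ``name`` in a residue, or None."""
        span = self.residue_atoms(residue_index)
        hits = span[self.names[span] == name]
        return int(hits[0]) if len(hits) else None

    def copy(self) -> "MolecularSystem":
        return MolecularSystem(
            names=self.names.copy(),
            elements=self.elements.copy(),
            residue_indices=self.residue_indices.copy(),
            residue_names=self.residue_names.copy(),
            residue_seqs=self.residue_seqs.copy(),
            residue_icodes=self.residue_icodes.copy(),
            chain_ids=self.chain_ids.copy(),
            roles=self.roles.copy(),
            source_path=self.source_path,
        )


@dataclass
class Frame:
    """A single configuration: coordinates (nm), triclinic box (nm), time (ps).

    The box is a 3x3 matrix of row lattice vectors in the reduced
    triclinic convention (upper-triangular zeros, positive diagonal).
    """

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.box.shape == (3,):
            self.box = np.diag(self.box)
        if self.box.shape != (3, 3):
            raise ValueError("box must be a 3x3 matrix or 3 orthorhombic lengths")
        if np.any(np.diag(self.box) <= 0):
            raise ValueError("box diagonal must be positive")
        if self.time < 0:
            raise ValueError("time must be non-negative")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


class Trajectory:
    """Time-ordered frames over one :class:`MolecularSystem`.

    Frames must be uniformly spaced in time; ``dt`` is the frame
    interval in ps (0 for a single-frame trajectory).
    """

    def __init__(self, system: MolecularSystem, frames: Sequence[Frame]) -> None:
        if len(frames) == 0:
            raise ValueError("a trajectory needs at least one frame")
        for k, fr in enumerate(frames):
            if fr.n_atoms != system.n_atoms:
                raise ValueError(
                    f"frame {k} has {fr.n_atoms} atoms, system has {system.n_atoms}"
                )
        times = np.array([fr.time for fr in frames], dtype=np.float64)
        if len(times) > 1:
            diffs = np.diff(times)
            if np.any(diffs <= 0):
                raise ValueError("frame times must be strictly increasing")
            dt = diffs[0]
            if np.any(np.abs(diffs - dt) > 1e-6 * max(dt, 1.0)):
                raise ValueError("frame interval is not uniform")
            self.dt = float(dt)
        else:
            warnings.warn("single-frame trajectory: dt undefined, stored as 0")
            self.dt = 0.0
        self.system = system
        self.frames = list(frames)
        self.times = times

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def analyzed_indices(self, start_time: float = 0.0) -> np.ndarray:
        """Frame indices with time >= start_time (the analysis window)."""
        idx = np.flatnonzero(self.times >= start_time - 1e-9)
        if len(idx) == 0:
            raise ValueError(
                f"start_time {start_time} ps is beyond the trajectory end "
                f"({self.times[-1]} ps)"
            )
        return idx

    def sliced(self, indices: Sequence[int]) -> "Trajectory":
        """New trajectory restricted to the given frame indices."""
        return Trajectory(self.system, [self.frames[i] for i in indices])

    def coordinate_array(self) -> np.ndarray:
        """Stacked (n_frames, n_atoms, 3) coordinate array."""
        return np.stack([fr.coordinates for fr in self.frames])
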