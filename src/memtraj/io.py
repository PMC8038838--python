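"""Structure/trajectory readers and writers plus particle-group assignment.

Parsing of the standard formats (PDB, single-frame GRO, XTC/TRR/DCD) is
delegated to MDAnalysis; everything is converted to the internal nm/ps
convention on the way in.  Multi-frame GRO files (concatenated GRO
blocks, the plain-text trajectory dialect GROMACS emits with
``trjconv``) get a small dedicated reader because MDAnalysis treats a
GRO file as a single frame.

Group assignment classifies every atom into one of the particle groups
used by the contact statistics: protein, water, lipid tails (aliphatic
acyl-chain carbons only), remaining lipid atoms, ions, free ligand
molecules, and "other".
"""

from __future__ import annotations

import fnmatch
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .core import PROTEIN_RESNAMES, Frame, GroupRole, MolecularSystem, Trajectory

__all__ = [
    "load_structure",
    "load_trajectory",
    "write_structure",
    "write_trajectory",
    "SelectionRule",
    "SelectionSpec",
    "default_selection_spec",
    "assign_groups",
    "guess_element",
]

_TWO_LETTER_ELEMENTS = {
    "CL": "Cl", "NA": "Na", "MG": "Mg", "BR": "Br", "FE": "Fe",
    "ZN": "Zn", "CA": "Ca", "MN": "Mn", "CU": "Cu",
}
_ION_NAMES = {"K", "K+", "POT", "NA", "NA+", "SOD", "CL", "CL-", "CLA",
              "MG", "MG2", "CAL", "CA2"}


def guess_element(name: str, resname: str = "") -> str:
    """Guess the element symbol from an atom name.

    Follows the usual PDB heuristic: strip leading digits, then take the
    first letter — except for monatomic ions and a few two-letter
    elements that are recognised by full name.
    """
    stripped = name.lstrip("0123456789 ")
    if not stripped:
        return "X"
    upper = stripped.upper()
    # monatomic ions carry their element as the whole atom/residue name
    if resname.upper() in _ION_NAMES and upper[:2] in _TWO_LETTER_ELEMENTS:
        return _TWO_LETTER_ELEMENTS[upper[:2]]
    if upper in _ION_NAMES and upper[:2] in _TWO_LETTER_ELEMENTS:
        return _TWO_LETTER_ELEMENTS[upper[:2]]
    if upper in ("K", "NA+", "K+"):
        return upper[0] if upper[0] != "N" else "Na"
    return stripped[0].upper()


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _mda_universe(*paths, **kwargs):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(*paths, **kwargs)


def _box_from_dimensions(dimensions) -> np.ndarray:
    """MDAnalysis [lx ly lz alpha beta gamma] (Angstrom) → 3x3 nm matrix."""
    from MDAnalysis.lib import mdamath

    if dimensions is None or np.all(np.asarray(dimensions)[:3] == 0):
        # no box information (e.g. PDB without CRYST1): use a huge box so
        # that minimum-image wrapping is a no-op
        return np.diag([999.0, 999.0, 999.0])
    return np.asarray(mdamath.triclinic_vectors(dimensions), dtype=np.float64) / 10.0


def _system_from_universe(u, source_path: str) -> MolecularSystem:
    atoms = u.atoms
    if len(atoms) == 0:
        raise ValueError(f"{source_path}: file contains zero atoms")
    names = [str(n) for n in atoms.names]
    resnames_atom = [str(r) for r in atoms.resnames]
    elements = [guess_element(n, r) for n, r in zip(names, resnames_atom)]
    resindices = np.asarray(atoms.resindices, dtype=np.int64)
    residues = u.residues
    resnames = [str(r) for r in residues.resnames]
    resseqs = np.asarray(residues.resids, dtype=np.int64)
    try:
        icodes = [str(i) for i in residues.icodes]
    except AttributeError:
        icodes = [""] * len(residues)
    chain_ids = None
    for attr in ("chainIDs", "segids"):
        try:
            vals = getattr(residues, attr)
            chain_ids = [str(v) for v in vals]
            break
        except AttributeError:
            continue
    return MolecularSystem(
        names=names,
        elements=elements,
        residue_indices=resindices,
        residue_names=resnames,
        residue_seqs=resseqs,
        residue_icodes=icodes,
        chain_ids=chain_ids,
        source_path=source_path,
    )


def load_structure(path: str | Path, dialect: str | None = None) -> MolecularSystem:
    """Read a PDB or GRO structure file into a :class:`MolecularSystem`.

    ``dialect`` may be ``"pdb"`` or ``"gro"``; by default it is inferred
    from the file suffix.  Group roles are *not* assigned here — run
    :func:`assign_groups` afterwards.
    """
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower()
    if dialect not in ("pdb", "gro"):
        raise ValueError(f"unsupported structure dialect: {dialect!r}")
    try:
        u = _mda_universe(str(path), format=dialect)
    except Exception as exc:  # surface parser context
        raise ValueError(f"failed to parse {path} as {dialect}: {exc}") from exc
    return _system_from_universe(u, str(path))


def load_frame(path: str | Path, dialect: str | None = None) -> Frame:
    """Read the (first) frame of coordinates from a structure file, in nm."""
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower()
    u = _mda_universe(str(path), format=dialect)
    ts = u.trajectory[0]
    return Frame(
        coordinates=np.asarray(u.atoms.positions, dtype=np.float64) / 10.0,
        box=_box_from_dimensions(ts.dimensions),
        time=0.0,
    )


def _read_multigro(path: Path) -> list[Frame]:
    frames = []
    with open(path) as fh:
        while True:
            title = fh.readline()
            if not title:
                break
            if not title.strip():
                continue
            time = 0.0
            if "t=" in title:
                try:
                    time = float(title.split("t=")[1].split()[0])
                except (IndexError, ValueError):
                    pass
            natoms = int(fh.readline())
            coords = np.empty((natoms, 3))
            for i in range(natoms):
                line = fh.readline()
                coords[i] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            boxvals = [float(x) for x in fh.readline().split()]
            if len(boxvals) >= 9:
                lx, ly, lz = boxvals[0], boxvals[1], boxvals[2]
                box = np.array(
                    [[lx, boxvals[3], boxvals[4]],
                     [boxvals[5], ly, boxvals[6]],
                     [boxvals[7], boxvals[8], lz]]
                )
            else:
                box = np.diag(boxvals[:3])
            frames.append(Frame(coordinates=coords, box=box, time=time))
    return frames


_BINARY_FORMATS = ("xtc", "trr", "dcd")


def load_trajectory(
    path: str | Path,
    system: MolecularSystem,
    format: str | None = None,
    dt: float | None = None,
) -> Trajectory:
    """Read a trajectory against an existing system.

    Supported formats: ``xtc``/``trr``/``dcd`` (binary, read through the
    system's source structure file), ``multipdb`` (multi-MODEL PDB) and
    ``multigro`` (concatenated GRO blocks).  Coordinates are converted
    to nm whatever the source convention (PDB and DCD are in Angstrom).

    ``dt`` (ps) overrides the frame interval for formats that do not
    store physical times (multi-model PDB; DCD headers are unreliable).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lstrip(".").lower()
        format = {"pdb": "multipdb", "gro": "multigro"}.get(suffix, suffix)

    if format == "multigro":
        frames = _read_multigro(path)
    elif format in ("multipdb",) + _BINARY_FORMATS:
        if format == "multipdb":
            u = _mda_universe(str(path), format="pdb")
        else:
            if system.source_path is None:
                raise ValueError(
                    f"reading {format} requires a system loaded from a structure file"
                )
            u = _mda_universe(system.source_path, str(path), format=format)
        frames = []
        for k, ts in enumerate(u.trajectory):
            if ts.n_atoms != system.n_atoms:
                raise ValueError(
                    f"frame {k} of {path} has {ts.n_atoms} atoms, "
                    f"system has {system.n_atoms}"
                )
            time = float(ts.time) if format in _BINARY_FORMATS else float(k)
            frames.append(
                Frame(
                    coordinates=np.asarray(u.atoms.positions, np.float64) / 10.0,
                    box=_box_from_dimensions(ts.dimensions),
                    time=time,
                )
            )
    else:
        raise ValueError(f"unsupported trajectory format: {format!r}")

    if len(frames) == 0:
        raise ValueError(f"{path}: no frames read")
    for k, fr in enumerate(frames):
        if fr.n_atoms != system.n_atoms:
            raise ValueError(
                f"frame {k} of {path} has {fr.n_atoms} atoms, "
                f"system has {system.n_atoms}"
            )
    if dt is not None:
        t0 = frames[0].time if format in _BINARY_FORMATS else 0.0
        for k, fr in enumerate(frames):
            fr.time = t0 + k * dt
    return Trajectory(system, frames)


# ---------------------------------------------------------------------------
# writing (plain-text formats only)
# ---------------------------------------------------------------------------

def _gro_box_line(box: np.ndarray) -> str:
    if np.allclose(box, np.diag(np.diag(box))):
        return "%10.5f%10.5f%10.5f\n" % (box[0, 0], box[1, 1], box[2, 2])
    vals = (box[0, 0], box[1, 1], box[2, 2], 0.0, 0.0,
            box[1, 0], 0.0, box[2, 0], box[2, 1])
    return ("%10.5f" * 9 % vals) + "\n"


def _write_gro_block(fh, system: MolecularSystem, frame: Frame, title: str) -> None:
    fh.write(f"{title} t= {frame.time:.5f}\n")
    fh.write(f"{system.n_atoms:5d}\n")
    for i in range(system.n_atoms):
        ri = system.residue_indices[i]
        fh.write(
            "%5d%-5s%5s%5d%8.3f%8.3f%8.3f\n"
            % (
                int(system.residue_seqs[ri]) % 100000,
                str(system.residue_names[ri])[:5],
                str(system.names[i])[:5],
                (i + 1) % 100000,
                frame.coordinates[i, 0],
                frame.coordinates[i, 1],
                frame.coordinates[i, 2],
            )
        )
    fh.write(_gro_box_line(frame.box))


def _pdb_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return (" " + name).ljust(4)
    return name.ljust(4)


def _write_pdb_frames(fh, system: MolecularSystem, frames: Sequence[Frame]) -> None:
    box = frames[0].box
    from MDAnalysis.lib import mdamath

    lx, ly, lz, a, b, g = mdamath.triclinic_box(*(box * 10.0))
    fh.write(
        "CRYST1%9.3f%9.3f%9.3f%7.2f%7.2f%7.2f P 1           1\n"
        % (lx, ly, lz, a, b, g)
    )
    multi = len(frames) > 1
    for m, frame in enumerate(frames, start=1):
        if multi:
            fh.write(f"MODEL     {m:4d}\n")
        xyz = frame.coordinates * 10.0
        for i in range(system.n_atoms):
            ri = system.residue_indices[i]
            fh.write(
                "ATOM  %5d %s %-4s%1s%4d%1s   %8.3f%8.3f%8.3f%6.2f%6.2f          %2s\n"
                % (
                    (i + 1) % 100000,
                    _pdb_atom_name(str(system.names[i]), str(system.elements[i])),
                    str(system.residue_names[ri])[:4],
                    str(system.chain_ids[ri])[:1],
                    int(system.residue_seqs[ri]) % 10000,
                    str(system.residue_icodes[ri])[:1],
                    xyz[i, 0], xyz[i, 1], xyz[i, 2],
                    1.0, 0.0,
                    str(system.elements[i])[:2],
                )
            )
        if multi:
            fh.write("ENDMDL\n")
    fh.write("END\n")


def write_structure(
    path: str | Path,
    system: MolecularSystem,
    frame: Frame,
    dialect: str | None = None,
    title: str = "memtraj snapshot",
) -> None:
    """Write a single-frame PDB or GRO snapshot (dialect from suffix)."""
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower()
    with open(path, "w") as fh:
        if dialect == "gro":
            _write_gro_block(fh, system, frame, title)
        elif dialect == "pdb":
            _write_pdb_frames(fh, system, [frame])
        else:
            raise ValueError(f"unsupported structure dialect: {dialect!r}")


def write_trajectory(
    path: str | Path,
    traj: Trajectory,
    format: str | None = None,
    title: str = "memtraj trajectory",
) -> None:
    """Write a trajectory as multi-frame GRO, multi-model PDB, or XTC."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lstrip(".").lower()
        format = {"pdb": "multipdb", "gro": "multigro"}.get(suffix, suffix)
    if format == "multigro":
        with open(path, "w") as fh:
            for frame in traj:
                _write_gro_block(fh, traj.system, frame, title)
    elif format == "multipdb":
        with open(path, "w") as fh:
            _write_pdb_frames(fh, traj.system, traj.frames)
    elif format == "xtc":
        import MDAnalysis as mda
        from MDAnalysis.coordinates.XTC import XTCWriter
        from MDAnalysis.lib import mdamath

        n_atoms = traj.system.n_atoms
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe.empty(n_atoms, trajectory=True)
        with XTCWriter(str(path), n_atoms=n_atoms) as w:
            for k, frame in enumerate(traj):
                ts = u.trajectory.ts
                u.atoms.positions = frame.coordinates * 10.0
                ts.dimensions = mdamath.triclinic_box(*(frame.box * 10.0))
                ts.time = frame.time
                ts.frame = k
                w.write(u.atoms)
    else:
        raise ValueError(f"unsupported trajectory format: {format!r}")


# ---------------------------------------------------------------------------
# particle-group assignment
# ---------------------------------------------------------------------------

@dataclass
class SelectionRule:
    """One pattern → role rule; ``fnmatch`` patterns, case-insensitive.

    Omitted fields match anything; the first matching rule wins.
    """

    role: GroupRole
    resname: str | None = None
    name: str | None = None
    element: str | None = None

    def matches(self, resname: str, name: str, element: str) -> bool:
        for pattern, value in (
            (self.resname, resname),
            (self.name, name),
            (self.element, element),
        ):
            if pattern is not None and not fnmatch.fnmatch(
                value.upper(), pattern.upper()
            ):
                return False
        return True


@dataclass
class SelectionSpec:
    """Ordered rule list mapping atoms to particle groups.

    ``warn_unmatched`` controls the warning on rules that match no atom
    (useful for user-written specs; the built-in default spec covers
    many residue-name dialects and keeps it off).
    """

    rules: list[SelectionRule] = field(default_factory=list)
    warn_unmatched: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SelectionSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        rules = [
            SelectionRule(
                role=GroupRole(r["role"]),
                resname=r.get("resname"),
                name=r.get("name"),
                element=r.get("element"),
            )
            for r in data.get("rules", [])
        ]
        return cls(rules=rules)


#: CHARMM-style acyl-chain carbon names: C22..C29/C210..C219 (sn-2 chain)
#: and C32..C39/C310..C319 (sn-1 chain).  C21/C31 are the ester carbonyl
#: carbons and are excluded — the tails group is aliphatic carbons only.
_TAIL_CARBON_PATTERNS = ("C[2345][2-9]", "C[2345]1[0-9]")
_LIPID_RESNAMES = ("POP*", "TMCL*", "CDL*", "CARD", "DPP*", "DOP*", "DMP*")
_WATER_RESNAMES = ("SOL", "TIP3", "TIP3P", "TIP4", "TIP4P", "HOH", "WAT", "SPC", "SPCE", "W")


def default_selection_spec() -> SelectionSpec:
    """Rules for a CHARMM-style membrane system (POPG/POPE/cardiolipin,
    TIP3P water, K+/Cl- ions)."""
    rules: list[SelectionRule] = []
    for rn in _WATER_RESNAMES:
        rules.append(SelectionRule(GroupRole.WATER, resname=rn))
    for rn in sorted(_ION_NAMES):
        rules.append(SelectionRule(GroupRole.ION, resname=rn))
    for rn in _LIPID_RESNAMES:
        for pat in _TAIL_CARBON_PATTERNS:
            rules.append(SelectionRule(GroupRole.LIPID_TAIL, resname=rn, name=pat))
        rules.append(SelectionRule(GroupRole.LIPID_OTHER, resname=rn))
    return SelectionSpec(rules=rules, warn_unmatched=False)


_PEPTIDE_BOND_CUTOFF = 0.2  # nm; C(i)-N(i+1) is ~0.133 nm when bonded


def _protein_molecules(
    system: MolecularSystem, frame: Frame | None
) -> list[list[int]]:
    """Group amino-acid residues into connected molecules.

    Residues are chained together when they are consecutive in file
    order, share a chain ID, and — when coordinates are available — the
    peptide C(i)–N(i+1) distance is bond-like.
    """
    from .geometry import min_image_distance

    amino = [
        ri
        for ri in range(system.n_residues)
        if str(system.residue_names[ri]).upper() in PROTEIN_RESNAMES
    ]
    molecules: list[list[int]] = []
    for ri in amino:
        if molecules and molecules[-1][-1] == ri - 1 and (
            system.chain_ids[ri] == system.chain_ids[molecules[-1][-1]]
        ):
            c = system.find_atom(ri - 1, "C")
            n = system.find_atom(ri, "N")
            # without backbone C and N no peptide bond is possible
            bonded = c is not None and n is not None
            if bonded and frame is not None:
                d = min_image_distance(
                    frame.coordinates[c], frame.coordinates[n], frame.box
                )
                bonded = d < _PEPTIDE_BOND_CUTOFF
            if bonded:
                molecules[-1].append(ri)
                continue
        molecules.append([ri])
    return molecules


def assign_groups(
    system: MolecularSystem,
    spec: SelectionSpec | None = None,
    frame: Frame | None = None,
) -> MolecularSystem:
    """Return a copy of ``system`` with every atom's group role assigned.

    Protein vs. free amino-acid ligand is decided structurally first: a
    chain of two or more peptide-connected amino-acid residues is
    protein; an isolated single amino-acid residue is a ligand (a free
    amino acid such as L-alanine is chemically identical to a protein
    residue, so residue names cannot distinguish them).  Passing the
    ``frame`` lets the peptide-bond check use actual geometry.  The
    remaining atoms are classified by the first matching selection rule;
    unmatched atoms keep the role "other".
    """
    if spec is None:
        spec = default_selection_spec()
    out = system.copy()
    out.roles[:] = GroupRole.OTHER.value

    molecules = _protein_molecules(system, frame)
    protein_molecules = []
    for molecule in molecules:
        role = GroupRole.PROTEIN if len(molecule) > 1 else GroupRole.LIGAND
        if role is GroupRole.PROTEIN:
            protein_molecules.append(molecule)
        for ri in molecule:
            out.roles[system.residue_atoms(ri)] = role.value

    # formats without chain records (GRO) leave every residue in one
    # chain; give each peptide-connected protein molecule its own chain
    # id so downstream per-chain logic (i→i+4 pairing) sees the breaks
    if len(protein_molecules) > 1:
        ids = {str(system.chain_ids[m[0]]) for m in protein_molecules}
        if len(ids) == 1:
            for m, molecule in enumerate(protein_molecules):
                for ri in molecule:
                    out.chain_ids[ri] = f"P{m + 1}"

    unassigned = out.roles == GroupRole.OTHER.value
    for rule in spec.rules:
        hit_any = False
        for i in np.flatnonzero(unassigned):
            ri = system.residue_indices[i]
            if rule.matches(
                str(system.residue_names[ri]),
                str(system.names[i]),
                str(system.elements[i]),
            ):
                out.roles[i] = GroupRole(rule.role).value
                unassigned[i] = False
                hit_any = True
        if not hit_any and spec.warn_unmatched:
            warnings.warn(f"selection rule matched no atoms: {rule}")
    return out
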