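"""Structures, trajectories, atom selections, PDB I/O, and rigid-body superposition.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of :class:`Atom` records (topology), and a :class:`Trajectory` pairs one
topology with an ``(F, A, 3)`` coordinate array in Ångström.  Multi-model PDB
files map one MODEL block to one frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Selection",
    "PDBParseError",
    "STANDARD_AMINO_ACIDS",
    "read_pdb",
    "read_pdb_file",
    "write_pdb",
    "select_calpha",
    "select_atoms",
    "kabsch_superpose",
    "kabsch_rotation",
]

#: Three-letter codes treated as standard amino acids for Cα selection.
STANDARD_AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL SEC PYL MSE HID HIE HIP CYX ASH GLH LYN""".split()
)


class PDBParseError(ValueError):
    """Raised for malformed PDB text or inconsistent multi-model blocks."""


@dataclass(frozen=True)
class Atom:
    """One atom record.

    ``residue_seq`` keeps the author numbering from the file; an insertion
    code, when present, is appended to the residue key used for grouping.
    """

    serial: int
    name: str
    element: str
    residue_seq: int
    residue_name: str
    chain_id: str
    coords: np.ndarray
    insertion_code: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial} has invalid coordinates {coords}")
        object.__setattr__(self, "coords", coords)

    @property
    def residue_key(self) -> tuple[str, str]:
        """(chain, residue) key, e.g. ``('A', '135')`` or ``('A', '52A')``."""
        return self.chain_id, f"{self.residue_seq}{self.insertion_code}"

    @property
    def residue_label(self) -> str:
        """Human-readable residue label, e.g. ``A:ARG135``."""
        return f"{self.chain_id}:{self.residue_name}{self.residue_seq}{self.insertion_code}"


@dataclass
class Structure:
    """An ordered collection of atoms with a title."""

    atoms: list[Atom]
    title: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a Structure requires at least one atom")
        seen = set()
        for atom in self.atoms:
            key = (atom.chain_id, atom.residue_seq, atom.insertion_code, atom.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in structure")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(A, 3) coordinate array."""
        return np.array([a.coords for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coords=c) for a, c in zip(self.atoms, coords)]
        return Structure(atoms=atoms, title=self.title)

    def residues(self) -> list[tuple[tuple[str, str], str, list[int]]]:
        """Group atoms by residue, preserving file order.

        Returns ``[(residue_key, residue_name, atom_indices), ...]``.
        """
        order: list[tuple[str, str]] = []
        groups: dict[tuple[str, str], tuple[str, list[int]]] = {}
        for i, atom in enumerate(self.atoms):
            key = atom.residue_key
            if key not in groups:
                groups[key] = (atom.residue_name, [])
                order.append(key)
            groups[key][1].append(i)
        return [(key, groups[key][0], groups[key][1]) for key in order]

    def chains(self) -> list[str]:
        out: list[str] = []
        for atom in self.atoms:
            if atom.chain_id not in out:
                out.append(atom.chain_id)
        return out


@dataclass
class Trajectory:
    """A topology plus F frames of coordinates (Å)."""

    topology: Structure
    frames: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3 or frames.shape[1] != len(self.topology) or frames.shape[2] != 3:
            raise ValueError(
                f"frames shape {frames.shape} incompatible with topology of "
                f"{len(self.topology)} atoms"
            )
        if frames.shape[0] < 1:
            raise ValueError("a Trajectory requires at least one frame")
        if not np.all(np.isfinite(frames)):
            raise ValueError("non-finite coordinates in trajectory")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_structure(self, index: int) -> Structure:
        return self.topology.with_coords(self.frames[index])


@dataclass(frozen=True)
class Selection:
    """Strictly increasing atom indices into a Structure."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("selection indices must be strictly increasing")
        if idx and idx[0] < 0:
            raise ValueError("negative atom index")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def validate(self, structure: Structure) -> None:
        if self.indices and self.indices[-1] >= len(structure):
            raise IndexError("selection index out of range for structure")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords)[..., list(self.indices), :]

    def labels(self, structure: Structure) -> list[str]:
        return [structure.atoms[i].residue_label for i in self.indices]


# ---------------------------------------------------------------------------
# PDB I/O (fixed-column wwPDB dialect)
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, str, float]:
    """Parse one ATOM/HETATM record; returns (atom, altloc, occupancy)."""
    line = line.rstrip("\n").ljust(80)
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0
    name = line[12:16].strip()
    altloc = line[16].strip()
    residue_name = line[17:20].strip() or line[17:21].strip()
    chain_id = line[21].strip() or " "
    try:
        residue_seq = int(line[22:26])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: unparseable residue number") from exc
    insertion = line[26].strip()
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: unparseable coordinate field") from exc
    try:
        occupancy = float(line[54:60])
    except ValueError:
        occupancy = 1.0
    element = line[76:78].strip()
    if not element:
        # fall back to the first alphabetic character of the atom name
        element = next((c for c in name if c.isalpha()), "X").upper()
    atom = Atom(
        serial=serial,
        name=name,
        element=element,
        residue_seq=residue_seq,
        residue_name=residue_name,
        chain_id=chain_id,
        coords=np.array([x, y, z]),
        insertion_code=insertion,
    )
    return atom, altloc, occupancy


def read_pdb(text: str, frame_interval: float = 1.0) -> Trajectory:
    """Parse multi-model PDB text into a Trajectory.

    One frame per MODEL block; a file without MODEL records yields a single
    frame.  Topology (atom names, residues) is taken from the first model;
    later models must list the same number of atoms.  Alternate locations
    are collapsed by keeping the highest-occupancy record (tie → first seen).
    """
    title_parts: list[str] = []
    models: list[list[tuple[Atom, str, float]]] = []
    current: list[tuple[Atom, str, float]] | None = None
    in_model = False

    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "TITLE":
            title_parts.append(line[10:].strip())
        elif record == "MODEL":
            if current:
                models.append(current)
            current = []
            in_model = True
        elif record == "ENDMDL":
            if current is not None:
                models.append(current)
            current = None
        elif record in ("ATOM", "HETATM"):
            if current is None:
                if in_model:
                    raise PDBParseError(f"line {lineno}: ATOM outside MODEL block")
                current = []
            current.append(_parse_atom_line(line, lineno))
    if current:
        models.append(current)
    if not models:
        raise PDBParseError("no ATOM/HETATM records found")

    # collapse altlocs within each model
    collapsed: list[list[Atom]] = []
    for parsed in models:
        best: dict[tuple, tuple[Atom, float]] = {}
        order: list[tuple] = []
        for atom, altloc, occupancy in parsed:
            key = (atom.chain_id, atom.residue_seq, atom.insertion_code, atom.name)
            if key not in best:
                best[key] = (atom, occupancy)
                order.append(key)
            elif altloc and occupancy > best[key][1]:
                best[key] = (atom, occupancy)
            elif not altloc:
                raise PDBParseError(f"duplicate atom {key} without altloc")
        collapsed.append([best[key][0] for key in order])

    n_atoms = len(collapsed[0])
    for m, atoms in enumerate(collapsed[1:], start=2):
        if len(atoms) != n_atoms:
            raise PDBParseError(
                f"MODEL {m} has {len(atoms)} atoms, expected {n_atoms}"
            )

    topology = Structure(atoms=collapsed[0], title=" ".join(title_parts))
    frames = np.stack([np.array([a.coords for a in atoms]) for atoms in collapsed])
    return Trajectory(topology=topology, frames=frames, frame_interval=frame_interval)


def read_pdb_file(path) -> Trajectory:
    with open(path) as handle:
        return read_pdb(handle.read())


def write_pdb(trajectory: Trajectory) -> str:
    """Serialize a Trajectory as multi-model PDB text (coordinates %.3f)."""
    lines: list[str] = []
    if trajectory.topology.title:
        lines.append(f"TITLE     {trajectory.topology.title}")
    multi = trajectory.n_frames > 1
    for f in range(trajectory.n_frames):
        if multi:
            lines.append(f"MODEL     {f + 1:4d}")
        for i, atom in enumerate(trajectory.topology.atoms):
            x, y, z = trajectory.frames[f, i]
            name = atom.name
            if len(name) < 4 and len(atom.element) < 2:
                name = f" {name}"
            lines.append(
                f"ATOM  {atom.serial % 100000:5d} {name:<4s} {atom.residue_name:>3s} "
                f"{atom.chain_id}{atom.residue_seq:4d}{atom.insertion_code:1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{atom.element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def select_calpha(structure: Structure, chains: list[str] | None = None) -> Selection:
    """Select one Cα per standard amino-acid residue, in residue order.

    Hetero groups (ligands such as GDP) are excluded by the standard
    residue-name whitelist.  A residue carrying zero or more than one CA
    atom raises a ``ValueError`` naming the residue.
    """
    indices: list[int] = []
    for key, resname, atom_idx in structure.residues():
        if chains is not None and key[0] not in chains:
            continue
        if resname not in STANDARD_AMINO_ACIDS:
            continue
        ca = [i for i in atom_idx if structure.atoms[i].name == "CA"]
        if len(ca) != 1:
            raise ValueError(
                f"residue {key[0]}:{resname}{key[1]} has {len(ca)} CA atoms (expected 1)"
            )
        indices.append(ca[0])
    return Selection(indices=tuple(indices))


def select_atoms(structure: Structure, chain: str,
                 residue_range: tuple[int, int] | None = None,
                 names: list[str] | None = None) -> Selection:
    """Select atoms by chain, optional residue range (inclusive) and names."""
    indices = []
    for i, atom in enumerate(structure.atoms):
        if atom.chain_id != chain:
            continue
        if residue_range is not None and not (
            residue_range[0] <= atom.residue_seq <= residue_range[1]
        ):
            continue
        if names is not None and atom.name not in names:
            continue
        indices.append(i)
    return Selection(indices=tuple(indices))


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centered ``mobile`` onto ``reference``.

    If the best orthogonal transform is a reflection (determinant −1), the
    smallest singular direction is flipped so a proper rotation is returned.
    """
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, 1.0, d])
    return u @ flip @ vt


def kabsch_superpose(mobile_coords: np.ndarray,
                     reference_coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the transformed mobile coordinates and the post-fit RMSD
    ``sqrt(mean ||r_i − r_i'||²)`` in the same units as the input (Å).
    """
    mobile = np.asarray(mobile_coords, dtype=float)
    reference = np.asarray(reference_coords, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (N, 3) with equal N")
    if mobile.shape[0] < 1:
        raise ValueError("at least one point required")

    mobile_center = mobile.mean(axis=0)
    reference_center = reference.mean(axis=0)
    rotation = kabsch_rotation(mobile - mobile_center, reference - reference_center)
    rotated = (mobile - mobile_center) @ rotation + reference_center
    rmsd = float(np.sqrt(np.mean(np.sum((rotated - reference) ** 2, axis=1))))
    return rotated, rmsd
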