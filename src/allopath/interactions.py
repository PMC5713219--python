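"""Geometric detection of interface hydrogen bonds, salt bridges, cation-π.

Distance/angle criteria are heavy-atom based (hydrogen-free structures are
the norm for trajectory snapshots): donor–acceptor ≤ 3.9 Å for hydrogen
bonds (plus a D–H···A ≥ 120° gate when explicit hydrogens exist), cationic
nitrogen to carboxylate oxygen ≤ 4.0 Å for salt bridges, and cation to
aromatic-ring centroid ≤ 6.0 Å with the cation within 45° of the ring normal
for cation-π contacts.  All thresholds are keyword-configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Structure

__all__ = [
    "InteractionRecord",
    "find_hbonds",
    "find_salt_bridges",
    "find_cation_pi",
    "find_all_interactions",
    "residue_interaction_census",
    "records_frame",
]

# cationic side-chain nitrogens and anionic side-chain / terminal oxygens
CATIONIC_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
    "HIP": ("ND1", "NE2"),
}
ANIONIC_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
TERMINAL_ANIONS = ("OXT",)

# aromatic six-rings (His handled as its five-ring for centroid purposes)
AROMATIC_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
CATION_CENTER_ATOMS = {"ARG": "CZ", "LYS": "NZ"}


@dataclass(frozen=True)
class InteractionRecord:
    """One detected interface contact."""

    kind: str                      # hbond | salt_bridge | cation_pi
    atom_a: tuple[str, str, str]   # (chain, residue label, atom name)
    atom_b: tuple[str, str, str]
    distance: float
    frame: int = 0

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")


def _atom_id(structure: Structure, index: int) -> tuple[str, str, str]:
    atom = structure.atoms[index]
    return (atom.chain_id, f"{atom.residue_name}{atom.residue_seq}{atom.insertion_code}", atom.name)


def _chain_atoms(structure: Structure, chain: str) -> list[int]:
    idx = [i for i, a in enumerate(structure.atoms) if a.chain_id == chain]
    if not idx:
        raise ValueError(f"chain {chain!r} not present in structure")
    return idx


def _cross_chain_pairs(structure: Structure, chain_pair: tuple[str, str]):
    ia = _chain_atoms(structure, chain_pair[0])
    ib = _chain_atoms(structure, chain_pair[1])
    for i in ia:
        for j in ib:
            yield i, j


def find_hbonds(
    structure: Structure,
    chain_pair: tuple[str, str],
    max_distance: float = 3.9,
    min_angle: float = 120.0,
    frame: int = 0,
) -> list[InteractionRecord]:
    """Inter-chain donor-acceptor hydrogen bonds.

    Donors are N/O heavy atoms (hydrogens implied when absent); acceptors
    are N/O/S.  When an explicit hydrogen is bonded to the donor (≤ 1.2 Å),
    the D-H···A angle must additionally be ≥ ``min_angle`` degrees.
    """
    records = []
    coords = structure.coords
    hydrogens = [i for i, a in enumerate(structure.atoms) if a.element == "H"]
    for i, j in _cross_chain_pairs(structure, chain_pair):
        a_i, a_j = structure.atoms[i], structure.atoms[j]
        if a_i.element not in ("N", "O") or a_j.element not in ("N", "O", "S"):
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d > max_distance:
            continue
        # explicit-hydrogen angle gate: whichever heavy atom carries the H
        # is the donor and must satisfy D-H···A ≥ min_angle
        bonded_h = {
            donor: [
                h for h in hydrogens
                if structure.atoms[h].residue_key == structure.atoms[donor].residue_key
                and np.linalg.norm(coords[h] - coords[donor]) <= 1.2
            ]
            for donor in (i, j)
        }
        if bonded_h[i] or bonded_h[j]:
            ok = False
            for donor, acceptor in ((i, j), (j, i)):
                for h in bonded_h[donor]:
                    v1 = coords[donor] - coords[h]
                    v2 = coords[acceptor] - coords[h]
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= min_angle:
                        ok = True
                        break
                if ok:
                    break
            if not ok:
                continue
        records.append(
            InteractionRecord("hbond", _atom_id(structure, i), _atom_id(structure, j), d, frame)
        )
    return records


def find_salt_bridges(
    structure: Structure,
    chain_pair: tuple[str, str],
    max_distance: float = 4.0,
    frame: int = 0,
) -> list[InteractionRecord]:
    """Inter-chain salt bridges between cationic N and anionic O atoms."""
    records = []
    coords = structure.coords

    def is_cationic(atom) -> bool:
        return atom.name in CATIONIC_ATOMS.get(atom.residue_name, ())

    def is_anionic(atom) -> bool:
        return (
            atom.name in ANIONIC_ATOMS.get(atom.residue_name, ())
            or atom.name in TERMINAL_ANIONS
        )

    for i, j in _cross_chain_pairs(structure, chain_pair):
        a_i, a_j = structure.atoms[i], structure.atoms[j]
        if is_cationic(a_i) and is_anionic(a_j):
            pass
        elif is_anionic(a_i) and is_cationic(a_j):
            pass
        else:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d <= max_distance:
            records.append(
                InteractionRecord(
                    "salt_bridge", _atom_id(structure, i), _atom_id(structure, j), d, frame
                )
            )
    return records


def find_cation_pi(
    structure: Structure,
    chain_pair: tuple[str, str],
    max_distance: float = 6.0,
    max_angle: float = 45.0,
    frame: int = 0,
) -> list[InteractionRecord]:
    """Inter-chain cation-π contacts.

    The cationic group centre (Arg CZ, Lys NZ) must lie within
    ``max_distance`` of an aromatic ring centroid and within ``max_angle``
    degrees of the ring normal.  Rings with missing atoms are skipped with a
    warning.  The record's ``atom_b`` names the ring residue's first ring
    atom.
    """
    records = []
    coords = structure.coords

    def ring_residues(chain: str):
        seen = set()
        for i in _chain_atoms(structure, chain):
            atom = structure.atoms[i]
            if atom.residue_name in AROMATIC_RINGS and atom.residue_key not in seen:
                seen.add(atom.residue_key)
                yield atom.residue_key, atom.residue_name

    def cation_atoms(chain: str):
        for i in _chain_atoms(structure, chain):
            atom = structure.atoms[i]
            if atom.name == CATION_CENTER_ATOMS.get(atom.residue_name):
                yield i

    index = {
        (a.residue_key, a.name): i for i, a in enumerate(structure.atoms)
    }

    for cat_chain, ring_chain in (chain_pair, chain_pair[::-1]):
        for key, resname in ring_residues(ring_chain):
            names = AROMATIC_RINGS[resname]
            try:
                ring_idx = [index[(key, n)] for n in names]
            except KeyError:
                warnings.warn(f"aromatic residue {key} has missing ring atoms; skipped",
                              stacklevel=2)
                continue
            ring = coords[ring_idx]
            centroid = ring.mean(axis=0)
            # normal from SVD of the centred ring atoms
            _, _, vt = np.linalg.svd(ring - centroid)
            normal = vt[2]
            for ci in cation_atoms(cat_chain):
                vec = coords[ci] - centroid
                d = float(np.linalg.norm(vec))
                if d == 0 or d > max_distance:
                    continue
                cosang = abs(np.dot(vec / d, normal))
                angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if angle <= max_angle:
                    records.append(
                        InteractionRecord(
                            "cation_pi",
                            _atom_id(structure, ci),
                            _atom_id(structure, ring_idx[0]),
                            d,
                            frame,
                        )
                    )
    return records


def find_all_interactions(
    structure: Structure, chain_pair: tuple[str, str], frame: int = 0, **kwargs
) -> list[InteractionRecord]:
    """All three interaction kinds for one structure/frame."""
    return (
        find_hbonds(structure, chain_pair, frame=frame)
        + find_salt_bridges(structure, chain_pair, frame=frame)
        + find_cation_pi(structure, chain_pair, frame=frame)
    )


def records_frame(records: list[InteractionRecord]) -> pd.DataFrame:
    """Records as a flat table (atom pair + distance layout)."""
    rows = [
        {
            "kind": r.kind,
            "chain_a": r.atom_a[0],
            "residue_a": r.atom_a[1],
            "atom_a": r.atom_a[2],
            "chain_b": r.atom_b[0],
            "residue_b": r.atom_b[1],
            "atom_b": r.atom_b[2],
            "distance": r.distance,
            "frame": r.frame,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["kind", "chain_a", "residue_a", "atom_a",
                 "chain_b", "residue_b", "atom_b", "distance", "frame"],
    )


def residue_interaction_census(records: list[InteractionRecord]) -> pd.DataFrame:
    """Per-residue interaction counts, sorted by total (descending).

    Each record contributes to both partner residues; columns are
    ``n_hbond``, ``n_salt_bridge``, ``n_cation_pi`` plus ``total``.
    """
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for r in records:
        for chain, residue, _ in (r.atom_a, r.atom_b):
            key = (chain, residue)
            entry = counts.setdefault(
                key, {"n_hbond": 0, "n_salt_bridge": 0, "n_cation_pi": 0}
            )
            entry[f"n_{r.kind}"] += 1
    rows = [
        {"chain": c, "residue": res, **v, "total": sum(v.values())}
        for (c, res), v in counts.items()
    ]
    frame = pd.DataFrame(
        rows, columns=["chain", "residue", "n_hbond", "n_salt_bridge", "n_cation_pi", "total"]
    )
    if not frame.empty:
        frame = frame.sort_values(
            ["total", "chain", "residue"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return frame
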