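"""Synthetic trajectories, planted graphs, interface geometries and toy systems.

Every downstream stage — fluctuation statistics, the cross-correlation
matrix, network path analysis, interaction detection, and the nonbonded
energy terms — is exercised here against inputs whose ground truth is known
by construction:

* Gaussian residue fluctuations around a reference chain with a planted
  inter-residue correlation matrix (the expected cross-correlation matrix is
  the planted matrix itself when all residues share one displacement
  direction);
* correlation matrices + contact maps that realise a prescribed residue
  graph exactly;
* two-chain interface geometries with a named donor/acceptor pair at an
  exact distance;
* two-particle charged/Lennard-Jones systems with closed-form energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Atom, Structure, Trajectory

__all__ = [
    "PlantedModel",
    "make_chain",
    "sample_correlated_trajectory",
    "plant_path_graph",
    "make_interaction_fixture",
    "make_two_particle_system",
]


def make_chain(n_res: int, geometry: str = "line", chain_id: str = "A") -> Structure:
    """Build a Cα-only reference chain.

    ``line`` places consecutive Cα 3.8 Å apart on the x-axis; ``helix`` uses
    ideal α-helix Cα parameters (rise 1.5 Å per residue, 100° twist,
    radius 2.3 Å).
    """
    if n_res < 2:
        raise ValueError("a chain needs at least 2 residues")
    if geometry == "line":
        coords = np.zeros((n_res, 3))
        coords[:, 0] = 3.8 * np.arange(n_res)
    elif geometry == "helix":
        t = np.deg2rad(100.0) * np.arange(n_res)
        coords = np.column_stack(
            [2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n_res)]
        )
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    atoms = [
        Atom(
            serial=i + 1,
            name="CA",
            element="C",
            residue_seq=i + 1,
            residue_name="ALA",
            chain_id=chain_id,
            coords=coords[i],
        )
        for i in range(n_res)
    ]
    return Structure(atoms=atoms, title=f"synthetic {geometry} chain n={n_res}")


@dataclass
class PlantedModel:
    """Specification of a correlated-fluctuation trajectory.

    Frame ``t`` places residue ``i`` at ``reference_i + amplitude · η_i(t) ·
    direction_i`` with ``η(t)`` zero-mean unit-variance Gaussians whose
    correlation matrix is ``target_corr``.  With the default single common
    direction the expected cross-correlation matrix equals ``target_corr``
    exactly, so parameter recovery is analytic.
    """

    reference: Structure
    target_corr: np.ndarray
    amplitude: float = 1.0
    n_frames: int = 1000
    seed: int = 0
    directions: np.ndarray | None = None  # (N, 3) unit vectors; None = common +x

    def __post_init__(self) -> None:
        corr = np.asarray(self.target_corr, dtype=float)
        n = len(self.reference)
        if corr.shape != (n, n):
            raise ValueError("target_corr must be N×N for N reference atoms")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("target_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("target_corr must have unit diagonal")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        self.target_corr = corr
        if self.directions is not None:
            d = np.asarray(self.directions, dtype=float)
            if d.shape != (n, 3):
                raise ValueError("directions must be (N, 3)")
            self.directions = d / np.linalg.norm(d, axis=1, keepdims=True)


def _correlation_sqrt(corr: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Symmetric square root; small negative eigenvalues clipped at ``-tol``."""
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals.min() < -tol:
        raise ValueError(
            f"target correlation matrix is not positive semidefinite "
            f"(min eigenvalue {eigvals.min():.3g})"
        )
    eigvals = np.clip(eigvals, 0.0, None)
    return eigvecs @ np.diag(np.sqrt(eigvals)) @ eigvecs.T


def sample_correlated_trajectory(model: PlantedModel) -> Trajectory:
    """Draw a trajectory with the planted fluctuation correlation structure.

    Deterministic for a fixed ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    n = len(model.reference)
    root = _correlation_sqrt(model.target_corr)
    # η (F, N): i.i.d. standard normals mixed to the target correlation
    eta = rng.standard_normal((model.n_frames, n)) @ root.T
    if model.directions is None:
        directions = np.tile(np.array([1.0, 0.0, 0.0]), (n, 1))
    else:
        directions = model.directions
    reference = model.reference.coords
    frames = reference[None, :, :] + model.amplitude * eta[:, :, None] * directions[None, :, :]
    return Trajectory(topology=model.reference, frames=frames)


def plant_path_graph(
    n_nodes: int,
    edges: list[tuple[int, int, float]],
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Realise a prescribed residue graph as (correlation_matrix, contact_map).

    Each requested edge ``(i, j, |X|)`` appears in the correlation matrix with
    exactly that absolute correlation and in the boolean contact map; all
    other off-diagonal entries are zero / non-contact, so the residue graph
    derived downstream is known by construction.
    """
    corr = np.eye(n_nodes)
    contacts = np.zeros((n_nodes, n_nodes), dtype=bool)
    for i, j, x in edges:
        if not (0.0 < x <= 1.0):
            raise ValueError(f"edge ({i},{j}) has |X|={x} outside (0, 1]")
        if i == j:
            raise ValueError("self-loops not allowed")
        corr[i, j] = corr[j, i] = x
        contacts[i, j] = contacts[j, i] = True
    # connectivity check by simple BFS over the planted edges
    if n_nodes > 1:
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in np.nonzero(contacts[u])[0]:
                if v not in seen:
                    seen.add(int(v))
                    stack.append(int(v))
        if len(seen) != n_nodes:
            raise ValueError("planted edges do not form a connected graph")
    return corr, contacts


# ---------------------------------------------------------------------------
# Interface fixtures
# ---------------------------------------------------------------------------

# minimal side-chain templates: atom name -> offset (Å) from the group anchor
_RING = {
    "CG": (0.0, 0.0, 0.0),
    "CD1": (1.21, 0.70, 0.0),
    "CD2": (-1.21, 0.70, 0.0),
    "CE1": (1.21, 2.10, 0.0),
    "CE2": (-1.21, 2.10, 0.0),
    "CZ": (0.0, 2.80, 0.0),
}


def _single_atom_chain(
    resname: str, resseq: int, atom_name: str, chain_id: str, position: np.ndarray,
    element: str, serial: int,
) -> list[Atom]:
    return [
        Atom(
            serial=serial,
            name=atom_name,
            element=element,
            residue_seq=resseq,
            residue_name=resname,
            chain_id=chain_id,
            coords=position,
        )
    ]


def make_interaction_fixture(
    kind: str,
    distance: float,
    *,
    group_a: tuple[str, int, str] | None = None,
    group_b: tuple[str, int, str] | None = None,
) -> Structure:
    """Two-chain fixture with a named atom pair at an exact distance.

    ``kind`` selects the default chemistry (modelled on the H-Ras–NS1
    interface): ``hbond`` places a Glu OE1 acceptor (chain A) against an Arg
    NE donor (chain B); ``salt_bridge`` a Glu OE2 against a Lys NZ;
    ``cation_pi`` a Tyr six-ring (chain A) with an Arg CZ cation on the ring
    normal at the requested centroid distance.  ``group_a``/``group_b``
    override the residue name, number, and atom name of either partner for
    distance-based kinds.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    if kind == "hbond":
        a = group_a or ("GLU", 49, "OE1")
        b = group_b or ("ARG", 135, "NE")
    elif kind == "salt_bridge":
        a = group_a or ("GLU", 49, "OE2")
        b = group_b or ("LYS", 135, "NZ")
    elif kind == "cation_pi":
        ring_res = group_a or ("TYR", 31, "ring")
        cation = group_b or ("ARG", 135, "CZ")
        atoms: list[Atom] = []
        centroid = np.array([0.0, 1.4, 0.0])
        for serial, (name, offset) in enumerate(_RING.items(), start=1):
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element="C",
                    residue_seq=ring_res[1],
                    residue_name=ring_res[0],
                    chain_id="A",
                    coords=np.array(offset),
                )
            )
        # cation on the ring normal (z-axis) above the centroid
        atoms.extend(
            _single_atom_chain(
                cation[0], cation[1], cation[2], "B",
                centroid + np.array([0.0, 0.0, distance]),
                "N" if cation[2].startswith("N") else "C",
                serial=10,
            )
        )
        return Structure(atoms=atoms, title=f"synthetic cation-pi fixture d={distance}")
    else:
        raise ValueError(f"unknown interaction kind {kind!r}")

    element_a = a[2][0]
    element_b = b[2][0]
    atoms = _single_atom_chain(a[0], a[1], a[2], "A", np.zeros(3), element_a, serial=1)
    atoms += _single_atom_chain(
        b[0], b[1], b[2], "B", np.array([distance, 0.0, 0.0]), element_b, serial=2
    )
    return Structure(atoms=atoms, title=f"synthetic {kind} fixture d={distance}")


def make_two_particle_system(
    q1: float, q2: float, eps: float, sigma: float, r: float
) -> tuple[Structure, pd.DataFrame]:
    """Two parameterized particles on the x-axis separated by ``r`` Å.

    Returns the structure and a nonbonded parameter table (charge in e,
    Lennard-Jones ε in kcal/mol, σ in Å) keyed by atom index.
    """
    if r <= 0:
        raise ValueError("separation must be positive")
    atoms = [
        Atom(serial=1, name="P1", element="X", residue_seq=1, residue_name="TOY",
             chain_id="A", coords=np.zeros(3)),
        Atom(serial=2, name="P2", element="X", residue_seq=2, residue_name="TOY",
             chain_id="A", coords=np.array([r, 0.0, 0.0])),
    ]
    params = pd.DataFrame(
        {
            "atom_index": [0, 1],
            "charge": [q1, q2],
            "eps": [eps, eps],
            "sigma": [sigma, sigma],
        }
    )
    return Structure(atoms=atoms, title="synthetic two-particle system"), params
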