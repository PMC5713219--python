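"""MM/GBSA end-state bookkeeping, gas-phase nonbonded terms, and SASA.

The binding free energy follows the single-trajectory end-state convention:

    ΔG_binding = ΔG_gas + ΔG_solvation − TΔS
    ΔG_gas     = ΔE_vdW + ΔE_ele + ΔE_int
    ΔG_solvation = ΔG_polar + ΔG_nonpolar,   ΔG_nonpolar = γ·SASA + b

with every Δterm the per-frame ``complex − receptor − ligand`` difference.
The polar (Generalized-Born) term is consumed from an input table, never
computed here; the nonpolar term uses γ = 0.00542 kcal·mol⁻¹·Å⁻² and
b = 0.92 kcal/mol.  The entropy term −TΔS defaults to 0 (omitted), keeping
only the relative ordering of binding free energies meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Structure

__all__ = [
    "COULOMB_CONSTANT",
    "GAMMA_DEFAULT",
    "B_DEFAULT",
    "BONDI_RADII",
    "EnergyComponents",
    "BindingSummary",
    "nonbonded_energy",
    "sasa",
    "nonpolar_solvation",
    "binding_summary",
    "residue_decomposition",
    "read_components_csv",
]

#: Coulomb conversion constant, kcal·Å·mol⁻¹·e⁻².
COULOMB_CONSTANT = 332.0637
#: Surface-tension coefficient for the nonpolar solvation term, kcal·mol⁻¹·Å⁻².
GAMMA_DEFAULT = 0.00542
#: Offset of the nonpolar solvation term, kcal/mol.
B_DEFAULT = 0.92

#: Bondi van der Waals radii (Å) by element.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

_TERMS = ("E_vdW", "E_ele", "E_int", "G_polar", "G_nonpolar")


@dataclass
class EnergyComponents:
    """Per-frame energy components (kcal/mol) for one role.

    ``role`` is one of ``complex``, ``receptor``, ``ligand``.  Any component
    may be a scalar (broadcast) or a length-F array.
    """

    role: str
    E_vdW: np.ndarray
    E_ele: np.ndarray
    E_int: np.ndarray | float = 0.0
    G_polar: np.ndarray | float = 0.0
    G_nonpolar: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ("complex", "receptor", "ligand"):
            raise ValueError(f"unknown role {self.role!r}")
        n = np.atleast_1d(np.asarray(self.E_vdW, dtype=float)).shape[0]
        for term in _TERMS:
            arr = np.atleast_1d(np.asarray(getattr(self, term), dtype=float))
            if arr.shape[0] == 1:
                arr = np.full(n, arr[0])
            if arr.shape[0] != n:
                raise ValueError(f"{term} has {arr.shape[0]} frames, expected {n}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {term}")
            setattr(self, term, arr)

    @property
    def n_frames(self) -> int:
        return self.E_vdW.shape[0]


@dataclass
class BindingSummary:
    """Mean ± SD ledger of the binding free-energy terms (kcal/mol)."""

    means: dict[str, float]
    sds: dict[str, float]
    n_frames: int
    entropy_term: float = 0.0
    gamma: float = GAMMA_DEFAULT
    b: float = B_DEFAULT

    ROWS = (
        "dE_vdW", "dE_ele", "dE_int", "dG_GB", "dG_SURF",
        "dG_gas", "dG_solvation", "dG_binding",
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.ROWS),
                "mean": [self.means[r] for r in self.ROWS],
                "sd": [self.sds[r] for r in self.ROWS],
            }
        )

    @staticmethod
    def comparison_table(wt: "BindingSummary", mut: "BindingSummary") -> pd.DataFrame:
        """Side-by-side ledger with the ``mut − wt`` difference column."""
        rows = []
        for term in BindingSummary.ROWS:
            rows.append(
                {
                    "term": term,
                    "wt_mean": wt.means[term],
                    "wt_sd": wt.sds[term],
                    "mut_mean": mut.means[term],
                    "mut_sd": mut.sds[term],
                    "difference": mut.means[term] - wt.means[term],
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gas-phase nonbonded terms
# ---------------------------------------------------------------------------

def nonbonded_energy(
    structure: Structure,
    parameter_table: pd.DataFrame,
    cutoff: float = 10.0,
    exclusions: set[tuple[int, int]] | None = None,
) -> tuple[float, float]:
    """Pairwise van der Waals and Coulomb energies (kcal/mol).

    ``parameter_table`` must provide ``atom_index``, ``charge`` (e), ``eps``
    (kcal/mol) and ``sigma`` (Å) for every atom.  Lorentz–Berthelot
    combining rules; pairs beyond ``cutoff`` are excluded by plain
    truncation (no switching function), as are pairs in the user-supplied
    bonded-exclusion set.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    params = parameter_table.set_index("atom_index")
    n = len(structure)
    missing = [i for i in range(n) if i not in params.index]
    if missing:
        raise ValueError(f"missing nonbonded parameters for atom indices {missing}")
    q = params.loc[range(n), "charge"].to_numpy(dtype=float)
    eps = params.loc[range(n), "eps"].to_numpy(dtype=float)
    sigma = params.loc[range(n), "sigma"].to_numpy(dtype=float)
    coords = structure.coords
    excl = {tuple(sorted(p)) for p in (exclusions or set())}

    e_vdw = 0.0
    e_ele = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excl:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r > cutoff:
                continue
            e_ele += COULOMB_CONSTANT * q[i] * q[j] / r
            eps_ij = np.sqrt(eps[i] * eps[j])
            sigma_ij = 0.5 * (sigma[i] + sigma[j])
            sr6 = (sigma_ij / r) ** 6
            e_vdw += 4.0 * eps_ij * (sr6**2 - sr6)
    return float(e_vdw), float(e_ele)


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake–Rupley)
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform unit-sphere point set (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> tuple[np.ndarray, float]:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom's sphere of radius ``r_atom + probe`` is sampled with
    ``n_points`` near-uniform points; the accessible fraction (points not
    inside any neighbour's expanded sphere) times ``4π(r+probe)²`` is that
    atom's SASA.  Returns (per-atom areas, total) in Å².
    """
    if probe < 0:
        raise ValueError("probe radius must be nonnegative")
    table = radii or BONDI_RADII
    try:
        r = np.array([table[a.element.upper()] for a in structure.atoms]) + probe
    except KeyError as exc:
        raise ValueError(f"no radius for element {exc.args[0]!r}") from exc
    coords = structure.coords
    sphere = _fibonacci_sphere(n_points)
    n = len(structure)
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + r[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            if np.linalg.norm(coords[i] - coords[j]) >= r[i] + r[j]:
                continue
            accessible &= np.sum((pts - coords[j]) ** 2, axis=1) >= r[j] ** 2
        areas[i] = accessible.mean() * 4.0 * np.pi * r[i] ** 2
    return areas, float(areas.sum())


def nonpolar_solvation(
    sasa_total: float, gamma: float = GAMMA_DEFAULT, b: float = B_DEFAULT
) -> float:
    """Nonpolar solvation free energy ``γ·SASA + b`` (kcal/mol)."""
    if sasa_total < 0:
        raise ValueError("SASA cannot be negative")
    return gamma * sasa_total + b


# ---------------------------------------------------------------------------
# End-state ledger
# ---------------------------------------------------------------------------

def binding_summary(
    complex_: EnergyComponents,
    receptor: EnergyComponents,
    ligand: EnergyComponents,
    entropy_term: float = 0.0,
    gamma: float = GAMMA_DEFAULT,
    b: float = B_DEFAULT,
) -> BindingSummary:
    """Per-frame end-state differences, averaged into a Table-style ledger.

    For each term, ``Δterm(f) = term_complex(f) − term_receptor(f) −
    term_ligand(f)``; the ledger reports the mean and population SD over
    frames of every Δterm plus the derived sums

        ΔG_gas = ΔE_vdW + ΔE_ele + ΔE_int
        ΔG_solvation = ΔG_GB + ΔG_SURF
        ΔG_binding = ΔG_gas + ΔG_solvation − TΔS.
    """
    n = complex_.n_frames
    if receptor.n_frames != n or ligand.n_frames != n:
        raise ValueError("frame counts differ across roles")
    delta = {
        term: getattr(complex_, term) - getattr(receptor, term) - getattr(ligand, term)
        for term in _TERMS
    }
    series = {
        "dE_vdW": delta["E_vdW"],
        "dE_ele": delta["E_ele"],
        "dE_int": delta["E_int"],
        "dG_GB": delta["G_polar"],
        "dG_SURF": delta["G_nonpolar"],
    }
    series["dG_gas"] = series["dE_vdW"] + series["dE_ele"] + series["dE_int"]
    series["dG_solvation"] = series["dG_GB"] + series["dG_SURF"]
    series["dG_binding"] = series["dG_gas"] + series["dG_solvation"] - entropy_term
    means = {k: float(v.mean()) for k, v in series.items()}
    sds = {k: float(v.std()) for k, v in series.items()}
    return BindingSummary(
        means=means, sds=sds, n_frames=n, entropy_term=entropy_term, gamma=gamma, b=b
    )


def residue_decomposition(
    per_residue_wt: pd.DataFrame,
    per_residue_mut: pd.DataFrame,
    threshold: float = 0.3,
) -> pd.DataFrame:
    """Per-residue free-energy comparison between two systems.

    Inputs carry ``residue``, ``mean`` and optional ``sd`` columns of
    per-residue contributions to the binding free energy (kcal/mol).  The
    difference column is ``mut − wt``; a residue is flagged when its
    difference is strictly greater than ``threshold`` (an unfavourable shift
    of more than 0.3 kcal/mol by default).  Residues present in only one
    system are reported with a missing difference and never flagged.
    """
    wt = per_residue_wt.set_index("residue")
    mut = per_residue_mut.set_index("residue")
    residues = list(dict.fromkeys(list(wt.index) + list(mut.index)))
    rows = []
    for res in residues:
        g_wt = float(wt.loc[res, "mean"]) if res in wt.index else np.nan
        g_mut = float(mut.loc[res, "mean"]) if res in mut.index else np.nan
        diff = g_mut - g_wt
        rows.append(
            {
                "residue": res,
                "G_wt": g_wt,
                "sd_wt": float(wt.loc[res, "sd"]) if res in wt.index and "sd" in wt else np.nan,
                "G_mut": g_mut,
                "sd_mut": float(mut.loc[res, "sd"]) if res in mut.index and "sd" in mut else np.nan,
                "difference": diff,
                "flagged": bool(np.isfinite(diff) and diff > threshold),
            }
        )
    return pd.DataFrame(
        rows, columns=["residue", "G_wt", "sd_wt", "G_mut", "sd_mut", "difference", "flagged"]
    )


def read_components_csv(path) -> dict[str, EnergyComponents]:
    """Read a per-frame component table into role-keyed EnergyComponents.

    Expected columns: ``frame, role, E_vdW, E_ele, E_int, G_polar,
    G_nonpolar`` with role in {complex, receptor, ligand}.
    """
    table = pd.read_csv(path)
    out = {}
    for role, group in table.groupby("role"):
        group = group.sort_values("frame")
        out[role] = EnergyComponents(
            role=role,
            E_vdW=group["E_vdW"].to_numpy(),
            E_ele=group["E_ele"].to_numpy(),
            E_int=group["E_int"].to_numpy() if "E_int" in group else 0.0,
            G_polar=group["G_polar"].to_numpy() if "G_polar" in group else 0.0,
            G_nonpolar=group["G_nonpolar"].to_numpy() if "G_nonpolar" in group else 0.0,
        )
    return out
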