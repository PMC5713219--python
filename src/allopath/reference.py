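"""Bundled reference tables for the wild-type vs R135K H-Ras–NS1 system.

These small CSVs hold published MM/GBSA component means, per-residue
free-energy contributions, interface contact geometries, and allosteric
pathway statistics for the H-Ras–NS1 monobody complex.  They serve as
worked-example inputs: the end-state ledger and residue decomposition can be
recomputed from the component tables, and every interface contact row can be
rebuilt as a synthetic fixture and re-detected geometrically.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_energy_components",
    "load_residue_energies",
    "load_interface_contacts",
    "load_pathway_table",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("allopath.data").joinpath(name).open() as handle:
        return pd.read_csv(handle)


def load_energy_components() -> pd.DataFrame:
    """Δ-component means/SDs (kcal/mol) for both systems.

    Rows ``dE_vdW``, ``dE_ele``, ``dG_GB``, ``dG_SURF``; columns hold the
    wild-type and mutant means and standard deviations.
    """
    return _read("hras_ns1_energy_components.csv")


def load_residue_energies() -> pd.DataFrame:
    """Per-residue binding free-energy contributions for both systems."""
    return _read("hras_ns1_residue_energies.csv")


def load_interface_contacts() -> pd.DataFrame:
    """Interface hydrogen-bond/salt-bridge geometries around residue 135."""
    return _read("hras_ns1_interface_contacts.csv")


def load_pathway_table() -> pd.DataFrame:
    """Optimal/suboptimal pathway statistics for both systems."""
    return _read("hras_ns1_pathways.csv")
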