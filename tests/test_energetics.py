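"""Nonbonded terms, Shrake–Rupley SASA, and the MM/GBSA end-state ledger."""

import numpy as np
import pandas as pd
import pytest

from allopath import (
    EnergyComponents,
    binding_summary,
    make_two_particle_system,
    nonbonded_energy,
    nonpolar_solvation,
    residue_decomposition,
    sasa,
)
from allopath.core import Atom, Structure
from allopath.energetics import COULOMB_CONSTANT
from allopath.reference import load_energy_components, load_residue_energies


def summary_from_deltas(dE_vdW, dE_ele, dG_GB, dG_SURF):
    """Feed Δ-component means through the ledger via zeroed receptor/ligand."""
    def comp(role, scale):
        return EnergyComponents(
            role=role,
            E_vdW=np.array([dE_vdW * scale]),
            E_ele=np.array([dE_ele * scale]),
            G_polar=np.array([dG_GB * scale]),
            G_nonpolar=np.array([dG_SURF * scale]),
        )

    return binding_summary(comp("complex", 1.0), comp("receptor", 0.0), comp("ligand", 0.0))


class TestNonbondedEnergy:
    def test_neutral_pair_at_sigma_has_zero_energy(self):
        s, params = make_two_particle_system(0, 0, eps=0.2, sigma=3.0, r=3.0)
        e_vdw, e_ele = nonbonded_energy(s, params)
        assert e_vdw == pytest.approx(0.0, abs=1e-12)
        assert e_ele == 0.0

    def test_lj_minimum_depth(self):
        r = 2 ** (1 / 6) * 3.0
        s, params = make_two_particle_system(0, 0, eps=0.2, sigma=3.0, r=r)
        e_vdw, _ = nonbonded_energy(s, params)
        assert e_vdw == pytest.approx(-0.2, rel=1e-12)

    def test_unit_charges_give_round_coulomb_energy(self):
        r = COULOMB_CONSTANT / 100.0
        s, params = make_two_particle_system(1, 1, eps=0.0, sigma=3.0, r=r)
        _, e_ele = nonbonded_energy(s, params, cutoff=10.0)
        assert e_ele == pytest.approx(100.0, rel=1e-12)

    def test_cutoff_truncation_and_brute_force_parity(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 12, size=(6, 3))
        atoms = [
            Atom(serial=i + 1, name=f"P{i}", element="X", residue_seq=i + 1,
                 residue_name="TOY", chain_id="A", coords=coords[i])
            for i in range(6)
        ]
        s = Structure(atoms=atoms)
        params = pd.DataFrame({
            "atom_index": range(6),
            "charge": rng.uniform(-1, 1, 6),
            "eps": rng.uniform(0.05, 0.3, 6),
            "sigma": rng.uniform(2.5, 3.5, 6),
        })
        # cutoff beyond the system diameter equals the full double loop
        e_vdw, e_ele = nonbonded_energy(s, params, cutoff=1e6)
        q = params["charge"].to_numpy()
        eps = params["eps"].to_numpy()
        sig = params["sigma"].to_numpy()
        ref_vdw = ref_ele = 0.0
        for i in range(6):
            for j in range(i + 1, 6):
                r = np.linalg.norm(coords[i] - coords[j])
                ref_ele += COULOMB_CONSTANT * q[i] * q[j] / r
                e = np.sqrt(eps[i] * eps[j])
                srt = ((sig[i] + sig[j]) / 2 / r) ** 6
                ref_vdw += 4 * e * (srt**2 - srt)
        assert e_vdw == pytest.approx(ref_vdw, rel=1e-12)
        assert e_ele == pytest.approx(ref_ele, rel=1e-12)
        # a tight cutoff removes distant pairs
        e_cut, _ = nonbonded_energy(s, params, cutoff=5.0)
        assert e_cut != pytest.approx(ref_vdw, rel=1e-9)

    def test_missing_parameters_rejected(self):
        s, params = make_two_particle_system(0, 0, 0.1, 3.0, 4.0)
        with pytest.raises(ValueError, match="missing"):
            nonbonded_energy(s, params.iloc[:1])


class TestSasa:
    def lone_atom(self, element="S"):
        return Structure(atoms=[
            Atom(serial=1, name="X", element=element, residue_seq=1,
                 residue_name="TOY", chain_id="A", coords=np.zeros(3))
        ])

    def test_isolated_atom_matches_closed_form(self):
        # r = 1.6 Å radius + 1.4 Å probe → 4π·3² = 113.097 Å²
        _, total = sasa(self.lone_atom(), probe=1.4, radii={"S": 1.6})
        assert total == pytest.approx(4 * np.pi * 3.0**2, rel=0.01)

    def test_distant_atoms_are_additive(self):
        a = Atom(serial=1, name="X", element="C", residue_seq=1,
                 residue_name="TOY", chain_id="A", coords=np.zeros(3))
        b = Atom(serial=2, name="Y", element="C", residue_seq=2,
                 residue_name="TOY", chain_id="A", coords=np.array([100.0, 0, 0]))
        _, total = sasa(Structure(atoms=[a, b]))
        _, single = sasa(Structure(atoms=[a]))
        assert total == pytest.approx(2 * single, rel=1e-9)

    def test_fully_caged_atom_has_zero_area(self):
        # a small atom surrounded by an octahedral cage of large spheres
        cage_positions = 2.0 * np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
        )
        atoms = [Atom(serial=1, name="X", element="H", residue_seq=1,
                      residue_name="TOY", chain_id="A", coords=np.zeros(3))]
        atoms += [
            Atom(serial=i + 2, name=f"C{i}", element="C", residue_seq=2 + i,
                 residue_name="TOY", chain_id="A", coords=p)
            for i, p in enumerate(cage_positions)
        ]
        areas, _ = sasa(Structure(atoms=atoms), probe=1.4,
                        radii={"H": 1.2, "C": 3.0})
        assert areas[0] == pytest.approx(0.0, abs=1e-9)

    def test_point_count_convergence(self):
        rng = np.random.default_rng(1)
        atoms = [
            Atom(serial=i + 1, name=f"C{i}", element="C", residue_seq=i + 1,
                 residue_name="TOY", chain_id="A", coords=rng.uniform(0, 5, 3))
            for i in range(5)
        ]
        s = Structure(atoms=atoms)
        _, total_960 = sasa(s, n_points=960)
        _, total_1920 = sasa(s, n_points=1920)
        assert abs(total_1920 - total_960) / total_960 < 0.005

    def test_agrees_with_independent_shrake_rupley(self):
        biotite_struc = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 6, size=(6, 3))
        atoms = [
            Atom(serial=i + 1, name="CA", element="C", residue_seq=i + 1,
                 residue_name="GLY", chain_id="A", coords=coords[i])
            for i in range(6)
        ]
        _, total = sasa(Structure(atoms=atoms), n_points=1920)
        arr = biotite_struc.AtomArray(6)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(["C"] * 6)
        arr.atom_name = np.array(["CA"] * 6)
        arr.res_name = np.array(["GLY"] * 6)
        arr.res_id = np.arange(1, 7)
        arr.chain_id = np.array(["A"] * 6)
        ref = float(biotite_struc.sasa(arr, point_number=1000, vdw_radii="Single").sum())
        assert total == pytest.approx(ref, rel=0.02)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            sasa(self.lone_atom(element="ZZ"))


class TestNonpolarSolvation:
    def test_zero_area_limit_is_offset_constant(self):
        assert nonpolar_solvation(0.0) == pytest.approx(0.92)

    def test_linear_in_area(self):
        assert nonpolar_solvation(1000.0) == pytest.approx(6.34)

    def test_zero_gamma_gives_constant(self):
        assert nonpolar_solvation(1234.5, gamma=0.0) == pytest.approx(0.92)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            nonpolar_solvation(-1.0)


class TestBindingSummary:
    def test_wild_type_ledger_reproduces_published_totals(self):
        ref = load_energy_components().set_index("term")
        summary = summary_from_deltas(
            ref.loc["dE_vdW", "wt_mean"], ref.loc["dE_ele", "wt_mean"],
            ref.loc["dG_GB", "wt_mean"], ref.loc["dG_SURF", "wt_mean"],
        )
        assert summary.means["dG_gas"] == pytest.approx(-143.80, abs=0.01)
        assert summary.means["dG_binding"] == pytest.approx(-55.19, abs=0.01)

    def test_mutant_ledger_reproduces_published_total(self):
        ref = load_energy_components().set_index("term")
        summary = summary_from_deltas(
            ref.loc["dE_vdW", "mut_mean"], ref.loc["dE_ele", "mut_mean"],
            ref.loc["dG_GB", "mut_mean"], ref.loc["dG_SURF", "mut_mean"],
        )
        assert summary.means["dG_gas"] == pytest.approx(-99.17, abs=0.01)
        assert summary.means["dG_binding"] == pytest.approx(-38.47, abs=0.01)

    def test_all_zero_components_give_zero_summary(self):
        summary = summary_from_deltas(0.0, 0.0, 0.0, 0.0)
        assert all(v == 0.0 for v in summary.means.values())

    def test_per_frame_ledger_closure(self):
        rng = np.random.default_rng(3)

        def comp(role):
            return EnergyComponents(
                role=role,
                E_vdW=rng.normal(size=20), E_ele=rng.normal(size=20),
                E_int=rng.normal(size=20), G_polar=rng.normal(size=20),
                G_nonpolar=rng.normal(size=20),
            )

        summary = binding_summary(comp("complex"), comp("receptor"), comp("ligand"))
        total = (summary.means["dG_gas"] + summary.means["dG_solvation"]
                 - summary.entropy_term)
        assert summary.means["dG_binding"] == pytest.approx(total, abs=1e-12)
        parts = (summary.means["dE_vdW"] + summary.means["dE_ele"]
                 + summary.means["dE_int"] + summary.means["dG_GB"]
                 + summary.means["dG_SURF"])
        assert summary.means["dG_binding"] == pytest.approx(parts, abs=1e-12)

    def test_frame_count_mismatch_rejected(self):
        a = EnergyComponents(role="complex", E_vdW=np.zeros(3), E_ele=np.zeros(3))
        b = EnergyComponents(role="receptor", E_vdW=np.zeros(2), E_ele=np.zeros(2))
        c = EnergyComponents(role="ligand", E_vdW=np.zeros(3), E_ele=np.zeros(3))
        with pytest.raises(ValueError):
            binding_summary(a, b, c)


class TestResidueDecomposition:
    @staticmethod
    def reference_tables():
        ref = load_residue_energies()
        wt = ref.rename(columns={"wt_mean": "mean", "wt_sd": "sd"})[["residue", "mean", "sd"]]
        mut = ref.rename(columns={"mut_mean": "mean", "mut_sd": "sd"})[["residue", "mean", "sd"]]
        return wt, mut

    def test_published_differences_and_flags(self):
        wt, mut = self.reference_tables()
        table = residue_decomposition(wt, mut).set_index("residue")
        assert table.loc["D29", "difference"] == pytest.approx(1.69, abs=0.005)
        assert table.loc["R135K", "difference"] == pytest.approx(7.81, abs=0.005)
        assert table.loc["I142", "difference"] == pytest.approx(0.31, abs=0.005)
        assert table["flagged"].all()  # every catalogued residue exceeds 0.3

    def test_threshold_is_strictly_greater_than(self):
        wt = pd.DataFrame({"residue": ["X1"], "mean": [0.0], "sd": [0.1]})
        mut = pd.DataFrame({"residue": ["X1"], "mean": [0.30], "sd": [0.1]})
        assert not residue_decomposition(wt, mut)["flagged"].iloc[0]
        mut["mean"] = 0.31
        assert residue_decomposition(wt, mut)["flagged"].iloc[0]

    def test_identical_inputs_have_no_flags(self):
        wt, _ = self.reference_tables()
        table = residue_decomposition(wt, wt)
        assert (table["difference"] == 0.0).all()
        assert not table["flagged"].any()

    def test_residue_in_one_system_reported_not_flagged(self):
        wt = pd.DataFrame({"residue": ["A1"], "mean": [-1.0], "sd": [0.1]})
        mut = pd.DataFrame({"residue": ["A1", "B2"], "mean": [-1.0, 5.0], "sd": [0.1, 0.1]})
        table = residue_decomposition(wt, mut).set_index("residue")
        assert np.isnan(table.loc["B2", "difference"])
        assert not table.loc["B2", "flagged"]

    def test_sum_of_decomposition_matches_total_on_consistent_ledger(self):
        rng = np.random.default_rng(9)
        contributions = rng.normal(size=8)
        wt = pd.DataFrame({"residue": [f"R{i}" for i in range(8)],
                           "mean": contributions, "sd": np.zeros(8)})
        table = residue_decomposition(wt, wt)
        assert table["G_wt"].sum() == pytest.approx(contributions.sum())
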