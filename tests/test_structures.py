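"""Molecule parsing, charges, conformers, scaffold matching and superposition."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors
from scipy.spatial.transform import Rotation

from cptqsar import structures as st
from cptqsar.errors import (
    ChargeModelError,
    DegenerateAlignmentError,
    MoleculeParseError,
    ScaffoldNotFoundError,
    UnsupportedFormatError,
)

from conftest import random_rotation

# molecular formulas from the elemental-analysis characterization of each
# synthesized compound; the SMILES fixtures must reproduce them exactly
FORMULAS = {
    "4a": "C28H23N5O4S", "4b": "C29H25N5O4S", "4c": "C28H22ClN5O4S",
    "4d": "C28H22BrN5O4S", "4e": "C29H25N5O5S", "4f": "C29H25N5O4S",
    "4g": "C29H25N5O5S", "4h": "C29H25N5O4S", "4i": "C32H25N5O4S",
    "4j": "C28H22FN5O4S", "4k": "C28H22ClN5O4S", "4l": "C28H29N5O4S",
    "5a": "C28H23N5O5", "5b": "C28H22FN5O5", "5c": "C28H22ClN5O5",
    "5d": "C28H22BrN5O5", "5e": "C29H25N5O6", "5f": "C29H25N5O5",
    "5g": "C29H25N5O6", "5h": "C28H22BrN5O5", "5i": "C28H22FN5O5",
    "5j": "C28H22ClN5O5", "5k": "C32H25N5O5", "5l": "C28H22ClN5O5",
    "6a": "C29H23N5O5S", "6b": "C30H25N5O5S", "6c": "C29H22ClN5O5S",
    "6d": "C33H25N5O5S", "1": "C20H16N2O4",
}


def _methane_block() -> str:
    mol = Chem.AddHs(Chem.MolFromSmiles("C"))
    params = AllChem.ETKDGv3()
    params.randomSeed = 7
    AllChem.EmbedMolecule(mol, params)
    mol.SetProp("_Name", "methane")
    return Chem.MolToMolBlock(mol)


class TestParsing:
    def test_sdf_identity_roundtrip(self):
        block = _methane_block()
        mol = st.parse_molecule(block, "sdf")
        assert mol.n_atoms == 5
        ref = Chem.MolFromMolBlock(block, removeHs=False).GetConformer().GetPositions()
        np.testing.assert_allclose(mol.coords, np.asarray(ref), atol=1e-8)

    def test_smiles_has_no_coordinates(self):
        mol = st.parse_molecule("CCO ethanol", "smiles")
        assert mol.id == "ethanol"
        assert mol.n_atoms == 3
        assert not mol.has_coords

    def test_mol2_block(self):
        mol2 = """@<TRIPOS>MOLECULE
methane
5 4 0 0 0
SMALL
NO_CHARGES
@<TRIPOS>ATOM
1 C 0.0 0.0 0.0 C.3
2 H 1.09 0.0 0.0 H
3 H -0.36 1.03 0.0 H
4 H -0.36 -0.51 0.89 H
5 H -0.36 -0.51 -0.89 H
@<TRIPOS>BOND
1 1 2 1
2 1 3 1
3 1 4 1
4 1 5 1
"""
        mol = st.parse_molecule(mol2, "mol2", mol_id="methane")
        assert mol.n_atoms == 5
        assert mol.has_coords

    @pytest.mark.parametrize(
        "record,fmt,exc",
        [
            ("garbage\nnot a molfile", "sdf", MoleculeParseError),
            ("C1CC", "smiles", MoleculeParseError),
            ("", "smiles", MoleculeParseError),
            ("CCO", "xyz", UnsupportedFormatError),
        ],
    )
    def test_parse_errors(self, record, fmt, exc):
        with pytest.raises(exc):
            st.parse_molecule(record, fmt)

    @pytest.mark.parametrize("cid", sorted(FORMULAS))
    def test_compound_formulas_match_elemental_analysis(self, paper_fixture, cid):
        mol = st.parse_molecule(paper_fixture.compounds[cid], "smiles", mol_id=cid)
        assert rdMolDescriptors.CalcMolFormula(mol.rdmol) == FORMULAS[cid]


class TestCharges:
    def test_methane_symmetry(self):
        mol = st.parse_molecule(_methane_block(), "sdf")
        charged = st.assign_charges(mol)
        q = charged.partial_charges
        assert q[0] < 0  # carbon
        np.testing.assert_allclose(q[1:], q[1], atol=1e-9)  # equal hydrogens
        assert abs(q.sum()) < 1e-3

    def test_chloromethane_chlorine_negative(self):
        mol = st.parse_molecule("CCl", "smiles")
        q = st.assign_charges(mol).partial_charges
        assert q[1] < 0  # PEOE pulls density onto the more electronegative atom

    def test_anion_sums_to_formal_charge(self):
        mol = st.parse_molecule("CC(=O)[O-]", "smiles")
        q = st.assign_charges(mol).partial_charges
        assert abs(q.sum() - (-1.0)) < 1e-3

    def test_determinism_bitwise(self, paper_fixture):
        mol = st.parse_molecule(paper_fixture.compounds["4d"], "smiles", mol_id="4d")
        q1 = st.assign_charges(mol).partial_charges
        q2 = st.assign_charges(mol).partial_charges
        assert np.array_equal(q1, q2)

    def test_permutation_equivariance(self):
        mol = st.parse_molecule("CCOC(=O)c1ccccc1Cl", "smiles")
        q = st.assign_charges(mol).partial_charges
        perm = list(reversed(range(mol.n_atoms)))
        rd = Chem.RenumberAtoms(mol.rdmol, perm)
        mol_p = st.Molecule3D.from_rdkit(rd, "perm")
        q_p = st.assign_charges(mol_p).partial_charges
        np.testing.assert_allclose(q_p, q[perm], atol=1e-12)

    def test_unknown_model_rejected(self):
        mol = st.parse_molecule("CC", "smiles")
        with pytest.raises(ChargeModelError):
            st.assign_charges(mol, model="am1-bcc")


class TestConformer:
    def test_ethane_bond_lengths(self, prep_config):
        mol = st.prepare_conformer(st.parse_molecule("CC", "smiles"), prep_config)
        coords = mol.coords
        for i, j, _ in mol.bonds:
            d = np.linalg.norm(coords[i] - coords[j])
            ref = 1.54 if mol.elements[i] == mol.elements[j] == "C" else 1.09
            assert abs(d - ref) / ref < 0.10

    def test_same_seed_identical_coordinates(self, prep_config):
        m1 = st.prepare_conformer(st.parse_molecule("CCOCC", "smiles"), prep_config)
        m2 = st.prepare_conformer(st.parse_molecule("CCOCC", "smiles"), prep_config)
        assert np.array_equal(m1.coords, m2.coords)

    def test_minimization_lowers_forcefield_energy(self, paper_fixture, prep_config):
        parsed = st.parse_molecule(paper_fixture.compounds["4a"], "smiles", mol_id="4a")
        rd = Chem.AddHs(Chem.Mol(parsed.rdmol))
        params = AllChem.ETKDGv3()
        params.randomSeed = prep_config.embed_seed
        AllChem.EmbedMolecule(rd, params)
        raw = st.Molecule3D.from_rdkit(rd, "4a-embedded")
        e_before = st.forcefield_energy(raw)
        prepared = st.prepare_conformer(parsed, prep_config)
        e_after = st.forcefield_energy(prepared)
        assert e_after <= e_before + 1e-6

    def test_bonded_distances_sane(self, prepared_template):
        coords = prepared_template.coords
        for i, j, _ in prepared_template.bonds:
            d = np.linalg.norm(coords[i] - coords[j])
            assert 0.5 < d < 2.5


class TestScaffold:
    def test_template_self_match_is_identity(self, prepared_template, paper_fixture):
        corr = st.match_scaffold(
            prepared_template, prepared_template, paper_fixture.scaffold_smarts
        )
        query = Chem.MolFromSmarts(paper_fixture.scaffold_smarts)
        assert corr.n_atoms == query.GetNumAtoms() == 28
        assert all(t == m for t, m in corr.pairs)

    @pytest.mark.parametrize("cid", ["4a", "4l", "5b", "5k", "6d"])
    def test_derivatives_share_28_atoms(
        self, paper_fixture, prepared_template, cid
    ):
        mol = st.parse_molecule(paper_fixture.compounds[cid], "smiles", mol_id=cid)
        corr = st.match_scaffold(mol, prepared_template, paper_fixture.scaffold_smarts)
        assert corr.n_atoms == 28
        t_el = prepared_template.elements
        m_el = mol.elements
        assert all(t_el[t] == m_el[m] for t, m in corr.pairs)

    def test_no_quinoline_core_raises(self, prepared_template, paper_fixture):
        benzene = st.parse_molecule("c1ccccc1", "smiles")
        with pytest.raises(ScaffoldNotFoundError):
            st.match_scaffold(benzene, prepared_template, paper_fixture.scaffold_smarts)

    def test_match_is_deterministic(self, paper_fixture, prepared_template):
        mol = st.parse_molecule(paper_fixture.compounds["5c"], "smiles", mol_id="5c")
        c1 = st.match_scaffold(mol, prepared_template, paper_fixture.scaffold_smarts)
        c2 = st.match_scaffold(mol, prepared_template, paper_fixture.scaffold_smarts)
        assert c1.pairs == c2.pairs


def _toy_molecule(coords, mol_id="toy"):
    n = len(coords)
    return st.Molecule3D(
        id=mol_id,
        atoms=[("C", 6, 0)] * n,
        bonds=[],
        coords=np.asarray(coords, dtype=float),
    )


def _identity_corr(n):
    return st.ScaffoldCorrespondence(
        template_id="t", target_id="m", pairs=tuple((i, i) for i in range(n))
    )


class TestSuperpose:
    def test_self_superposition_rmsd_zero(self, prepared_template, paper_fixture):
        corr = st.match_scaffold(
            prepared_template, prepared_template, paper_fixture.scaffold_smarts
        )
        moved, rmsd = st.superpose(prepared_template, prepared_template, corr)
        assert rmsd < 1e-8
        np.testing.assert_allclose(moved.coords, prepared_template.coords, atol=1e-8)

    def test_rigid_motion_recovered(self, prepared_template, paper_fixture, rng):
        R = random_rotation(rng)
        t = rng.normal(size=3) * 5
        shifted = prepared_template.copy()
        shifted.coords = prepared_template.coords @ R.T + t
        corr = st.match_scaffold(
            shifted, prepared_template, paper_fixture.scaffold_smarts
        )
        moved, rmsd = st.superpose(shifted, prepared_template, corr)
        assert rmsd < 1e-6
        np.testing.assert_allclose(moved.coords, prepared_template.coords, atol=1e-6)

    def test_internal_geometry_preserved(self, prepared_template, prepared_4a, paper_fixture):
        corr = st.match_scaffold(prepared_4a, prepared_template, paper_fixture.scaffold_smarts)
        moved, _ = st.superpose(prepared_4a, prepared_template, corr)
        d_before = np.linalg.norm(
            prepared_4a.coords[:, None] - prepared_4a.coords[None, :], axis=-1
        )
        d_after = np.linalg.norm(moved.coords[:, None] - moved.coords[None, :], axis=-1)
        np.testing.assert_allclose(d_after, d_before, atol=1e-6)

    def test_idempotent(self, prepared_template, prepared_4a, paper_fixture):
        corr = st.match_scaffold(prepared_4a, prepared_template, paper_fixture.scaffold_smarts)
        once, r1 = st.superpose(prepared_4a, prepared_template, corr)
        twice, r2 = st.superpose(once, prepared_template, corr)
        assert abs(r1 - r2) < 1e-8
        np.testing.assert_allclose(twice.coords, once.coords, atol=1e-8)

    def test_matches_brute_force_rotation_search(self, rng):
        """Kabsch result equals an exhaustive rotation-grid minimum on a
        4-point asymmetric set with differing internal geometry."""
        a = np.array([[0.0, 0, 0], [1.7, 0, 0], [0.3, 1.9, 0], [0.2, 0.4, 2.3]])
        b = np.array([[0.1, 0, 0], [1.5, 0.2, 0], [0.1, 2.1, 0.3], [0.4, 0.2, 2.0]])
        tmpl = _toy_molecule(a, "template")
        mol = _toy_molecule(b, "target")
        _, rmsd = st.superpose(mol, tmpl, _identity_corr(4))

        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)

        def grid_best(center, width, n):
            angles = [np.linspace(c - width, c + width, n) for c in center]
            best, arg = np.inf, center
            for ai in angles[0]:
                for aj in angles[1]:
                    for ak in angles[2]:
                        R = Rotation.from_euler("zyx", [ai, aj, ak]).as_matrix()
                        r = np.sqrt(np.mean(np.sum((ac - bc @ R.T) ** 2, axis=1)))
                        if r < best:
                            best, arg = r, (ai, aj, ak)
            return best, arg

        best, arg = grid_best((0.0, 0.0, 0.0), np.pi, 25)
        for width in (0.3, 0.05, 0.01, 0.002):
            best, arg = grid_best(arg, width, 11)
        assert abs(rmsd - best) < 1e-3

    def test_too_few_atoms_rejected(self):
        tmpl = _toy_molecule([[0, 0, 0], [1, 0, 0]])
        mol = _toy_molecule([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(DegenerateAlignmentError):
            st.superpose(mol, tmpl, _identity_corr(2))

    def test_collinear_atoms_rejected(self):
        line = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]
        with pytest.raises(DegenerateAlignmentError):
            st.superpose(_toy_molecule(line), _toy_molecule(line), _identity_corr(4))
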