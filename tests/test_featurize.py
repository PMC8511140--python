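"""Featurization: atom features, bond-type adjacency, descriptors, box axes."""

import numpy as np
import pytest

from ccgnet.featurize import (
    ATOM_TYPES,
    DESCRIPTOR_NAMES,
    HYBRIDIZATIONS,
    NUM_ATOM_FEATURES,
    FeaturizeError,
    box_axes,
    bond_adjacency_tensor,
    compute_descriptors,
    read_molecule,
    shrake_rupley_sasa,
    vertex_matrix,
)

D = {name: i for i, name in enumerate(DESCRIPTOR_NAMES)}
CORPUS = ["CCO", "c1ccccc1", "Oc1ccccc1", "CC(=O)Nc1ccc(O)cc1", "C1CCC2(CC1)CCCC2",
          "O=[N+]([O-])c1ccc(Cl)cc1", "CC(C)CO", "c1ccncc1", "N#Cc1ccco1"]


def _row(mol, idx):
    return vertex_matrix(mol)[idx]


class TestReadMolecule:
    @pytest.mark.parametrize(
        "smiles,n_atoms,n_bonds",
        [("CCO", 9, 8), ("c1ccccc1", 12, 12), ("C", 5, 4)],
    )
    def test_atom_and_bond_counts(self, smiles, n_atoms, n_bonds):
        mol = read_molecule(smiles)
        assert mol.num_atoms == n_atoms
        assert mol.mol.GetNumBonds() == n_bonds

    def test_same_seed_gives_bitwise_identical_coordinates(self):
        a = read_molecule("CC(=O)Nc1ccc(O)cc1", conformer_seed=11)
        b = read_molecule("CC(=O)Nc1ccc(O)cc1", conformer_seed=11)
        assert np.array_equal(a.coords, b.coords)

    def test_unparseable_record_names_the_record(self):
        with pytest.raises(FeaturizeError, match="not-a-smiles"):
            read_molecule("not-a-smiles")

    def test_disallowed_element_rejected(self):
        with pytest.raises(FeaturizeError, match="element"):
            read_molecule("[Fe]")  # metal outside the supported set


class TestAtomFeatures:
    def test_benzene_ring_carbon(self, cache):
        mol = cache.molecule("c1ccccc1")
        row = _row(mol, 0)
        assert row[ATOM_TYPES.index("C")] == 1 and row[: len(ATOM_TYPES)].sum() == 1
        off = len(ATOM_TYPES)
        assert row[off + HYBRIDIZATIONS.index("SP2")] == 1
        base = off + len(HYBRIDIZATIONS) + 3
        is_cyclic, is_aromatic = row[base + 2], row[base + 3]
        assert is_cyclic == 1 and is_aromatic == 1
        ints = base + 6
        degree, total_h, charge = row[ints + 3], row[ints + 4], row[ints + 2]
        assert degree == 3 and total_h == 1 and charge == 0

    def test_methane_hydrogen_terminal(self, cache):
        mol = cache.molecule("C")
        h_idx = next(i for i, a in enumerate(mol.mol.GetAtoms()) if a.GetSymbol() == "H")
        row = _row(mol, h_idx)
        assert row[ATOM_TYPES.index("H")] == 1
        base = len(ATOM_TYPES) + len(HYBRIDIZATIONS) + 3
        assert row[base + 3] == 0  # not aromatic
        ints = base + 6
        assert row[ints + 3] == 1 and row[ints + 4] == 0  # degree 1, no attached H

    def test_spiro_atom_flagged(self, cache):
        mol = cache.molecule("C1CCC2(CC1)CCCC2")  # spiro[4.5]decane analogue
        V = vertex_matrix(mol)
        base = len(ATOM_TYPES) + len(HYBRIDIZATIONS) + 3
        spiro_col, cyclic_col = V[:, base + 1], V[:, base + 2]
        assert spiro_col.sum() == 1
        idx = int(np.argmax(spiro_col))
        assert cyclic_col[idx] == 1

    @pytest.mark.parametrize("smiles", CORPUS)
    def test_atom_type_one_hot_sums_to_one(self, cache, smiles):
        V = vertex_matrix(cache.molecule(smiles))
        assert V.shape[1] == NUM_ATOM_FEATURES
        assert np.array_equal(V[:, : len(ATOM_TYPES)].sum(axis=1), np.ones(len(V)))
        hyb = V[:, len(ATOM_TYPES) : len(ATOM_TYPES) + len(HYBRIDIZATIONS)]
        assert (hyb.sum(axis=1) <= 1).all()


class TestAdjacencyTensor:
    def test_ethane_single_bond_slice(self, cache):
        A = bond_adjacency_tensor(cache.molecule("CC"))
        assert (A[:, :, 0] > 0).sum() == 14  # 7 bonds, symmetric
        assert A[:, :, 1:].sum() == 0

    def test_benzene_aromatic_and_ch_slices(self, cache):
        A = bond_adjacency_tensor(cache.molecule("c1ccccc1"))
        assert (A[:, :, 3] > 0).sum() == 12  # 6 aromatic bonds
        assert (A[:, :, 0] > 0).sum() == 12  # 6 C-H single bonds
        assert A[:, :, 1].sum() == 0 and A[:, :, 2].sum() == 0

    @pytest.mark.parametrize("smiles", CORPUS)
    def test_slices_symmetric_zero_diagonal_exclusive(self, cache, smiles):
        A = bond_adjacency_tensor(cache.molecule(smiles))
        for sl in range(A.shape[2]):
            assert np.array_equal(A[:, :, sl], A[:, :, sl].T)
            assert np.diagonal(A[:, :, sl]).sum() == 0
        # at most one bond type per atom pair
        assert ((A > 0).sum(axis=2) <= 1).all()


class TestDescriptors:
    def test_benzene_fractions(self, cache):
        d = compute_descriptors(cache.molecule("c1ccccc1"))
        assert d[D["Fr_NO"]] == 0.0
        assert d[D["Fr_AromaticAtoms"]] == 1.0

    def test_pyridine_fr_no(self, cache):
        d = compute_descriptors(cache.molecule("c1ccncc1"))
        assert d[D["Fr_NO"]] == pytest.approx(1 / 6)

    def test_butane_one_rotatable_bond(self, cache):
        d = compute_descriptors(cache.molecule("CCCC"))
        assert d[D["RBN"]] == 1

    def test_phenol_donor_and_globularity(self, cache):
        d = compute_descriptors(cache.molecule("Oc1ccccc1"))
        assert d[D["HBD"]] == 1
        assert 0 < d[D["Globularity"]] < 1

    @pytest.mark.parametrize("smiles", CORPUS)
    def test_descriptor_bounds(self, cache, smiles):
        d = compute_descriptors(cache.molecule(smiles))
        assert np.all(np.isfinite(d))
        s_l, s_m, m_l = d[D["S_L"]], d[D["S_M"]], d[D["M_L"]]
        assert 0 <= s_l <= s_m <= 1 and 0 <= m_l <= 1
        assert 0 <= d[D["Globularity"]] <= 1
        assert 0 <= d[D["Fr_NO"]] <= 1 and 0 <= d[D["Fr_AromaticAtoms"]] <= 1
        assert d[D["FrTPSA"]] >= 0
        assert d[D["HBA"]] >= 0 and d[D["HBD"]] >= 0 and d[D["RBN"]] >= 0

    def test_2d_descriptors_conformer_invariant(self):
        names_2d = ("Fr_NO", "Fr_AromaticAtoms", "HBA", "HBD", "RBN")
        a = compute_descriptors(read_molecule("CC(=O)Nc1ccc(O)cc1", conformer_seed=1))
        b = compute_descriptors(read_molecule("CC(=O)Nc1ccc(O)cc1", conformer_seed=99))
        for n in names_2d:
            assert a[D[n]] == b[D[n]]

    def test_sasa_matches_freesasa_oracle(self, cache):
        # independent oracle: RDKit's bundled FreeSASA implementation
        from rdkit.Chem import rdFreeSASA
        from ccgnet.featurize import _vdw_radii

        mol = cache.molecule("Oc1ccccc1")
        radii = _vdw_radii(mol.mol)
        mine = shrake_rupley_sasa(mol.coords, radii, probe=1.4)
        ref = rdFreeSASA.CalcSASA(mol.mol, [float(r) for r in radii])
        assert mine == pytest.approx(ref, rel=0.03)


class TestBoxAxes:
    def test_two_atoms_degenerate_segment(self):
        s, m, length, degenerate = box_axes(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        assert length == pytest.approx(1.0)
        assert s == pytest.approx(0.0, abs=1e-9) and m == pytest.approx(0.0, abs=1e-9)
        assert degenerate

    def test_rotation_invariance(self, cache):
        coords = cache.molecule("CC(=O)Nc1ccc(O)cc1").coords
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        a = box_axes(coords)[:3]
        b = box_axes(coords @ R.T + np.array([3.0, -1.0, 2.0]))[:3]
        assert np.allclose(a, b, atol=1e-6)

    def test_methane_near_spherical(self, cache):
        s, _, length, _ = box_axes(cache.molecule("C").coords)
        assert s / length >= 0.8
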