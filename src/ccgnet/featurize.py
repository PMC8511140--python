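"""Molecular featurization for cocrystal screening.

A coformer is represented three ways, mirroring the network's inputs:

* a vertex feature matrix ``V`` (one row of atom attributes per atom,
  explicit hydrogens included as graph nodes),
* a bond-type adjacency tensor ``A`` of shape ``N x N x 4`` whose slices
  encode single / double / triple / aromatic bonds as symmetric 0/1
  matrices, and
* a 12-descriptor *global state* vector capturing shape, size, polarity,
  flexibility and hydrogen-bonding tendency.

The atom-feature column layout is frozen (``FEATURE_LAYOUT_VERSION``);
checkpoints record it and refuse to load under a different layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Lipinski, rdMolDescriptors, rdPartialCharges

__all__ = [
    "FEATURE_LAYOUT_VERSION",
    "ATOM_TYPES",
    "NUM_ATOM_FEATURES",
    "DESCRIPTOR_NAMES",
    "DESCRIPTORS_2D",
    "DESCRIPTORS_3D",
    "Molecule3D",
    "MolecularGraph",
    "FeaturizeError",
    "read_molecule",
    "atom_features",
    "vertex_matrix",
    "bond_adjacency_tensor",
    "molecular_graph",
    "compute_descriptors",
    "box_axes",
    "shrake_rupley_sasa",
    "donor_acceptor_atoms",
]

FEATURE_LAYOUT_VERSION = "ccgnet-atom-v1"

# Table layout: 11 one-hot element types plus Si appended so every element the
# screening rules admit maps onto exactly one bit.
ATOM_TYPES = ("Cl", "N", "P", "Br", "B", "S", "I", "F", "C", "O", "H", "Si")
HYBRIDIZATIONS = ("SP2", "SP3", "SP", "S")
ALLOWED_ELEMENTS = frozenset(ATOM_TYPES)

# columns: atom type one-hot | hybridization one-hot | chirality (none,R,S) |
# is_chiral, is_spiro, is_cyclic, is_aromatic, is_acceptor, is_donor |
# explicit valence, implicit valence, formal charge, degree, total H, atomic number |
# vdW radius
NUM_ATOM_FEATURES = len(ATOM_TYPES) + len(HYBRIDIZATIONS) + 3 + 6 + 6 + 1

DESCRIPTOR_NAMES = (
    "S", "S_L", "S_M", "M_L", "Globularity", "FrTPSA",
    "Fr_NO", "Fr_AromaticAtoms", "HBA", "HBD", "RBN", "Dipole_Moment",
)
# Conformer-dependent descriptors vs. ones fixed by the 2D structure.
DESCRIPTORS_3D = ("S", "S_L", "S_M", "M_L", "Globularity", "FrTPSA", "Dipole_Moment")
DESCRIPTORS_2D = ("Fr_NO", "Fr_AromaticAtoms", "HBA", "HBD", "RBN")

BOND_TYPE_SLICES = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}
NUM_BOND_TYPES = 4

# 1 electron charge * 1 Angstrom in Debye
_EA_TO_DEBYE = 4.803204

DEFAULT_CONFORMER_SEED = 2021


class FeaturizeError(ValueError):
    """Raised for unparseable records, disallowed elements, or embedding failures."""


@dataclass
class Molecule3D:
    """An RDKit molecule with explicit hydrogens and one 3D conformer."""

    mol: Chem.Mol
    source_id: str = ""
    conformer_seed: int | None = None

    @property
    def num_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)

    @property
    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(Chem.RemoveHs(self.mol))


@dataclass
class MolecularGraph:
    """Vertex matrix V (N x C) and adjacency tensor A (N x N x L)."""

    V: np.ndarray
    A: np.ndarray
    descriptors: np.ndarray = field(default_factory=lambda: np.zeros(0))
    source_id: str = ""

    @property
    def num_nodes(self) -> int:
        return self.V.shape[0]


def _mol_from_record(record: str) -> Chem.Mol | None:
    text = record.strip()
    if "\n" in text or text.endswith("M  END"):
        return Chem.MolFromMolBlock(record, removeHs=False)
    return Chem.MolFromSmiles(text)


def read_molecule(
    record: str,
    source_id: str = "",
    conformer_seed: int = DEFAULT_CONFORMER_SEED,
) -> Molecule3D:
    """Parse a SMILES string or an SDF/MOL V2000 block into a ``Molecule3D``.

    Explicit hydrogens are added and, when the record carries no 3D
    coordinates, a conformer is embedded with distance geometry from
    ``conformer_seed`` and relaxed with MMFF (UFF fallback), so repeated
    calls are bitwise reproducible.
    """
    mol = _mol_from_record(record)
    if mol is None:
        raise FeaturizeError(f"could not parse molecule record: {record[:80]!r}")
    bad = {a.GetSymbol() for a in mol.GetAtoms()} - ALLOWED_ELEMENTS
    if bad:
        raise FeaturizeError(
            f"element(s) {sorted(bad)} outside supported set for {source_id or record[:40]!r}"
        )
    has_3d = mol.GetNumConformers() > 0 and mol.GetConformer().Is3D()
    mol = Chem.AddHs(mol, addCoords=has_3d)
    Chem.SanitizeMol(mol)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    if not has_3d:
        params = AllChem.ETKDGv3()
        params.randomSeed = int(conformer_seed)
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise FeaturizeError(f"3D embedding failed for {source_id or record[:40]!r}")
        if AllChem.MMFFHasAllMoleculeParams(mol):
            AllChem.MMFFOptimizeMolecule(mol)
        else:
            AllChem.UFFOptimizeMolecule(mol)
    if mol.GetNumAtoms() < 2:
        raise FeaturizeError("molecule must have at least two atoms")
    return Molecule3D(mol=mol, source_id=source_id, conformer_seed=conformer_seed)


def donor_acceptor_atoms(mol: Chem.Mol) -> tuple[frozenset[int], frozenset[int]]:
    """Indices of hydrogen-bond donor and acceptor atoms.

    Single authority for both the per-atom flags and the HBD/HBA counts:
    the Lipinski pharmacophore SMARTS shipped with RDKit (donor = N/O
    bearing hydrogen; acceptor = N/O with an available lone pair).
    """
    donors = frozenset(i for (i,) in mol.GetSubstructMatches(Lipinski.HDonorSmarts))
    acceptors = frozenset(i for (i,) in mol.GetSubstructMatches(Lipinski.HAcceptorSmarts))
    return donors, acceptors


def _spiro_atoms(mol: Chem.Mol) -> set[int]:
    # spiro atom: shared by two rings whose intersection is exactly that atom
    rings = [set(r) for r in mol.GetRingInfo().AtomRings()]
    out: set[int] = set()
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            inter = rings[i] & rings[j]
            if len(inter) == 1:
                out |= inter
    return out


def atom_features(molecule: Molecule3D, atom_index: int) -> np.ndarray:
    """One frozen-layout feature row for atom ``atom_index``."""
    return vertex_matrix(molecule)[atom_index]


def vertex_matrix(molecule: Molecule3D) -> np.ndarray:
    """The N x C vertex feature matrix of a molecule (explicit H as nodes)."""
    mol = molecule.mol
    donors, acceptors = donor_acceptor_atoms(mol)
    spiro = _spiro_atoms(mol)
    pt = Chem.GetPeriodicTable()
    ring_info = mol.GetRingInfo()
    V = np.zeros((mol.GetNumAtoms(), NUM_ATOM_FEATURES), dtype=float)
    for idx, atom in enumerate(mol.GetAtoms()):
        row = V[idx]
        row[ATOM_TYPES.index(atom.GetSymbol())] = 1.0
        off = len(ATOM_TYPES)
        hyb = str(atom.GetHybridization())
        if hyb in HYBRIDIZATIONS:
            row[off + HYBRIDIZATIONS.index(hyb)] = 1.0
        off += len(HYBRIDIZATIONS)
        cip = atom.GetPropsAsDict().get("_CIPCode")
        if cip == "R":
            row[off + 1] = 1.0
        elif cip == "S":
            row[off + 2] = 1.0
        else:
            row[off] = 1.0
        off += 3
        row[off + 0] = float(cip in ("R", "S"))
        row[off + 1] = float(idx in spiro)
        row[off + 2] = float(ring_info.NumAtomRings(idx) > 0)
        row[off + 3] = float(atom.GetIsAromatic())
        row[off + 4] = float(idx in acceptors)
        row[off + 5] = float(idx in donors)
        off += 6
        row[off + 0] = atom.GetExplicitValence()
        row[off + 1] = atom.GetImplicitValence()
        row[off + 2] = atom.GetFormalCharge()
        row[off + 3] = atom.GetDegree()
        row[off + 4] = atom.GetTotalNumHs(includeNeighbors=True)
        row[off + 5] = atom.GetAtomicNum()
        off += 6
        row[off] = pt.GetRvdw(atom.GetAtomicNum())
    return V


def bond_adjacency_tensor(molecule: Molecule3D) -> np.ndarray:
    """N x N x 4 one-hot bond-type adjacency tensor (single, double, triple, aromatic)."""
    mol = molecule.mol
    n = mol.GetNumAtoms()
    A = np.zeros((n, n, NUM_BOND_TYPES), dtype=float)
    for bond in mol.GetBonds():
        try:
            sl = BOND_TYPE_SLICES[bond.GetBondType()]
        except KeyError:
            raise FeaturizeError(
                f"unsupported bond type {bond.GetBondType()} in {molecule.source_id!r}"
            ) from None
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        A[i, j, sl] = A[j, i, sl] = 1.0
    return A


def molecular_graph(molecule: Molecule3D) -> MolecularGraph:
    return MolecularGraph(
        V=vertex_matrix(molecule),
        A=bond_adjacency_tensor(molecule),
        descriptors=compute_descriptors(molecule),
        source_id=molecule.source_id,
    )


# --- geometry / surface descriptors -------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 256,
) -> float:
    """Shrake–Rupley solvent-accessible surface area (Å²).

    Each atom is inflated by ``probe``; surface test points on a deterministic
    Fibonacci sphere count as accessible when outside every other inflated atom.
    ``probe=0`` yields the van der Waals surface.
    """
    coords = np.asarray(coords, dtype=float)
    r = np.asarray(radii, dtype=float) + probe
    sphere = _fibonacci_sphere(n_points)
    total = 0.0
    for i in range(len(coords)):
        pts = coords[i] + r[i] * sphere
        buried = np.zeros(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            if np.linalg.norm(coords[i] - coords[j]) > r[i] + r[j]:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            buried |= d2 < r[j] ** 2
        frac = 1.0 - buried.mean()
        total += frac * 4.0 * np.pi * r[i] ** 2
    return float(total)


def box_axes(coords: np.ndarray) -> tuple[float, float, float, bool]:
    """Extents (S, M, L) of the molecule along its principal axes, in Å.

    The enclosing box is the axis-aligned box in the principal-axis frame of
    the centered atomic coordinates (rotation and translation invariant).
    Returns ``(S, M, L, degenerate)`` with S <= M <= L; ``degenerate`` flags
    (near-)collinear geometries where S or M collapse to ~0.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2 or not np.all(np.isfinite(coords)):
        raise FeaturizeError("box_axes needs >= 2 atoms with finite coordinates")
    centered = coords - coords.mean(axis=0)
    # principal axes of the coordinate covariance
    _, _, vt = np.linalg.svd(centered, full_matrices=True)
    proj = centered @ vt.T
    extents = np.sort(proj.max(axis=0) - proj.min(axis=0))
    s, m, length = (float(x) for x in extents)
    degenerate = m < 1e-8
    return s, m, length, degenerate


def _vdw_radii(mol: Chem.Mol) -> np.ndarray:
    pt = Chem.GetPeriodicTable()
    return np.array([pt.GetRvdw(a.GetAtomicNum()) for a in mol.GetAtoms()])


def _dipole_moment(molecule: Molecule3D) -> float:
    mol = Chem.Mol(molecule.mol)
    rdPartialCharges.ComputeGasteigerCharges(mol)
    q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()])
    q = np.nan_to_num(q)
    mu = (q[:, None] * molecule.coords).sum(axis=0)
    return float(np.linalg.norm(mu) * _EA_TO_DEBYE)


def compute_descriptors(molecule: Molecule3D) -> np.ndarray:
    """The 12-descriptor global-state vector, ordered as ``DESCRIPTOR_NAMES``.

    Shape (S and the box-axis ratios, globularity), surface polarity
    (TPSA/SASA), composition fractions, H-bond donor/acceptor and rotatable
    bond counts, and the Gasteiger point-charge dipole moment in Debye.
    """
    mol = molecule.mol
    if mol.GetNumConformers() == 0:
        raise FeaturizeError("descriptors need 3D coordinates")
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    if not heavy:
        raise FeaturizeError("descriptors undefined for a molecule with no heavy atoms")

    coords = molecule.coords
    s, m, length, _ = box_axes(coords)
    radii = _vdw_radii(mol)
    sasa = shrake_rupley_sasa(coords, radii, probe=1.4)
    vdw_area = shrake_rupley_sasa(coords, radii, probe=0.0)
    volume = AllChem.ComputeMolVolume(mol)
    sphere_area = (36.0 * np.pi * volume**2) ** (1.0 / 3.0)
    globularity = float(np.clip(sphere_area / vdw_area, 0.0, 1.0))

    tpsa = rdMolDescriptors.CalcTPSA(mol)
    n_heavy = len(heavy)
    n_no = sum(1 for a in heavy if a.GetAtomicNum() in (7, 8))
    n_arom = sum(1 for a in heavy if a.GetIsAromatic())
    donors, acceptors = donor_acceptor_atoms(mol)
    # rotatable bonds on the implicit-H graph so terminal heavy atoms stay terminal
    rbn = rdMolDescriptors.CalcNumRotatableBonds(Chem.RemoveHs(mol))

    return np.array(
        [
            s,
            s / length if length > 0 else 0.0,
            s / m if m > 0 else 0.0,
            m / length if length > 0 else 0.0,
            globularity,
            tpsa / sasa if sasa > 0 else 0.0,
            n_no / n_heavy,
            n_arom / n_heavy,
            float(len(acceptors)),
            float(len(donors)),
            float(rbn),
            _dipole_moment(molecule),
        ],
        dtype=float,
    )
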