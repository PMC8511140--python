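"""Pairing coformers into cocrystal graph samples.

A sample (``CCGraph``) is the disjoint union of two coformer graphs: stacked
vertex matrices, a block-diagonal bond-type adjacency tensor with no
cross-coformer edges, and a 2 x 12 global-state matrix holding each
coformer's descriptors. This module also hosts the dataset plumbing around
it: the screening rules applied when curating pairs, order-swap data
augmentation, stratified fold assignment (augmentation twins co-assigned),
and batch padding for the network.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
from rdkit import Chem
from sklearn.model_selection import StratifiedKFold

from .featurize import (
    DESCRIPTOR_NAMES,
    Molecule3D,
    MolecularGraph,
    molecular_graph,
    read_molecule,
)

__all__ = [
    "CCGraph",
    "ScreeningRules",
    "FoldAssignment",
    "load_solvent_blacklist",
    "screen_pair",
    "make_ccgraph",
    "pair_from_smiles",
    "augment",
    "stratified_kfold",
    "pad_batch",
    "unpad_batch",
    "save_dataset",
    "load_dataset",
    "FeaturizerCache",
]

DEFAULT_N_MAX = 160
SCREEN_ELEMENTS = frozenset({"C", "H", "O", "N", "P", "S", "Cl", "Br", "I", "F", "Si"})


@dataclass
class CCGraph:
    """One cocrystal sample: disjoint union of two coformer graphs."""

    V: np.ndarray            # (n+m) x C stacked vertex matrix
    A: np.ndarray            # (n+m) x (n+m) x L block-diagonal adjacency tensor
    U: np.ndarray            # 2 x 12 global-state matrix (row per coformer)
    coformer_slices: tuple[slice, slice]
    label: int | None = None
    sample_id: str = ""
    twin_of: str | None = None

    @property
    def num_nodes(self) -> int:
        return self.V.shape[0]

    @property
    def comp(self) -> np.ndarray:
        """0/1 coformer membership per node."""
        out = np.zeros(self.num_nodes, dtype=np.int64)
        out[self.coformer_slices[1]] = 1
        return out

    def swapped(self) -> "CCGraph":
        """The order-swapped twin: coformer 2 first, same label."""
        s1, s2 = self.coformer_slices
        n1, n2 = s1.stop - s1.start, s2.stop - s2.start
        perm = np.concatenate([np.arange(s2.start, s2.stop), np.arange(s1.start, s1.stop)])
        return CCGraph(
            V=self.V[perm],
            A=self.A[np.ix_(perm, perm)],
            U=self.U[::-1].copy(),
            coformer_slices=(slice(0, n2), slice(n2, n2 + n1)),
            label=self.label,
            sample_id=f"{self.sample_id}#swap",
            twin_of=self.sample_id,
        )


@dataclass(frozen=True)
class ScreeningRules:
    """Dataset-curation rules for candidate coformer pairs."""

    solvent_blacklist: frozenset[str]
    allowed_elements: frozenset[str] = SCREEN_ELEMENTS
    mw_max: float = 700.0
    require_neutral: bool = True
    require_two_components: bool = True

    @classmethod
    def default(cls) -> "ScreeningRules":
        return cls(solvent_blacklist=load_solvent_blacklist())


def load_solvent_blacklist() -> frozenset[str]:
    """Canonical SMILES of common solvents / small molecules to exclude.

    The packaged list is a curated stand-in configuration of solvents that
    are liquid or gaseous at room temperature; entries are canonicalized at
    load so lookups are representation independent.
    """
    text = resources.files("ccgnet.data").joinpath("solvent_blacklist.smi").read_text()
    out = set()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles = line.split()[0]
        mol = Chem.MolFromSmiles(smiles)
        if mol is not None:
            out.add(Chem.MolToSmiles(mol))
    return frozenset(out)


def blacklist_hash() -> str:
    data = resources.files("ccgnet.data").joinpath("solvent_blacklist.smi").read_bytes()
    return hashlib.sha256(data).hexdigest()[:16]


def _component_violations(mol: Molecule3D, rules: ScreeningRules) -> list[str]:
    from rdkit.Chem import Descriptors

    reasons = []
    heavy_mol = Chem.RemoveHs(mol.mol)
    elements = {a.GetSymbol() for a in mol.mol.GetAtoms()}
    if not elements <= rules.allowed_elements:
        reasons.append("allowed_elements")
    if Descriptors.MolWt(mol.mol) >= rules.mw_max:
        reasons.append("mw_max")
    if rules.require_neutral and Chem.GetFormalCharge(mol.mol) != 0:
        reasons.append("require_neutral")
    if Chem.MolToSmiles(heavy_mol) in rules.solvent_blacklist:
        reasons.append("solvent_blacklist")
    return reasons


def screen_pair(
    a: Molecule3D, b: Molecule3D, rules: ScreeningRules | None = None
) -> tuple[bool, list[str]]:
    """Apply the curation rules to a candidate pair.

    Violations are reported by rule name, never raised; a pair is accepted
    iff every rule passes for both components.
    """
    rules = rules or ScreeningRules.default()
    reasons = sorted(set(_component_violations(a, rules) + _component_violations(b, rules)))
    if rules.require_two_components and a.canonical_smiles == b.canonical_smiles:
        reasons.append("require_two_components")
    return (not reasons, reasons)


def make_ccgraph(
    a_graph: MolecularGraph,
    b_graph: MolecularGraph,
    label: int | None = None,
    sample_id: str = "",
) -> CCGraph:
    """Disjoint-union two coformer graphs into one sample (no cross edges)."""
    if a_graph.V.shape[1] != b_graph.V.shape[1]:
        raise ValueError("coformers have mismatched feature layouts")
    n, m = a_graph.num_nodes, b_graph.num_nodes
    L = a_graph.A.shape[2]
    V = np.vstack([a_graph.V, b_graph.V])
    A = np.zeros((n + m, n + m, L), dtype=float)
    A[:n, :n] = a_graph.A
    A[n:, n:] = b_graph.A
    U = np.vstack([a_graph.descriptors, b_graph.descriptors])
    if U.shape != (2, len(DESCRIPTOR_NAMES)):
        raise ValueError(f"global state must be 2 x {len(DESCRIPTOR_NAMES)}")
    return CCGraph(
        V=V, A=A, U=U, coformer_slices=(slice(0, n), slice(n, n + m)),
        label=label, sample_id=sample_id,
    )


class FeaturizerCache:
    """Featurize each unique molecule once, keyed by canonical SMILES."""

    def __init__(self, conformer_seed: int = 2021):
        self.conformer_seed = conformer_seed
        self._graphs: dict[str, MolecularGraph] = {}
        self._mols: dict[str, Molecule3D] = {}

    def molecule(self, record: str) -> Molecule3D:
        if record not in self._mols:
            self._mols[record] = read_molecule(
                record, source_id=record, conformer_seed=self.conformer_seed
            )
        return self._mols[record]

    def graph(self, record: str) -> MolecularGraph:
        if record not in self._graphs:
            self._graphs[record] = molecular_graph(self.molecule(record))
        return self._graphs[record]


def pair_from_smiles(
    smiles_a: str,
    smiles_b: str,
    label: int | None = None,
    sample_id: str = "",
    cache: FeaturizerCache | None = None,
) -> CCGraph:
    cache = cache or FeaturizerCache()
    return make_ccgraph(cache.graph(smiles_a), cache.graph(smiles_b), label, sample_id)


def augment(samples: list[CCGraph]) -> list[CCGraph]:
    """Double the sample list by appending each sample's order-swapped twin."""
    out: list[CCGraph] = []
    for s in samples:
        out.append(s)
        out.append(s.swapped())
    return out


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of the pre-augmentation samples into k folds."""

    k: int
    assignment: dict[str, int]
    seed: int

    def fold_of(self, sample: CCGraph) -> int:
        key = sample.twin_of if sample.twin_of is not None else sample.sample_id
        return self.assignment[key]


def stratified_kfold(samples: list[CCGraph], k: int, seed: int = 0) -> FoldAssignment:
    """Stratified fold assignment over original (unaugmented) samples.

    Augmentation twins inherit their original's fold via ``fold_of``, so
    splitting before augmentation can never leak a twin across the
    train/validation boundary.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.array([s.label for s in samples])
    if None in [s.label for s in samples]:
        raise ValueError("fold assignment requires labeled samples")
    counts = np.bincount(labels.astype(int), minlength=2)
    if counts.min() < k:
        raise ValueError(f"k={k} exceeds minority class count {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(len(samples)), labels)):
        for i in val_idx:
            assignment[samples[i].sample_id] = fold
    return FoldAssignment(k=k, assignment=assignment, seed=seed)


def pad_batch(graphs: list[CCGraph], n_max: int = DEFAULT_N_MAX) -> dict:
    """Pad a list of samples into dense batch tensors plus a node mask.

    Padded V rows are zero, padded A rows/columns are zero, and the mask is
    1 on real nodes only; downstream attention softmaxes must ignore masked
    nodes.
    """
    too_big = [g.sample_id for g in graphs if g.num_nodes > n_max]
    if too_big:
        raise ValueError(f"graphs exceed N_max={n_max}: {too_big}")
    B = len(graphs)
    C = graphs[0].V.shape[1]
    L = graphs[0].A.shape[2]
    D = graphs[0].U.shape[1]
    V = np.zeros((B, n_max, C))
    A = np.zeros((B, n_max, n_max, L))
    U = np.zeros((B, 2, D))
    mask = np.zeros((B, n_max))
    comp = np.zeros((B, n_max), dtype=np.int64)
    labels = np.full(B, -1, dtype=np.int64)
    for i, g in enumerate(graphs):
        n = g.num_nodes
        V[i, :n] = g.V
        A[i, :n, :n] = g.A
        U[i] = g.U
        mask[i, :n] = 1.0
        comp[i, :n] = g.comp
        if g.label is not None:
            labels[i] = g.label
    return {
        "V": V, "A": A, "U": U, "mask": mask, "comp": comp, "labels": labels,
        "ids": [g.sample_id for g in graphs],
        "n_nodes": np.array([g.num_nodes for g in graphs]),
        "split_at": np.array([g.coformer_slices[0].stop for g in graphs]),
    }


def unpad_batch(batch: dict) -> list[CCGraph]:
    """Recover the original CCGraph list from a padded batch (lossless)."""
    out = []
    for i in range(len(batch["ids"])):
        n = int(batch["n_nodes"][i])
        split = int(batch["split_at"][i])
        label = int(batch["labels"][i])
        out.append(
            CCGraph(
                V=batch["V"][i, :n].copy(),
                A=batch["A"][i, :n, :n].copy(),
                U=batch["U"][i].copy(),
                coformer_slices=(slice(0, split), slice(split, n)),
                label=None if label < 0 else label,
                sample_id=batch["ids"][i],
            )
        )
    return out


def save_dataset(path: str, graphs: list[CCGraph], n_max: int = DEFAULT_N_MAX, **meta):
    """Serialize padded tensors plus provenance metadata to HDF5."""
    import h5py

    from .featurize import FEATURE_LAYOUT_VERSION

    batch = pad_batch(graphs, n_max=n_max)
    with h5py.File(path, "w") as f:
        for key in ("V", "A", "U", "mask", "comp", "labels", "n_nodes", "split_at"):
            f.create_dataset(key, data=batch[key])
        f.create_dataset("ids", data=np.array(batch["ids"], dtype="S"))
        f.attrs["feature_layout"] = FEATURE_LAYOUT_VERSION
        f.attrs["blacklist_hash"] = blacklist_hash()
        for k, v in meta.items():
            f.attrs[k] = v


def load_dataset(path: str) -> list[CCGraph]:
    import h5py

    from .featurize import FEATURE_LAYOUT_VERSION

    with h5py.File(path, "r") as f:
        if f.attrs["feature_layout"] != FEATURE_LAYOUT_VERSION:
            raise ValueError("dataset feature layout does not match this package version")
        batch = {k: f[k][...] for k in
                 ("V", "A", "U", "mask", "comp", "labels", "n_nodes", "split_at")}
        batch["ids"] = [s.decode() for s in f["ids"][...]]
    return unpad_batch(batch)
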