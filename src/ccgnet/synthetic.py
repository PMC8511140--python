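"""Deterministic synthetic molecule libraries and planted-rule pair labels.

Everything downstream (training, transfer, screening reports) is exercised
without any database access: a fragment-grammar molecule generator produces
small, neutral, screening-compliant organics, and a planted labeling rule
assigns each pair a "cocrystallizes" label from a fixed linear score over
the 12 global-state descriptors plus a donor/acceptor complementarity term

    s(a, b) = sum_d w_d (d(a) + d(b))
              + w_c (min(HBD_a, HBA_b) + min(HBD_b, HBA_a))

labeled positive iff ``s >= tau``, then flipped with probability ``eps``.
The rule deliberately mixes 2D and 3D descriptors with a pair-level
complementarity term so that graph-only ablations underperform the
descriptor-fused model, and the default threshold is calibrated to the
~6.5:1 positive:negative imbalance of experimentally curated cocrystal
data. A "shifted" rule variant with altered weights emulates a
domain-shifted family (the transfer-learning target).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from rdkit import Chem

from .featurize import DESCRIPTOR_NAMES, donor_acceptor_atoms
from .graphdata import CCGraph, FeaturizerCache, load_solvent_blacklist, pair_from_smiles
from .network import GraphConvWeights

__all__ = [
    "PlantedRule",
    "DEFAULT_RULE",
    "SHIFTED_RULE",
    "molecule_library",
    "planted_pairs",
    "rule_score",
    "pairs_to_graphs",
    "make_planted_dataset",
    "calibrate_threshold",
    "tiny_graph_fixtures",
    "loop_graph_conv",
]

_CORES = (
    "c1ccc({a})cc1",                   # benzene, mono
    "c1ccc({a})c({b})c1",              # benzene, ortho
    "c1cc({a})cc({b})c1",              # benzene, meta
    "c1cc({a})ccn1",                   # pyridine, mono
    "c1cc({a})cnc1{b}",                # pyridine, di
    "c1cc({a})oc1",                    # furan, mono
    "c1c({b})c({a})oc1",               # furan, di
    "c1ccc2cc({a})ccc2c1",             # naphthalene, mono
    "c1cc({a})c2cc({b})ccc2c1",        # naphthalene, di
    "c1ccc(-c2ccc({a})cc2{b})cc1",     # biphenyl
    "c1ccc(Cc2ccc({a})cc2)cc1{b}",     # diphenylmethane bridge
    "c1ccc(Oc2ccc({a})cc2)cc1{b}",     # diphenyl ether bridge
    "c1ccc(CC({a})c2ccccc2)cc1",       # flexible ethylene bridge
    "c1cc2ccccc2c(N({a})C)c1",         # N-methyl naphthylamine-like (branching N)
)
_DONOR_SUBS = ("O", "N", "C(=O)O", "CO", "C(N)=O")
_APOLAR_SUBS = ("C", "CC", "F", "Cl", "Br", "C#N", "OC", "[N+](=O)[O-]", "C(C)=O")


@dataclass(frozen=True)
class PlantedRule:
    """Descriptor-based labeling rule for synthetic coformer pairs."""

    weights: tuple[tuple[str, float], ...]
    complementarity: float
    threshold: float
    noise: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.noise <= 0.1:
            raise ValueError("label-noise rate must be in [0, 0.1]")
        for name, _ in self.weights:
            if name not in DESCRIPTOR_NAMES:
                raise ValueError(f"unknown descriptor {name!r}")


# Default rule: polar-surface/composition driven, donor<->acceptor
# complementarity rewarded, flexibility penalized. The threshold is
# calibrated once so that the default library (n=50, seed=7) at m=600 pairs
# lands in the 6:1 .. 7:1 positive:negative band.
DEFAULT_RULE = PlantedRule(
    weights=(
        ("HBD", 3.5),
        ("FrTPSA", 8.0),
        ("Globularity", 10.0),
        ("S_L", 2.0),
    ),
    complementarity=0.5,
    # calibrated once on the default library (n=50, seed=7), m=600, seed=7:
    # yields 520 positive / 80 negative = 6.5:1
    threshold=19.4316,
    noise=0.0,
)

# Domain-shifted family: the drivers change sign/magnitude (polar surface now
# penalized, flexibility rewarded), emulating a chemistry where the learned
# weighting no longer transfers directly.
SHIFTED_RULE = PlantedRule(
    weights=(
        ("FrTPSA", -6.0),
        ("Fr_NO", 4.0),
        ("Dipole_Moment", 0.6),
        ("Fr_AromaticAtoms", -2.0),
        ("RBN", 0.5),
    ),
    complementarity=-0.5,
    # calibrated to a balanced split (120:120) at m=240, seed=11 on the
    # default library, mirroring the small, balanced target-domain set
    threshold=1.0399,
    noise=0.0,
)


def molecule_library(n: int, seed: int = 7) -> list[str]:
    """``n`` distinct, neutral, screening-compliant SMILES from the grammar.

    Deterministic given ``seed``. Roughly 64% of the library carries an
    H-bond donor and ~36% is donor-free (both classes always >= 20%), and
    every molecule has at least one acceptor, so donor/acceptor
    complementarity across a pair is controlled by the donor side.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    blacklist = load_solvent_blacklist()
    lib: list[str] = []
    seen: set[str] = set()
    n_donor = n_free = 0
    free_quota = int(np.ceil(0.38 * n))
    guard = 0
    while len(lib) < n and guard < 200 * n:
        guard += 1
        mode = "free" if n_free < free_quota else "donor"
        core = _CORES[rng.integers(len(_CORES))]
        if mode == "donor":
            a = _DONOR_SUBS[rng.integers(len(_DONOR_SUBS))]
            b = (_DONOR_SUBS + _APOLAR_SUBS)[rng.integers(len(_DONOR_SUBS + _APOLAR_SUBS))]
        else:
            a = _APOLAR_SUBS[rng.integers(len(_APOLAR_SUBS))]
            b = _APOLAR_SUBS[rng.integers(len(_APOLAR_SUBS))]
        smiles = core.format(a=a, b=b)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen or canon in blacklist:
            continue
        donors, acceptors = donor_acceptor_atoms(Chem.AddHs(mol))
        has_donor = len(donors) > 0
        if len(acceptors) == 0:
            continue
        if mode == "donor" and not has_donor:
            continue
        if mode == "free" and has_donor:
            continue
        seen.add(canon)
        lib.append(canon)
        n_donor += int(has_donor)
        n_free += int(not has_donor)
    if len(lib) < n:
        raise RuntimeError("fragment grammar exhausted before reaching n molecules")
    return lib


def rule_score(rule: PlantedRule, desc_a: np.ndarray, desc_b: np.ndarray) -> float:
    """The planted score of one pair from the two 12-descriptor vectors."""
    idx = {name: DESCRIPTOR_NAMES.index(name) for name, _ in rule.weights}
    s = sum(w * (desc_a[idx[name]] + desc_b[idx[name]]) for name, w in rule.weights)
    hba, hbd = DESCRIPTOR_NAMES.index("HBA"), DESCRIPTOR_NAMES.index("HBD")
    s += rule.complementarity * (
        min(desc_a[hbd], desc_b[hba]) + min(desc_b[hbd], desc_a[hba])
    )
    return float(s)


def planted_pairs(
    library: list[str],
    m: int,
    rule: PlantedRule = DEFAULT_RULE,
    seed: int = 7,
    cache: FeaturizerCache | None = None,
) -> pd.DataFrame:
    """``m`` labeled coformer pairs drawn without replacement from the library.

    Columns: id, coformer_a, coformer_b, label. Label = planted rule score
    thresholded at ``rule.threshold``, then flipped with probability
    ``rule.noise``. Fully reproducible from (library, rule, seed).
    """
    n = len(library)
    if n == 0:
        raise ValueError("empty library")
    max_pairs = n * (n - 1) // 2
    if m > max_pairs:
        raise ValueError(f"m={m} exceeds the {max_pairs} distinct unordered pairs")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(max_pairs, size=m, replace=False)
    iu = np.triu_indices(n, k=1)
    cache = cache or FeaturizerCache()
    rows = []
    for t, c in enumerate(chosen):
        a, b = library[iu[0][c]], library[iu[1][c]]
        s = rule_score(rule, cache.graph(a).descriptors, cache.graph(b).descriptors)
        label = int(s >= rule.threshold)
        if rule.noise > 0 and rng.random() < rule.noise:
            label = 1 - label
        rows.append({"id": f"pair{t:04d}", "coformer_a": a, "coformer_b": b, "label": label})
    return pd.DataFrame(rows)


def pairs_to_graphs(pairs: pd.DataFrame, cache: FeaturizerCache | None = None) -> list[CCGraph]:
    cache = cache or FeaturizerCache()
    return [
        pair_from_smiles(r.coformer_a, r.coformer_b,
                         label=None if pd.isna(getattr(r, "label", None)) else int(r.label),
                         sample_id=str(r.id), cache=cache)
        for r in pairs.itertuples(index=False)
    ]


def make_planted_dataset(
    n_molecules: int = 50,
    m_pairs: int = 600,
    rule: PlantedRule = DEFAULT_RULE,
    seed: int = 7,
    cache: FeaturizerCache | None = None,
) -> tuple[list[CCGraph], pd.DataFrame]:
    """Library + labeled pairs + featurized samples in one call."""
    cache = cache or FeaturizerCache()
    lib = molecule_library(n_molecules, seed=seed)
    pairs = planted_pairs(lib, m_pairs, rule=rule, seed=seed, cache=cache)
    return pairs_to_graphs(pairs, cache), pairs


def calibrate_threshold(
    library: list[str],
    m: int,
    rule: PlantedRule,
    seed: int = 7,
    target_positive_fraction: float = 6.5 / 7.5,
    cache: FeaturizerCache | None = None,
) -> float:
    """Threshold giving the target class balance on a concrete pair draw."""
    probe = replace(rule, threshold=-np.inf, noise=0.0)
    cache = cache or FeaturizerCache()
    pairs = planted_pairs(library, m, rule=probe, seed=seed, cache=cache)
    scores = np.array([
        rule_score(rule, cache.graph(r.coformer_a).descriptors,
                   cache.graph(r.coformer_b).descriptors)
        for r in pairs.itertuples(index=False)
    ])
    return float(np.quantile(scores, 1.0 - target_positive_fraction))


# --- hand-checkable tiny graph fixtures ----------------------------------------------

def loop_graph_conv(V, A, weights: GraphConvWeights) -> np.ndarray:
    """Independent loop-based evaluator of the bond-type graph convolution.

    Materializes the full N x N filter for every (input channel, output
    filter) pair; intentionally naive, used as the oracle for the vectorized
    implementation (identity activation).
    """
    V = np.asarray(V, dtype=float)
    A = np.asarray(A, dtype=float)
    L, C, F = weights.h.shape
    N = V.shape[0]
    out = np.zeros((N, F))
    for f in range(F):
        for c in range(C):
            Hcf = np.zeros((N, N))
            for l in range(L):
                Hcf += weights.h[l, c, f] * A[:, :, l]
            out[:, f] += Hcf @ V[:, c]
        out[:, f] += weights.b[f]
    out += V @ weights.W0
    return out


def tiny_graph_fixtures() -> list[dict]:
    """Hand-computable graphs with frozen expected convolution outputs."""
    fixtures = []

    # 1. two nodes, one edge, unit weights: neighbor sum plus self
    w = GraphConvWeights(h=np.ones((1, 1, 1)), W0=np.ones((1, 1)), b=np.zeros(1))
    fixtures.append({
        "name": "two-node-edge",
        "V": np.array([[1.0], [2.0]]),
        "A": np.array([[0.0, 1.0], [1.0, 0.0]]).reshape(2, 2, 1),
        "weights": w,
        "expected": np.array([[3.0], [3.0]]),
    })

    # 2. no edges, identity self-loop: output equals input
    w = GraphConvWeights(h=np.ones((1, 2, 2)), W0=np.eye(2), b=np.zeros(2))
    fixtures.append({
        "name": "isolated-identity",
        "V": np.array([[1.0, -1.0], [0.5, 2.0], [3.0, 0.0]]),
        "A": np.zeros((3, 3, 1)),
        "weights": w,
        "expected": np.array([[1.0, -1.0], [0.5, 2.0], [3.0, 0.0]]),
    })

    # 3. three-node path, unit weights, zero self-loop: pure neighbor sums
    w = GraphConvWeights(h=np.ones((1, 1, 1)), W0=np.zeros((1, 1)), b=np.zeros(1))
    A = np.zeros((3, 3, 1))
    A[0, 1, 0] = A[1, 0, 0] = A[1, 2, 0] = A[2, 1, 0] = 1.0
    fixtures.append({
        "name": "path-neighbor-sum",
        "V": np.array([[1.0], [2.0], [4.0]]),
        "A": A,
        "weights": w,
        "expected": np.array([[2.0], [5.0], [2.0]]),  # degree-weighted neighbor sums
    })

    # 4. two bond-type slices with different scalar filters
    h = np.zeros((2, 1, 1)); h[0, 0, 0] = 1.0; h[1, 0, 0] = 10.0
    w = GraphConvWeights(h=h, W0=np.zeros((1, 1)), b=np.zeros(1))
    A = np.zeros((3, 3, 2))
    A[0, 1, 0] = A[1, 0, 0] = 1.0   # type-0 edge 0-1
    A[1, 2, 1] = A[2, 1, 1] = 1.0   # type-1 edge 1-2
    fixtures.append({
        "name": "bond-type-slices",
        "V": np.array([[1.0], [1.0], [1.0]]),
        "A": A,
        "weights": w,
        "expected": np.array([[1.0], [11.0], [10.0]]),
    })

    # 5. bias and two filters: constant shift visible per filter
    h = np.ones((1, 1, 2))
    w = GraphConvWeights(h=h, W0=np.zeros((1, 2)), b=np.array([0.5, -0.5]))
    A = np.zeros((2, 2, 1)); A[0, 1, 0] = A[1, 0, 0] = 1.0
    fixtures.append({
        "name": "bias-two-filters",
        "V": np.array([[2.0], [3.0]]),
        "A": A,
        "weights": w,
        "expected": np.array([[3.5, 2.5], [2.5, 1.5]]),
    })

    for fx in fixtures:
        assert np.allclose(loop_graph_conv(fx["V"], fx["A"], fx["weights"]), fx["expected"])
    return fixtures
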