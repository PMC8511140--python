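# Methods

## The prediction problem

Whether two small organic molecules co-crystallize is a pair-level binary
classification problem with a strong class imbalance: experimentally
confirmed cocrystals vastly outnumber published failed screens (roughly
6.5:1 in curated collections). The model combines two complementary views
of each coformer:

* **Molecular graph** — atoms as nodes carrying a frozen 32-column feature
  layout (element one-hot, hybridization, chirality, ring/aromatic/spiro
  flags, H-bond donor/acceptor flags, valences, formal charge, degree,
  attached-H count, atomic number, van der Waals radius), bonds as a
  4-slice adjacency tensor (single / double / triple / aromatic). Explicit
  hydrogens are graph nodes; the redundant per-atom "total H" count is kept
  because the feature list is taken literally.
* **Global state** — 12 whole-molecule descriptors capturing shape
  (principal-axis box extents S and the ratios S/L, S/M, M/L; globularity),
  surface polarity (TPSA/SASA), composition (fraction of N+O and of
  aromatic heavy atoms), hydrogen-bond capacity (HBA, HBD), flexibility
  (rotatable bonds) and the point-charge dipole moment.

## Architecture

Four message-passing blocks, each of which (i) updates the two coformers'
global-state rows with a shared single-layer feedforward net, (ii) runs a
bond-type graph convolution `V' = relu(V W0 + sum_l A_l V h_l + b)` whose
filters are one scalar per (bond-type slice, input channel, output filter),
and (iii) concatenates each coformer's updated global state onto every atom
of that coformer. The readout is K=2 parallel global-attention heads (a
2-layer MLP scores each node; a masked softmax over the real nodes of the
pair weights a sum of node vectors), concatenated with both rows of the
final global state, followed by a dense head ending in two logits [a, b].
The pair is predicted to co-crystallize iff b > a; an exact tie classifies
negative, the conservative choice for screening.

Everything is implemented in NumPy (float64) with hand-derived reverse-mode
gradients; the test suite verifies them against central finite differences
on every parameter tensor. Training is Adam with softmax cross-entropy, no
class weighting: robustness to the imbalance is carried by the features
and architecture, not by loss reweighting.

## Regularization and capacity for small datasets

Two width presets exist. The library default (conv widths 64/64/128/128,
global widths matching, dense 256-128-2) mirrors commonly used GNN sizes
for datasets of several thousand pairs. The bundled experiments use a
compact preset chosen for CPU-scale runs and for the small (hundreds of
pairs) synthetic sets: conv widths 4/4/4/4, global widths 16/16/32/32,
attention hidden 4, dense 64-32-2. At this data scale the graph branch has
far more effective parameters per unit of usable signal than the
12-descriptor path and is the dominant source of overfitting (training
balanced accuracy near 100% against mid-80s held out), so weight decay is
group-specific: 1e-4 on dense/global weights and a stronger decay on the
convolution filters and attention scorers (`graph_weight_decay`). Biases
are never decayed. An optional train-time Gaussian jitter on the
descriptors exists but is off by default — it measurably blurs decision
boundaries that run close to descriptor thresholds.

Determinism: one run seed drives weight initialization, shuffling and any
jitter; two runs with the same seed produce bitwise-identical loss
trajectories. Minibatches are cropped to the largest graph they contain;
predictions are padding-invariant (tested to 1e-6), so this is exact.

## Featurization choices

* Conformers: ETKDGv3 distance-geometry embedding with a fixed, recorded
  seed, then MMFF (UFF fallback) minimization. Same SMILES + same seed give
  bitwise-identical coordinates.
* Enclosing box: extents along the three principal axes of the centered
  atomic coordinates — rotation/translation invariant and reproducible,
  with no van der Waals padding. Planar molecules therefore have S ~ 0;
  the short axis acts as a planarity indicator rather than a physical
  thickness.
* SASA: an own Shrake–Rupley implementation (deterministic 256-point
  Fibonacci sphere per atom, 1.4 Å probe, Bondi-type vdW radii); it agrees
  with RDKit's FreeSASA to ~2% and a probe of 0 yields the vdW surface used
  in globularity (sphere-surface-of-equal-volume / vdW surface, clamped to
  [0, 1] against grid-volume noise).
* Donor/acceptor definitions are pinned in one function (RDKit's Lipinski
  pharmacophore SMARTS); the per-atom flags and the HBD/HBA counts both use
  it, so they can never disagree.
* Dipole moment: magnitude of the Gasteiger-point-charge dipole on the
  generated conformer, in Debye. A quantum-chemical dipole is out of scope.
* Rotatable bonds are counted on the implicit-H graph so terminal heavy
  atoms stay terminal.
* The atom-type one-hot spans 12 elements (the 11 standard ones plus Si,
  which the dataset screening rules admit), so "exactly one type bit per
  atom" holds for every screenable molecule. The layout is versioned;
  checkpoints refuse to load across layout changes.

## Dataset handling

Screening rules for candidate pairs (two chemically different components;
allowed-element whitelist; each component's molecular weight < 700; neutral
components; a packaged solvent blacklist treated as configuration) are
reported as named violations, never raised. Order-swap augmentation doubles
a labeled set; folds are assigned by stratified splitting *before*
augmentation and each swapped twin inherits its original's fold, so twins
can never straddle a train/validation boundary. Cross-validation trains on
k-1 augmented folds and evaluates on the held-out unaugmented fold.

## The synthetic benchmark family

The generator builds neutral, screening-compliant molecules from a fragment
grammar (benzene / pyridine / furan / naphthalene cores, bridged biphenyls
and diphenyl ethers/methanes, donor and apolar substituents). Roughly 64%
of a library carries an H-bond donor, ~36% is donor-free, and every
molecule has at least one acceptor, so donor/acceptor complementarity
varies across pairs. Labels come from a planted linear rule over both
coformers' descriptors plus a complementarity term
min(HBD_a, HBA_b) + min(HBD_b, HBA_a), thresholded and optionally
noise-flipped. The default threshold was calibrated once, on the default
library and draw, to the ~6.5:1 positive:negative imbalance of curated
cocrystal data, and then frozen. A "shifted" rule with re-weighted
descriptors emulates a domain-shifted family (the transfer-learning
target), sized near the ~240-sample scale typical of energetic-cocrystal
curation.

What the generator does and does not emulate: it reproduces the *learning
problem shape* (pair input, descriptor-driven labels, imbalance, label
noise, domain shift) but not crystal-packing physics, and — because its
molecules are small and rigid and descriptors are deterministic functions
of the graph — the information gap between the graph-only and the
descriptor-fused model is much smaller than on real, chemically diverse
data. Passing the bundled benchmarks shows the pipeline learns planted
descriptor rules at realistic imbalance; it does not certify real-world
screening accuracy.

## Transfer learning

All weights except the last two dense layers are copied from a pretrained
model; those two are re-initialized from a seed; everything remains
trainable and is finetuned at a reduced learning rate (default 1e-4). Each
of the 10 pretrained models is finetuned under 5-fold random
cross-validation (50 candidates); the 10 candidates with the lowest
validation loss form the screening ensemble, ties broken by (pretrained
index, fold index). Ensembles rank pairs by the summed positive-class score
and label them by majority of the members' b > a votes.

## Numerical details and limitations

* Masked softmax assigns exactly zero attention to padded nodes; an
  all-masked graph is an error.
* Metrics are computed with exact rational arithmetic before float
  conversion; a class absent from the truth vector leaves its rate (and
  BACC) undefined rather than silently zero.
* Checkpoints are single-file archives with a SHA-256 checksum over all
  arrays; corrupt or layout-mismatched files refuse to load.
* Known limitations: no intermolecular (hydrogen-bond or pi-stacking) edges
  are modeled — only covalent bonds within each coformer, following the
  covalent-bond-only variant; hyperparameters are documented defaults, not
  a search optimum; the Gasteiger dipole is a rough surrogate; experiments
  at desk scale use the compact preset and small synthetic sets, with all
  problem sizes stated in the acceptance script.
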