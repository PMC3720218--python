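# bondscope

Topological bond descriptors and machine-learning models for ultra-fast
prediction of homolytic bond dissociation energies (BDEs).

## The problem

The BDE — the electronic energy change of the homolytic cleavage
A–B → A· + B·, in kcal/mol — governs reactivity-driven applications such
as mass-spectrum fragmentation scoring, metabolic soft-spot prediction
and antioxidant design. DFT-quality BDEs cost hours per bond; screening
thousands of candidate molecules needs answers in milliseconds.
`bondscope` is for cheminformaticians who have (or can simulate) a corpus
of per-bond energies and want a model that predicts new bonds directly
from the connection table: no 3D geometry, no quantum chemistry, no
explicit bond orders (so mesomers of an aromatic system cannot receive
different predictions).

## The method

A target bond is encoded by **counts of atom types and atom-type pairs in
topological spheres** around it. Two type systems are used: the plain
element (C, H, N, O, S) and the *connection-number* type — element plus
neighbour count (methane's carbon is C4, acetylene's C2; 14 labels in
total). Sphere *s* holds the atoms whose shortest-path distance to the
nearer bond atom is *s*. On top of these come:

* **point descriptors** — atoms of type *t* in sphere *s*, optionally
  restricted to ring / aromatic / π-system atoms;
* **pair descriptors** — unordered atom pairs at shortest-path distance
  *d* whose outer atom lies in sphere *s* (type pair, or untyped for low
  dimensionality);
* **bond-breaking difference descriptors** — pair counts before minus
  after cleavage (= cross-fragment pairs, since a non-ring bond is a
  bridge);
* **fragment point descriptors** — per-fragment counts, sorted so the
  vector is independent of bond orientation;
* **molecular descriptors** — whole-molecule counts shared by all bonds.

Bonds with identical vectors are deduplicated, datasets are split by
molecule, and two predictors are trained on the vectors: a 1000-tree
random forest validated out-of-bag (OOB), whose permutation importances
drive descriptor selection, and an **associative neural-network ensemble
(ASNN)** — feed-forward nets (one hidden layer of 6 logistic units,
inputs/targets normalized to [0.1, 0.9]) trained by Levenberg–Marquardt
with early stopping, whose mean prediction is corrected by the residuals
of the most similar training cases held in a memory. A fixed-value
baseline (training mean per element pair and bond order) calibrates how
much the environment actually buys.

A synthetic-data module generates valence-legal CHONS molecules and
surrogate energies from a transparent additive model (base energy per
bond class + sphere-1/2 increments + Gaussian noise), so the entire
pipeline is testable without quantum chemistry.

## Worked example

```bash
python examples/descriptor_walkthrough.py
```

prints (abridged):

```
molecule: CCCCN(C#CC(=O)CCC)CC  (35 atoms with H)
sphere 0: heavy atoms [8, 9] (printed 1-based numbering)
sphere 1: heavy atoms [5, 10] (printed 1-based numbering)
sphere 2: heavy atoms [4, 6, 11, 14] (printed 1-based numbering)
element pair descriptor (sphere 2, distance 2, C-C) = 4
contributing atom pairs: [(4, 6), (4, 8), (6, 8), (9, 11)]
selection3 vector: 127 descriptors, 38 non-zero
```

The target bond is the internal alkyne (atoms 8–9): its two atoms form
sphere 0, their remaining neighbours sphere 1, and four heavy atoms sit
two bonds away. Exactly four unordered C–C pairs lie at distance 2 with
an outer atom in sphere 2 — that count is one slot of the bond's
descriptor vector.

Model-side, `examples/train_random_forest.py` prints

```
2204 unique bonds x 127 descriptors
OOB: RMSD 3.11  MAD 1.96  MaxError 52.53  R2 0.975  (n=2204)
```

on a σ = 2 kcal/mol surrogate corpus — an out-of-bag RMSD close to the
injected noise floor, i.e. the forest has recovered the additive
environment model from the descriptors. `examples/asnn_memory_correction.py`
shows the memory correction cutting the held-out RMSD of a deliberately
under-parameterized ensemble from 6.1 to 0.6 kcal/mol, and absorbing new
labelled cases with zero retraining.

Other entry points: `examples/build_synthetic_dataset.py` (annotated SDF
round trip + deduplication), `examples/sphere_sweep.py` (accuracy vs
sphere count), and the `bondscope` CLI (`simulate`, `compute`,
`build-dataset`, `train`, `predict`, `experiment`).

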