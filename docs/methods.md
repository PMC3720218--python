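# Methods

This note records the models implemented by `bondscope`, the choices made
where the design was genuinely open, and what the synthetic corpora do
and do not establish.

## Descriptor model

A bond is represented by integer counts computed from the explicit-
hydrogen connection table only. Distances are unweighted shortest-path
bond counts; the sphere of an atom relative to the target bond is its
distance to the nearer bond atom (sphere 0 = the bond). All families are
invariant under exchanging the two bond atoms: sphere assignment is
symmetric by construction, fragment-resolved values are sorted
descending, and pair counts use unordered type pairs.

Conventions that the text sources left open, fixed here:

* **"N spheres" = sphere indices 0..N−1.** This makes the
  connection-number point pool over 7 layers plus molecular terms come
  out at 14×7 + 14 = 112 and the 4-layer variant at 14×4 = 56, the two
  closed forms the catalog reproduces exactly.
* **Pair feasibility pruning.** A sphere-0 pair can only be the target
  bond itself (distance 1); a pair with outer sphere *s* can be at most
  2s+1 bonds apart (path through the target bond). Infeasible
  (sphere, distance) slots are not enumerated. Distance 1–4 in the named
  presets.
* **Sphere-0 pairs at distance 1 include the target bond.** Excluding it
  would break the identity "untyped pair count = Σ typed pair counts",
  which the tests assert everywhere.
* **Bond-breaking differences** are computed as cross-fragment pair
  counts at each distance (provably equal to before-minus-after for a
  bridge bond, and verified against an independent before/after
  enumeration in the tests); they are enumerated at molecular scope.
* **Fragment sorting is descending**; the π-total variant sums the two
  fragment values, which equals the whole-molecule count over the
  restricted subset and is therefore defined even for ring bonds.
* **Preset compositions.** The historical descriptor pools cannot be
  re-derived exactly from their published group counts; the presets here
  use a consistent, documented enumeration instead. `selection3`
  (4 layers) contains: 56 connection-number points, 45 molecular element
  pairs (15 pairs × distances 1–3), 10 aromatic element fragment points,
  12 feasibility-pruned untyped pairs, and 4 element π totals (H cannot
  be part of a π system) — 127 descriptors. Group counts are reported by
  `DescriptorCatalog.group_counts()` so any preset is self-describing.
* **The final reduced descriptor list is a workflow, not a constant.**
  Importance-based selection depends on the training data, so the
  package ships `train_rf` (OOB permutation importances) +
  `select_descriptors` (top-k, then greedy removal of columns with
  |r| > 0.95 against retained ones — the threshold is configurable; the
  sources say only "high correlation").

## Perception models

Aromaticity is pinned to a Hückel 4n+2 electron count on simple rings
(RDKit's "simple" aromaticity model); π-system membership covers every
atom of a multiple or aromatic bond plus atoms bridging two conjugated
bonds, so terminal heteroatoms on aromatic rings (aniline's nitrogen) are
*not* π members. Different toolkits draw these boundaries slightly
differently; this dialect is fixed and versioned here so descriptor
vectors are reproducible. Aromatic input is kekulized to one canonical
resolution before anything else; since no descriptor reads bond orders,
mesomers are structurally indistinguishable (asserted vector-wide in the
tests).

Admission rules: net charge zero (zwitterions pass), elements within
C/H/N/O/S, connected graph, explicit hydrogens everywhere — H1 is an atom
type and neighbour counts include hydrogens.

## Random forest

Bootstrap ensemble of fully grown regression trees testing a random
subset of descriptors at each split (default 1000 trees, √p candidates).
It is implemented as bagged `DecisionTreeRegressor`s because the bagging
API exposes each member's bootstrap sample, which the out-of-bag
machinery needs: OOB predictions average only trees that did not see the
sample, and importance is the mean increase in a tree's OOB MSE after
permuting one column (bounded to `importance_max_trees` trees, default
100, to keep the cost linear).

One practical finding from the surrogate-recovery experiments: with the
√p default the forest dilutes the handful of sphere-0 columns that carry
the large between-class energy differences among ~127 weakly informative
count features, leaving several kcal/mol of avoidable error. The recovery
experiments therefore set `max_features=0.5`; the package default remains
√p. `RFConfig` exposes the field.

## FFNN ensemble and the associative memory

Members are fully connected nets with one hidden layer (6 logistic units
by default), bias units on the input and hidden layers, and a linear
output; inputs and the target are mapped to [0.1, 0.9] linearly with
bounds taken from the full training set only. Each member is trained by
Levenberg–Marquardt least squares on its own random half of the training
set, with the other half as validation: after every accepted damped
Gauss–Newton step the validation RMSD is evaluated, training stops when
it has not improved for `patience` accepted steps, and the
best-on-validation weights are restored. Members that end non-finite are
retrained with a fresh spawned seed (bounded retries). All randomness
flows from a single `SeedSequence`, so a seed reproduces member weights
bit-for-bit.

The ASNN prediction is the ensemble mean **plus the mean residual of the
k most similar training cases** held in a memory (descriptor vector,
label, per-member outputs, residual per case). Similarity is the Spearman
rank correlation between the query's and the case's per-member output
vectors; k defaults to 9 and the exact neighbour weighting of the
original ASNN program is not published, so the unweighted mean was chosen
and documented rather than guessed further. Rank correlation only orders
outputs, so distinct cases can tie at 1.0; ties are broken by Euclidean
distance between raw output vectors, which also guarantees exact recall
(a query identical to a memory case with k = 1 returns that case's
label). Extending the memory with new labelled cases requires no
retraining — the property the memory exists for.

Degenerate inputs: fewer than 4 training rows fall back to validating on
the training half itself; constant targets survive normalization (zero
spans map to the midpoint and invert to the constant); an empty memory
falls back to the plain ensemble mean with a warning.

## Fixed-value baseline

Training-set mean BDE per (element pair, bond order); unseen classes fall
back to the global mean and are flagged. It is deliberately strong on
corpora with small environment effects — the per-class comparison against
it is the honest measure of what the descriptors add.

## Synthetic data: what it emulates and what it does not

The generator grows random connected, valence-legal, net-neutral heavy-
atom graphs over C/N/O/S (element draw C 0.70 / O 0.13 / N 0.12 / S 0.05,
up to 12 heavy atoms by default, one ring-closure attempt per molecule at
probability 0.3, unsaturation upgrades at probability 0.25), then adds
explicit hydrogens. Surrogate labels are

    BDE = base(element pair, order) + Σ_sphere1 inc1(cn type)
        + Σ_sphere2 inc2(cn type) + N(0, σ),   σ = 2 kcal/mol default,

with single/double/triple base energies in literature ranges (C–H 99,
C–C 83 / 146 / 200, O–H 111, ... kcal/mol) and increments of a few
kcal/mol. These are configuration for testing, not chemical truth.

**Isolated unsaturation.** Multiple bonds are never placed on adjacent
atoms. Without conjugated or cumulated systems, the order of every
non-ring bond is a structural function of its two connection-number
types, which makes the noiseless label an exact function of the
sphere-0..2 descriptor environment — verified in the tests by checking
that identical descriptor vectors always carry identical noiseless
labels. This is the property that turns model evaluation into parameter
recovery: at σ = 0 the forest reaches OOB R² > 0.99, and at σ = 2 its
OOB RMSD lands in [σ, 2σ].

Consequences for interpretation: the synthetic corpora contain almost no
aromatic systems and no conjugation, no 3D or through-space effects
(hydrogen bonding, *cis/trans*), and homoscedastic Gaussian noise rather
than DFT error structure. Passing recovery tests therefore demonstrates
that the pipeline is correct and that the descriptors capture what they
claim to capture — not that real BDEs are predictable to 2 kcal/mol.
Aromatic/π descriptor behaviour is exercised separately with hand-written
aromatic molecules in the unit tests.

## Problem sizes and numerical choices

Simulation sizes used by the test suite and examples: 600-molecule
recovery corpus (~4,800 unique bonds), 200 molecules (≤ 30 atoms) for
brute-force oracle comparison, 20 paired seeds for the ASNN-vs-plain
comparison on XOR-arranged clusters (a structure a 1-hidden-unit net
cannot represent, so the memory correction is the only route to the
cluster offsets), forests of 120–400 trees and ensembles of 6–25 members.
These sizes were chosen as the smallest corpora on which the recovery
properties are stable across seeds.

Other numerics: LM damping starts at 1e-2, ×4 on rejection, ÷3 on
acceptance, abandoned above 1e10; logistic arguments are clipped at ±60;
distance tables use Dijkstra on the unweighted adjacency (scipy); random
splits use `numpy.random.Generator` exclusively, seeded per call.

## Known limitations

* Bonds whose environments differ only beyond the catalog's maximum
  sphere are indistinguishable by construction (asserted in the tests);
  the same holds for conformation-dependent energy differences between
  topologically equivalent bonds.
* The deduplication identity is descriptor-vector equality under the
  record's catalog — two genuinely different bonds that collide in
  descriptor space are merged, exactly as the modelling pipeline would
  see them.
* Mixed-order element-pair classes whose rare orders are weakly
  represented (e.g. nitrile triples) can locally favour the fixed-value
  baseline, which sees the order directly.
* The LM trainer is quadratic in parameter count; it is intended for the
  ≤ ~200-descriptor selections the workflow produces, not for the full
  pool.
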