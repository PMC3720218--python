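"""Synthetic CHONS molecules and surrogate bond energies.

The generator grows random connected, valence-legal, net-neutral heavy-atom
graphs (C/N/O/S with a ring-closure and unsaturation step), materializes
hydrogens, and labels every non-ring bond with a surrogate dissociation
energy:

    BDE = base(element pair, bond order)
        + Σ_{a in sphere 1} inc1(cn type of a)
        + Σ_{a in sphere 2} inc2(cn type of a)
        + Gaussian(0, σ)

The noiseless part depends only on the bond's sphere-0..2 topological
environment, so it is learnable from the descriptor families the package
computes — which makes the whole pipeline testable end-to-end without any
quantum chemistry.  Default base energies sit in literature single/double/
triple-bond ranges and the increments are a few kcal/mol; they are
configuration for tests, not chemical ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from rdkit import Chem

from .dataset import LabeledBond, enumerate_bonds, write_annotated_sdf
from .errors import ChemistryError, ConfigError
from .graph import CN_TYPES, MolecularGraph, atom_type, from_rdkit, prepare_rdkit_mol
from .spheres import assign_spheres

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}
_HEAVY = ("C", "N", "O", "S")
_DEFAULT_WEIGHTS = {"C": 0.70, "N": 0.12, "O": 0.13, "S": 0.05}

# Single-bond base energies, kcal/mol (order-of-magnitude literature values).
_SINGLE = {
    ("C", "C"): 83.0, ("C", "H"): 99.0, ("C", "N"): 73.0, ("C", "O"): 86.0,
    ("C", "S"): 65.0, ("H", "N"): 93.0, ("H", "O"): 111.0, ("H", "S"): 87.0,
    ("N", "N"): 40.0, ("N", "O"): 48.0, ("N", "S"): 55.0, ("O", "O"): 35.0,
    ("O", "S"): 62.0, ("S", "S"): 54.0, ("H", "H"): 104.0,
}
_DOUBLE = {
    ("C", "C"): 146.0, ("C", "N"): 147.0, ("C", "O"): 178.0, ("C", "S"): 115.0,
    ("N", "N"): 100.0, ("N", "O"): 97.0, ("O", "S"): 124.0, ("O", "O"): 119.0,
}
_TRIPLE = {("C", "C"): 200.0, ("C", "N"): 213.0, ("N", "N"): 226.0}

_INC1 = {
    "C2": 3.5, "C3": 2.0, "C4": -1.5, "H1": 0.5,
    "N1": 4.0, "N2": 2.5, "N3": -0.5, "N4": 0.0,
    "O1": 3.0, "O2": -1.0, "S1": 2.0, "S2": -0.8, "S3": 0.4, "S4": 1.0,
}
_INC2 = {k: round(v * 0.4, 2) for k, v in _INC1.items()}


@dataclass
class SurrogateParams:
    """Additive surrogate-energy parameters (kcal/mol)."""

    base: dict[tuple[tuple[str, str], int], float]
    sphere1_inc: dict[str, float]
    sphere2_inc: dict[str, float]
    sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigError("noise standard deviation must be non-negative")
        for inc in (self.sphere1_inc, self.sphere2_inc):
            unknown = set(inc) - set(CN_TYPES)
            if unknown:
                raise ConfigError(f"unknown cn labels in increments: {unknown}")

    def to_dict(self) -> dict:
        return {
            "sigma": self.sigma,
            "base": {f"{p[0]}-{p[1]}|{o}": v for (p, o), v in sorted(self.base.items())},
            "sphere1_inc": dict(sorted(self.sphere1_inc.items())),
            "sphere2_inc": dict(sorted(self.sphere2_inc.items())),
        }


def default_params(sigma: float = 2.0) -> SurrogateParams:
    """Default additive model covering every (element pair, order) class the
    generator can emit."""
    base: dict[tuple[tuple[str, str], int], float] = {}
    for pair, value in _SINGLE.items():
        base[(pair, 1)] = value
        base[(pair, 2)] = _DOUBLE.get(pair, value * 1.75 + 15.0)
        base[(pair, 3)] = _TRIPLE.get(pair, value * 2.2 + 40.0)
    return SurrogateParams(
        base=base, sphere1_inc=dict(_INC1), sphere2_inc=dict(_INC2), sigma=sigma
    )


# ---------------------------------------------------------------------------
# Molecule generation
# ---------------------------------------------------------------------------


def _grow_heavy_graph(rng, n_heavy, symbols_pool, weights, ring_prob, unsat_prob):
    symbols = [str(rng.choice(symbols_pool, p=weights))]
    bonds: list[list[int]] = []  # [i, j, order]
    used = [0]

    def free(i: int) -> int:
        return _VALENCE[symbols[i]] - used[i]

    for _ in range(1, n_heavy):
        candidates = [i for i in range(len(symbols)) if free(i) >= 1]
        if not candidates:
            break
        attach = int(rng.choice(candidates))
        symbols.append(str(rng.choice(symbols_pool, p=weights)))
        used.append(0)
        bonds.append([attach, len(symbols) - 1, 1])
        used[attach] += 1
        used[-1] += 1

    n = len(symbols)
    adjacency = {(min(b[0], b[1]), max(b[0], b[1])) for b in bonds}

    # One ring-closure attempt keeps a realistic acyclic/cyclic mix.
    if n >= 3 and rng.random() < ring_prob:
        closures = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if (i, j) not in adjacency and free(i) >= 1 and free(j) >= 1
        ]
        if closures:
            i, j = closures[int(rng.integers(len(closures)))]
            bonds.append([i, j, 1])
            adjacency.add((i, j))
            used[i] += 1
            used[j] += 1

    # Unsaturation pass: upgrade bond orders where valence allows.  Multiple
    # bonds are kept *isolated* (never on adjacent atoms): without
    # conjugated or cumulated systems, the bond order of every non-ring
    # bond is a structural function of the two atoms' connection-number
    # types, which keeps the noiseless surrogate an exact function of the
    # sphere-0..2 descriptor environment.
    neighbor_sets: dict[int, set[int]] = {a: set() for a in range(n)}
    for i, j, _ in bonds:
        neighbor_sets[i].add(j)
        neighbor_sets[j].add(i)
    unsaturated: set[int] = set()
    for b in bonds:
        i, j, _ = b
        pair = tuple(sorted((symbols[i], symbols[j])))
        if rng.random() >= unsat_prob or free(i) < 1 or free(j) < 1:
            continue
        if pair in (("O", "O"), ("S", "S"), ("O", "S")):
            continue  # no peroxide/disulfide-type multiple bonds
        near = (neighbor_sets[i] | neighbor_sets[j] | {i, j}) - {i, j}
        if {i, j} & unsaturated or near & unsaturated:
            continue
        b[2] += 1
        used[i] += 1
        used[j] += 1
        # occasional triple, C-C / C-N only
        if (
            pair in (("C", "C"), ("C", "N"))
            and rng.random() < unsat_prob / 2
            and free(i) >= 1
            and free(j) >= 1
        ):
            b[2] += 1
            used[i] += 1
            used[j] += 1
        unsaturated.update((i, j))
    return symbols, bonds


def generate_molecules(
    n: int,
    max_heavy_atoms: int = 12,
    element_weights: dict[str, float] | None = None,
    seed: int = 0,
    ring_prob: float = 0.3,
    unsat_prob: float = 0.25,
) -> list[MolecularGraph]:
    """Generate ``n`` connected, valence-legal, net-neutral CHONS molecules
    with explicit hydrogens; deterministic under ``seed``."""
    if n < 1 or max_heavy_atoms < 1:
        raise ConfigError("need n >= 1 and max_heavy_atoms >= 1")
    weights_map = dict(_DEFAULT_WEIGHTS if element_weights is None else element_weights)
    unknown = set(weights_map) - set(_HEAVY)
    if unknown:
        raise ConfigError(f"weights for non-heavy elements: {unknown}")
    pool = [e for e in _HEAVY if weights_map.get(e, 0.0) > 0]
    if not pool:
        raise ConfigError("element weights sum to zero")
    weights = np.array([weights_map[e] for e in pool], dtype=float)
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    graphs: list[MolecularGraph] = []
    attempts = 0
    while len(graphs) < n:
        attempts += 1
        if attempts > 50 * n:
            raise ConfigError("molecule generation failed to converge")
        n_heavy = int(rng.integers(1, max_heavy_atoms + 1))
        symbols, bonds = _grow_heavy_graph(
            rng, n_heavy, pool, weights, ring_prob, unsat_prob
        )
        mol = Chem.RWMol()
        for symbol in symbols:
            mol.AddAtom(Chem.Atom(symbol))
        order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
        for i, j, order in bonds:
            mol.AddBond(i, j, order_map[order])
        try:
            graphs.append(from_rdkit(prepare_rdkit_mol(mol.GetMol())))
        except ChemistryError:
            continue  # rare sanitization rejection; redraw
    return graphs


# ---------------------------------------------------------------------------
# Surrogate energies
# ---------------------------------------------------------------------------


def surrogate_bde(
    g: MolecularGraph,
    bond: tuple[int, int],
    params: SurrogateParams,
    rng: np.random.Generator | None = None,
) -> float:
    """Surrogate energy of one non-ring bond (kcal/mol); adds Gaussian noise
    only when an ``rng`` is supplied and σ > 0."""
    i, j = min(bond), max(bond)
    b = g.bond_between(i, j)
    if b is None:
        raise ConfigError(f"no bond between atoms {i} and {j}")
    pair = tuple(sorted((g.elements[i], g.elements[j])))
    key = (pair, b.order)
    if key not in params.base:
        raise ConfigError(f"surrogate base table does not cover class {key}")
    env = assign_spheres(g, (i, j))
    value = params.base[key]
    for a in range(g.n_atoms):
        sphere = env.spheres[a]
        if sphere == 1:
            value += params.sphere1_inc.get(atom_type(g, a, "cn"), 0.0)
        elif sphere == 2:
            value += params.sphere2_inc.get(atom_type(g, a, "cn"), 0.0)
    if rng is not None and params.sigma > 0:
        value += rng.normal(0.0, params.sigma)
    return float(value)


def generate_corpus(
    n_molecules: int,
    params: SurrogateParams | None = None,
    seed: int = 0,
    max_heavy_atoms: int = 12,
    element_weights: dict[str, float] | None = None,
    ring_prob: float = 0.3,
    unsat_prob: float = 0.25,
) -> list[LabeledBond]:
    """In-memory labelled corpus: every non-ring bond of every generated
    molecule gets a surrogate label."""
    params = params or default_params()
    ss = np.random.SeedSequence(seed)
    mol_seed, noise_seed = ss.spawn(2)
    graphs = generate_molecules(
        n_molecules,
        max_heavy_atoms=max_heavy_atoms,
        element_weights=element_weights,
        seed=mol_seed,
        ring_prob=ring_prob,
        unsat_prob=unsat_prob,
    )
    noise_rng = np.random.default_rng(noise_seed)
    labeled: list[LabeledBond] = []
    for idx, g in enumerate(graphs):
        g.title = f"mol-{idx}"
        if g._rdkit is not None:
            g._rdkit.SetProp("_Name", g.title)
        for bond in enumerate_bonds(g):
            labeled.append(
                LabeledBond(g, bond, surrogate_bde(g, bond, params, noise_rng), idx)
            )
    return labeled


def make_dataset(
    n_molecules: int,
    params: SurrogateParams | None = None,
    out_path=None,
    seed: int = 0,
    property_key: str = "BDE",
    bond_key: str = "BOND_ATOMS",
    **generator_kwargs,
) -> list[LabeledBond]:
    """Generate a labelled corpus and write it as an annotated SDF (one bond
    per record) plus a YAML manifest recording seeds and parameters."""
    params = params or default_params()
    labeled = generate_corpus(n_molecules, params, seed=seed, **generator_kwargs)
    if out_path is not None:
        write_annotated_sdf(labeled, out_path, property_key, bond_key)
        manifest = {
            "seed": seed,
            "n_molecules": n_molecules,
            "n_bonds": len(labeled),
            "property_key": property_key,
            "bond_key": bond_key,
            "generator": {k: v for k, v in generator_kwargs.items()},
            "params": params.to_dict(),
        }
        with open(str(out_path) + ".manifest.yaml", "w") as handle:
            yaml.safe_dump(manifest, handle, sort_keys=False)
    return labeled
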