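"""Topological bond descriptors.

A bond is encoded by counts of atom types and of atom-type pairs in and
around it.  All descriptors are computed from the connection table alone —
no 3D geometry, no quantum chemistry, and no explicit bond orders — and
every descriptor is invariant under exchanging the two bond atoms, so a
bond and its reverse always map to the same vector.

Families
--------
``point``
    Count of atoms of one type in one sphere, optionally restricted to an
    atom subset (ring / aromatic / π-system atoms).
``pair``
    Count of unordered atom pairs at a given shortest-path distance whose
    *outer* atom lies in the given sphere (the other atom in the same or a
    lower sphere).  With type system ``none``, a single count over all
    pairs ("no-type" pairs) keeps the dimensionality low.
``bb_diff_pair``
    Pair count before breaking the target bond minus the pair count over
    same-fragment pairs afterwards.  Because a non-ring bond is a bridge,
    same-fragment distances are unchanged by the cleavage, so the
    difference equals the number of cross-fragment pairs and is never
    negative.
``fragment_point``
    Point counts evaluated per cleavage fragment; the two values are
    sorted (descending) so the layout does not depend on bond orientation.
``molecular_point`` / ``molecular_pair``
    Whole-molecule counts, identical for every bond of a molecule.
``pi_total``
    Fragment point counts merged by summing the two fragments — which
    equals the whole-molecule count over the restricted subset, so the
    value is defined even for ring bonds.

The catalog fixes the definition order and is therefore part of the file
contract of any descriptor matrix written to disk.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import CatalogError
from .graph import (
    CN_PAIRS,
    CN_TYPES,
    ELEMENT_PAIRS,
    ELEMENTS,
    MolecularGraph,
    atom_types,
    subset_flags,
)
from .spheres import BondEnvironment, assign_spheres

FAMILIES = (
    "point",
    "pair",
    "bb_diff_pair",
    "fragment_point",
    "molecular_point",
    "molecular_pair",
    "pi_total",
)

#: Elements that can participate in a π system (H cannot: a one-neighbour
#: atom is never part of a multiple bond nor a conjugation bridge).
PI_ELEMENTS = ("C", "N", "O", "S")

PRESET_DISTANCES = (1, 2, 3, 4)


def _labels(type_system: str) -> tuple[str, ...]:
    if type_system == "element":
        return ELEMENTS
    if type_system == "cn":
        return CN_TYPES
    raise CatalogError(f"no point labels for type system {type_system!r}")


def _pairs(type_system: str) -> tuple[tuple[str, str], ...]:
    if type_system == "element":
        return ELEMENT_PAIRS
    if type_system == "cn":
        return CN_PAIRS
    raise CatalogError(f"no pair labels for type system {type_system!r}")


def sphere_distance_feasible(sphere: int, distance: int) -> bool:
    """Whether a pair with outer sphere ``sphere`` can exist at ``distance``.

    Both atoms of a sphere-0 pair are the target-bond atoms, so only
    distance 1 occurs there; otherwise the two atoms can be at most
    ``2*sphere + 1`` bonds apart (a path through the target bond).
    """
    if sphere == 0:
        return distance == 1
    return 1 <= distance <= 2 * sphere + 1


@dataclass(frozen=True)
class DescriptorDefinition:
    """One slot of the descriptor vector."""

    family: str
    type_system: str = "cn"          # element | cn | none
    subset: str = "all"              # all | ring | aromatic | pi
    sphere: int | None = None
    distance: int | None = None
    label: str | None = None         # point-like families
    pair: tuple[str, str] | None = None  # typed pair families (sorted)
    rank: int | None = None          # fragment_point: 0 = larger, 1 = smaller
    group: str = ""                  # reporting group within a preset

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise CatalogError(f"unknown descriptor family {self.family!r}")
        pairlike = self.family in ("pair", "bb_diff_pair", "molecular_pair")
        if pairlike and self.distance is None:
            raise CatalogError(f"{self.family} definitions carry a distance")
        if not pairlike and self.distance is not None:
            raise CatalogError(f"{self.family} definitions carry no distance")
        if self.family == "fragment_point" and self.rank not in (0, 1):
            raise CatalogError("fragment_point definitions carry rank 0 or 1")
        if self.pair is not None and tuple(self.pair) != tuple(sorted(self.pair)):
            raise CatalogError("type pairs are stored sorted (unordered pairs)")

    @property
    def name(self) -> str:
        bits = [self.family, self.type_system]
        if self.subset != "all":
            bits.append(self.subset)
        if self.sphere is not None:
            bits.append(f"s{self.sphere}")
        if self.distance is not None:
            bits.append(f"d{self.distance}")
        if self.label is not None:
            bits.append(self.label)
        if self.pair is not None:
            bits.append("-".join(self.pair))
        if self.rank is not None:
            bits.append("larger" if self.rank == 0 else "smaller")
        return "|".join(bits)


@dataclass(frozen=True)
class DescriptorCatalog:
    """Ordered descriptor definitions; the vector layout contract."""

    definitions: tuple[DescriptorDefinition, ...]
    preset: str = "custom"
    max_sphere: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.definitions)) != len(self.definitions):
            raise CatalogError("catalog contains duplicate definitions")

    def __len__(self) -> int:
        return len(self.definitions)

    def __iter__(self):
        return iter(self.definitions)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.definitions]

    def group_counts(self) -> dict[str, int]:
        counts: Counter[str] = Counter(d.group or d.family for d in self.definitions)
        return dict(counts)

    @property
    def max_distance(self) -> int:
        return max((d.distance for d in self.definitions if d.distance), default=1)

    @property
    def needs_cleavage(self) -> bool:
        return any(
            d.family in ("bb_diff_pair", "fragment_point") for d in self.definitions
        )

    def content_hash(self) -> str:
        digest = hashlib.sha256("\n".join(self.names).encode()).hexdigest()
        return digest[:16]

    # -- preset file round trip -----------------------------------------

    def to_yaml(self, path) -> None:
        def encode(d: DescriptorDefinition) -> dict:
            out = {}
            for k, v in d.__dict__.items():
                if v is None or v == "":
                    continue
                out[k] = list(v) if isinstance(v, tuple) else v
            return out

        payload = {
            "preset": self.preset,
            "max_sphere": self.max_sphere,
            "provenance": self.provenance,
            "definitions": [encode(d) for d in self.definitions],
        }
        with open(path, "w") as handle:
            yaml.safe_dump(payload, handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DescriptorCatalog":
        with open(path) as handle:
            payload = yaml.safe_load(handle)
        defs = []
        for entry in payload["definitions"]:
            if "pair" in entry and entry["pair"] is not None:
                entry["pair"] = tuple(entry["pair"])
            defs.append(DescriptorDefinition(**entry))
        return cls(
            definitions=tuple(defs),
            preset=payload.get("preset", "custom"),
            max_sphere=payload.get("max_sphere"),
            provenance=payload.get("provenance", ""),
        )


# ---------------------------------------------------------------------------
# Catalog presets
# ---------------------------------------------------------------------------


def _point_block(ts, spheres, subset="all", group=""):
    return [
        DescriptorDefinition(
            "point", ts, subset=subset, sphere=s, label=lbl,
            group=group or f"{ts}_point",
        )
        for s in spheres
        for lbl in _labels(ts)
    ]


def _molecular_point_block(ts, subset="all", group=""):
    return [
        DescriptorDefinition(
            "molecular_point", ts, subset=subset, label=lbl,
            group=group or f"molecular_{ts}_point",
        )
        for lbl in _labels(ts)
    ]


def _pair_block(ts, spheres, distances, group=""):
    defs = []
    for s in spheres:
        for d in distances:
            if not sphere_distance_feasible(s, d):
                continue
            if ts == "none":
                defs.append(
                    DescriptorDefinition(
                        "pair", "none", sphere=s, distance=d,
                        group=group or "no_type_pair",
                    )
                )
            else:
                defs.extend(
                    DescriptorDefinition(
                        "pair", ts, sphere=s, distance=d, pair=p,
                        group=group or f"{ts}_pair",
                    )
                    for p in _pairs(ts)
                )
    return defs


def _bb_diff_block(ts, distances, group=""):
    defs = []
    for d in distances:
        if ts == "none":
            defs.append(
                DescriptorDefinition(
                    "bb_diff_pair", "none", distance=d,
                    group=group or "no_type_bb_diff",
                )
            )
        else:
            defs.extend(
                DescriptorDefinition(
                    "bb_diff_pair", ts, distance=d, pair=p,
                    group=group or f"{ts}_bb_diff",
                )
                for p in _pairs(ts)
            )
    return defs


def _fragment_point_block(ts, subset="all", group=""):
    return [
        DescriptorDefinition(
            "fragment_point", ts, subset=subset, label=lbl, rank=r,
            group=group or f"{subset}_fragment_point",
        )
        for lbl in _labels(ts)
        for r in (0, 1)
    ]


def _molecular_pair_block(ts, distances, group=""):
    return [
        DescriptorDefinition(
            "molecular_pair", ts, distance=d, pair=p,
            group=group or f"molecular_{ts}_pair",
        )
        for d in distances
        for p in _pairs(ts)
    ]


def _pi_total_block(subset="pi", group="pi_total"):
    return [
        DescriptorDefinition(
            "pi_total", "element", subset=subset, label=lbl, group=group
        )
        for lbl in PI_ELEMENTS
    ]


PRESETS = ("full", "selection1", "selection2", "selection3", "cn-point-only", "custom")


def build_catalog(
    preset: str,
    max_sphere: int | None = None,
    distances: Sequence[int] = PRESET_DISTANCES,
    include_molecular: bool = True,
    definitions: Iterable[DescriptorDefinition] | None = None,
) -> DescriptorCatalog:
    """Build a descriptor catalog for a named preset.

    ``max_sphere`` counts sphere *layers*: N layers mean sphere indices
    0..N−1.  ``distances`` applies to sphere-resolved pair families and is
    restricted to 1–4 bonds in the named presets; infeasible
    (sphere, distance) combinations are pruned.  The enumeration is
    deterministic, so two calls with equal arguments produce identical
    vector layouts.
    """
    if preset not in PRESETS:
        raise CatalogError(f"unknown preset {preset!r}")
    if preset == "custom":
        return DescriptorCatalog(tuple(definitions or ()), preset="custom")
    if max_sphere is None:
        max_sphere = 4 if preset == "selection3" else 7
    if max_sphere < 1:
        raise CatalogError("at least one sphere layer is required")
    if preset != "selection2":
        for d in distances:
            if not 1 <= d <= 4:
                raise CatalogError(
                    "pair distances are restricted to 1-4 bonds in named presets"
                )
    spheres = range(max_sphere)
    defs: list[DescriptorDefinition] = []

    if preset == "cn-point-only":
        defs += _point_block("cn", spheres, group="cn_point")
        if include_molecular:
            defs += _molecular_point_block("cn", group="molecular_cn_point")

    elif preset == "full":
        defs += _point_block("cn", spheres, group="cn_point")
        if include_molecular:
            defs += _molecular_point_block("cn", group="molecular_cn_point")
        defs += _point_block("cn", spheres, subset="ring", group="ring_cn_point")
        defs += _point_block("cn", spheres, subset="pi", group="pi_cn_point")
        defs += _point_block(
            "cn", spheres, subset="aromatic", group="aromatic_cn_point"
        )
        defs += _pair_block("cn", spheres, distances, group="cn_pair")
        defs += _bb_diff_block("cn", distances, group="cn_bb_diff")

    elif preset == "selection1":
        # Element-typed twin of the full pool.
        defs += _point_block("element", spheres, group="element_point")
        if include_molecular:
            defs += _molecular_point_block(
                "element", group="molecular_element_point"
            )
        defs += _point_block(
            "element", spheres, subset="ring", group="ring_element_point"
        )
        defs += _point_block(
            "element", spheres, subset="pi", group="pi_element_point"
        )
        defs += _point_block(
            "element", spheres, subset="aromatic", group="aromatic_element_point"
        )
        defs += _pair_block("element", spheres, distances, group="element_pair")
        defs += _bb_diff_block("element", distances, group="element_bb_diff")

    elif preset == "selection2":
        # Detailed point types; cheap pair types: element pairs at distance
        # 1, no-type pairs at 2-7 bonds; subset point descriptors replaced
        # by fragment points.
        defs += _point_block("cn", spheres, group="cn_point")
        if include_molecular:
            defs += _molecular_point_block("cn", group="molecular_cn_point")
        defs += _pair_block("element", spheres, (1,), group="element_pair_d1")
        defs += _pair_block("none", spheres, (2, 3, 4, 5, 6, 7), group="no_type_pair")
        defs += _fragment_point_block("cn", group="cn_fragment_point")
        defs += _fragment_point_block(
            "element", subset="aromatic", group="aromatic_fragment_point"
        )
        defs += _fragment_point_block(
            "element", subset="ring", group="ring_fragment_point"
        )
        defs += _fragment_point_block(
            "element", subset="pi", group="pi_fragment_point"
        )
        defs += _bb_diff_block("none", PRESET_DISTANCES, group="no_type_bb_diff")
        defs += _molecular_pair_block(
            "element", PRESET_DISTANCES, group="molecular_element_pair"
        )

    elif preset == "selection3":
        # The compact configuration: detailed point types close to the
        # bond, whole-molecule element pairs, aromatic fragment points,
        # no-type pairs, and π totals.
        defs += _point_block("cn", spheres, group="cn_point")
        defs += _molecular_pair_block("element", (1, 2, 3), group="element_pair")
        defs += _fragment_point_block(
            "element", subset="aromatic", group="aromatic_fragment_point"
        )
        defs += _pair_block("none", spheres, distances, group="no_type_pair")
        defs += _pi_total_block(group="pi_total")

    return DescriptorCatalog(
        definitions=tuple(defs),
        preset=preset,
        max_sphere=max_sphere,
        provenance=f"preset={preset} max_sphere={max_sphere} distances={tuple(distances)}",
    )


# ---------------------------------------------------------------------------
# Per-bond tallies
# ---------------------------------------------------------------------------

_TYPE_CACHE = "_bondscope_types"
_MOL_TALLY_CACHE = "_bondscope_mol_tallies"


def _graph_types(g: MolecularGraph) -> dict[str, tuple[str, ...]]:
    cached = getattr(g, _TYPE_CACHE, None)
    if cached is None:
        cached = {"element": atom_types(g, "element"), "cn": atom_types(g, "cn")}
        object.__setattr__(g, _TYPE_CACHE, cached)
    return cached


class _MoleculeTallies:
    """Whole-molecule counts shared by every bond of the molecule."""

    def __init__(self, g: MolecularGraph):
        self.graph = g
        types = _graph_types(g)
        self.point: dict[tuple[str, str], Counter] = {}
        for ts in ("element", "cn"):
            for subset in ("all", "ring", "aromatic", "pi"):
                mask = subset_flags(g, subset)
                self.point[(ts, subset)] = Counter(
                    t for t, keep in zip(types[ts], mask) if keep
                )
        self._pair: dict[str, Counter] | None = None

    @property
    def pair(self) -> dict[str, Counter]:
        if self._pair is None:
            from .spheres import topological_distances

            g = self.graph
            types = _graph_types(g)
            dist = topological_distances(g)
            pair: dict[str, Counter] = {
                "element": Counter(), "cn": Counter(), "none": Counter()
            }
            n = g.n_atoms
            el, cn = types["element"], types["cn"]
            for i in range(n):
                for j in range(i + 1, n):
                    d = int(dist[i, j])
                    pair["none"][d] += 1
                    pair["element"][(d, tuple(sorted((el[i], el[j]))))] += 1
                    pair["cn"][(d, tuple(sorted((cn[i], cn[j]))))] += 1
            self._pair = pair
        return self._pair


def _molecule_tallies(g: MolecularGraph) -> _MoleculeTallies:
    cached = getattr(g, _MOL_TALLY_CACHE, None)
    if cached is None:
        cached = _MoleculeTallies(g)
        object.__setattr__(g, _MOL_TALLY_CACHE, cached)
    return cached


class _BondTallies:
    """Sphere/distance tallies for one target bond."""

    def __init__(self, env: BondEnvironment):
        self.env = env
        self._pair: dict[str, Counter] | None = None
        self._cross: dict[str, Counter] | None = None

    @property
    def pair(self) -> dict[str, Counter]:
        if self._pair is None:
            env = self.env
            g = env.graph
            types = _graph_types(g)
            el, cn = types["element"], types["cn"]
            sph = env.spheres
            dist = env.distances
            n = g.n_atoms
            pair: dict[str, Counter] = {
                "element": Counter(), "cn": Counter(), "none": Counter()
            }
            for i in range(n):
                for j in range(i + 1, n):
                    d = int(dist[i, j])
                    s = int(max(sph[i], sph[j]))
                    pair["none"][(s, d)] += 1
                    pair["element"][(s, d, tuple(sorted((el[i], el[j]))))] += 1
                    pair["cn"][(s, d, tuple(sorted((cn[i], cn[j]))))] += 1
            self._pair = pair
        return self._pair

    @property
    def cross(self) -> dict[str, Counter]:
        """Cross-fragment pair tallies (used by bond-breaking differences)."""
        if self._cross is None:
            env = self.env
            g = env.graph
            side = env.fragment_side
            types = _graph_types(g)
            el, cn = types["element"], types["cn"]
            dist = env.distances
            cross: dict[str, Counter] = {
                "element": Counter(),
                "cn": Counter(),
                "none": Counter(),
            }
            n = g.n_atoms
            for i in range(n):
                for j in range(i + 1, n):
                    if side[i] == side[j]:
                        continue
                    d = int(dist[i, j])
                    cross["none"][d] += 1
                    cross["element"][(d, tuple(sorted((el[i], el[j]))))] += 1
                    cross["cn"][(d, tuple(sorted((cn[i], cn[j]))))] += 1
            self._cross = cross
        return self._cross


# ---------------------------------------------------------------------------
# Single-family operations (public per-family API; also used by tests)
# ---------------------------------------------------------------------------


def point_descriptors(
    env: BondEnvironment, type_system: str, subset: str, sphere: int
) -> dict[str, int]:
    """Counts of atoms of each type in one sphere, restricted to a subset."""
    g = env.graph
    types = _graph_types(g)[type_system]
    mask = subset_flags(g, subset)
    counts = {lbl: 0 for lbl in _labels(type_system)}
    for a in range(g.n_atoms):
        if env.spheres[a] == sphere and mask[a]:
            counts[types[a]] += 1
    return counts


def pair_descriptors(
    env: BondEnvironment, type_system: str, sphere: int, distance: int
):
    """Counts of unordered atom pairs with outer sphere ``sphere`` and
    shortest-path separation ``distance``.

    Typed systems return a dict per unordered type pair; type system
    ``"none"`` returns a single integer over all pairs.
    """
    tallies = _BondTallies(env)
    if type_system == "none":
        return int(tallies.pair["none"][(sphere, distance)])
    return {
        p: int(tallies.pair[type_system][(sphere, distance, p)])
        for p in _pairs(type_system)
    }


def bond_breaking_difference(
    env: BondEnvironment, type_system: str, distance: int
):
    """Pair counts before cleavage minus same-fragment pair counts after.

    Equals the number of cross-fragment pairs at that distance (the target
    bond is a bridge), so the value is non-negative and orientation
    independent.  Raises :class:`CleavageError` for ring bonds.
    """
    tallies = _BondTallies(env)
    cross = tallies.cross
    if type_system == "none":
        return int(cross["none"][distance])
    return {p: int(cross[type_system][(distance, p)]) for p in _pairs(type_system)}


def fragment_point_descriptors(
    env: BondEnvironment, type_system: str, subset: str = "all"
) -> dict[str, tuple[int, int]]:
    """Per-type atom counts of the two cleavage fragments, sorted descending
    so the result does not depend on bond orientation."""
    g = env.graph
    types = _graph_types(g)[type_system]
    mask = subset_flags(g, subset)
    out: dict[str, tuple[int, int]] = {}
    frag_a, frag_b = env.fragments
    for lbl in _labels(type_system):
        a = sum(1 for atom in frag_a.atom_ids if types[atom] == lbl and mask[atom])
        b = sum(1 for atom in frag_b.atom_ids if types[atom] == lbl and mask[atom])
        out[lbl] = (max(a, b), min(a, b))
    return out


def molecular_descriptors(
    g: MolecularGraph,
    type_system: str,
    subset: str = "all",
    distance: int | None = None,
):
    """Whole-molecule point counts (``distance=None``) or pair counts at a
    given distance; identical for every bond of the molecule."""
    tallies = _molecule_tallies(g)
    if distance is None:
        counts = tallies.point[(type_system, subset)]
        return {lbl: int(counts[lbl]) for lbl in _labels(type_system)}
    if type_system == "none":
        return int(tallies.pair["none"][distance])
    return {
        p: int(tallies.pair[type_system][(distance, p)])
        for p in _pairs(type_system)
    }


# ---------------------------------------------------------------------------
# Vector computation
# ---------------------------------------------------------------------------


def _evaluate(
    definition: DescriptorDefinition,
    env: BondEnvironment,
    tallies: _BondTallies,
    mol_tallies: _MoleculeTallies,
    frag_counts: dict,
) -> int:
    d = definition
    g = env.graph
    if d.family == "point":
        types = _graph_types(g)[d.type_system]
        mask = subset_flags(g, d.subset)
        return sum(
            1
            for a in range(g.n_atoms)
            if env.spheres[a] == d.sphere and mask[a] and types[a] == d.label
        )
    if d.family == "pair":
        if d.type_system == "none":
            return int(tallies.pair["none"][(d.sphere, d.distance)])
        return int(tallies.pair[d.type_system][(d.sphere, d.distance, d.pair)])
    if d.family == "bb_diff_pair":
        cross = tallies.cross
        if d.type_system == "none":
            return int(cross["none"][d.distance])
        return int(cross[d.type_system][(d.distance, d.pair)])
    if d.family == "fragment_point":
        key = (d.type_system, d.subset)
        if key not in frag_counts:
            frag_counts[key] = fragment_point_descriptors(env, d.type_system, d.subset)
        return int(frag_counts[key][d.label][d.rank])
    if d.family == "molecular_point":
        return int(mol_tallies.point[(d.type_system, d.subset)][d.label])
    if d.family == "molecular_pair":
        if d.type_system == "none":
            return int(mol_tallies.pair["none"][d.distance])
        return int(mol_tallies.pair[d.type_system][(d.distance, d.pair)])
    if d.family == "pi_total":
        # Sum of the two fragment values == whole-molecule subset count.
        return int(mol_tallies.point[(d.type_system, d.subset)][d.label])
    raise CatalogError(f"unknown descriptor family {d.family!r}")


def compute_vector(
    g: MolecularGraph, bond: tuple[int, int], catalog: DescriptorCatalog
) -> np.ndarray:
    """Descriptor vector of one bond, in catalog order.

    Deterministic and identical for ``(a, b)`` and ``(b, a)``.  Cleavage-
    dependent families raise :class:`CleavageError` on ring bonds.
    """
    env = assign_spheres(g, bond)
    tallies = _BondTallies(env)
    mol_tallies = _molecule_tallies(g)
    frag_counts: dict = {}
    values = [
        _evaluate(d, env, tallies, mol_tallies, frag_counts)
        for d in catalog.definitions
    ]
    return np.asarray(values, dtype=np.float64)


def compute_matrix(
    entries: Sequence[tuple[MolecularGraph, tuple[int, int]]],
    catalog: DescriptorCatalog,
) -> pd.DataFrame:
    """Descriptor matrix for (graph, bond) entries.

    Rows are indexed by (molecule position, bond atom pair); columns carry
    the catalog's definition names, so the table is self-describing.
    """
    rows = []
    index = []
    for mol_idx, (g, bond) in enumerate(entries):
        rows.append(compute_vector(g, bond, catalog))
        index.append((mol_idx, f"{min(bond)}-{max(bond)}"))
    frame = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(catalog))),
        columns=catalog.names,
    )
    frame.index = pd.MultiIndex.from_tuples(index, names=["molecule", "bond"]) if index else frame.index
    return frame
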