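"""Topological distances, sphere assignment, and homolytic cleavage.

Distances are unweighted shortest-path bond counts (bond orders never
weight edges).  The *sphere* of an atom relative to a target bond is its
distance to the nearer of the two bond atoms: sphere 0 is the bond itself,
sphere 1 its immediate neighbours, and so on.  Cleaving a non-ring bond
partitions the atoms into exactly two fragments; because such a bond is a
bridge, shortest paths between same-fragment atoms are unchanged by the
cleavage — the property the bond-breaking difference descriptors rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .errors import CleavageError, StructureError
from .graph import MolecularGraph

_DIST_CACHE = "_bondscope_distances"


def topological_distances(g: MolecularGraph) -> np.ndarray:
    """All-pairs shortest-path bond counts as an ``(n, n)`` integer array.

    Raises :class:`StructureError` on disconnected input. Cached on the
    graph object (distances are reused by every bond of a molecule).
    """
    cached = getattr(g, _DIST_CACHE, None)
    if cached is not None:
        return cached
    n = g.n_atoms
    rows = [b.i for b in g.bonds] + [b.j for b in g.bonds]
    cols = [b.j for b in g.bonds] + [b.i for b in g.bonds]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    if np.isinf(dist).any():
        raise StructureError("graph is disconnected")
    dist = dist.astype(np.int64)
    object.__setattr__(g, _DIST_CACHE, dist)
    return dist


@dataclass
class Fragment:
    """One side of a cleaved bond; atoms keep their parent-graph ids."""

    graph: MolecularGraph
    atom_ids: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.atom_ids)

    def distances(self) -> dict[tuple[int, int], int]:
        """Shortest-path distances recomputed *within* the fragment
        (independent of the parent-graph distance table)."""
        members = set(self.atom_ids)
        out: dict[tuple[int, int], int] = {}
        for source in self.atom_ids:
            seen = {source: 0}
            frontier = [source]
            depth = 0
            while frontier:
                depth += 1
                nxt = []
                for atom in frontier:
                    for nbr in self.graph.neighbors(atom):
                        if nbr in members and nbr not in seen:
                            seen[nbr] = depth
                            nxt.append(nbr)
                frontier = nxt
            for target, d in seen.items():
                out[(source, target)] = d
        return out


@dataclass
class BondEnvironment:
    """A target bond plus the sphere index of every atom.

    ``spheres[a] = min(d(a, i), d(a, j))`` for target bond ``(i, j)``;
    both bond atoms sit in sphere 0.  Fragment membership (``fragment_side``)
    is computed lazily and only defined for non-ring bonds.
    """

    graph: MolecularGraph
    bond: tuple[int, int]
    distances: np.ndarray
    spheres: np.ndarray
    _fragments: tuple[Fragment, Fragment] | None = field(default=None, repr=False)

    @property
    def fragments(self) -> tuple[Fragment, Fragment]:
        if self._fragments is None:
            self._fragments = cleave_bond(self.graph, self.bond)
        return self._fragments

    @property
    def fragment_side(self) -> np.ndarray:
        """0/1 label per atom: which fragment it lands on after cleavage.
        The labelling is arbitrary (fragments are unordered)."""
        side = np.zeros(self.graph.n_atoms, dtype=np.int8)
        side[list(self.fragments[1].atom_ids)] = 1
        return side


def assign_spheres(g: MolecularGraph, bond: tuple[int, int]) -> BondEnvironment:
    """Sphere assignment for a target bond; orientation independent."""
    i, j = bond
    if g.bond_between(i, j) is None:
        raise StructureError(f"no bond between atoms {i} and {j}")
    dist = topological_distances(g)
    spheres = np.minimum(dist[i], dist[j])
    return BondEnvironment(g, (min(i, j), max(i, j)), dist, spheres)


def cleave_bond(g: MolecularGraph, bond: tuple[int, int]) -> tuple[Fragment, Fragment]:
    """Homolytic cleavage of a non-ring bond into two fragments.

    Raises :class:`CleavageError` for ring bonds (removing them leaves a
    single connected component).
    """
    i, j = min(bond), max(bond)
    b = g.bond_between(i, j)
    if b is None:
        raise StructureError(f"no bond between atoms {i} and {j}")
    if b.in_ring:
        raise CleavageError(
            f"bond {i}-{j} is in a ring; cleavage would not give two fragments"
        )
    side_i = _component_without(g, start=i, blocked_edge=(i, j))
    side_j = tuple(a for a in range(g.n_atoms) if a not in set(side_i))
    return Fragment(g, side_i), Fragment(g, side_j)


def _component_without(
    g: MolecularGraph, start: int, blocked_edge: tuple[int, int]
) -> tuple[int, ...]:
    bi, bj = blocked_edge
    seen = {start}
    frontier = [start]
    while frontier:
        nxt = []
        for atom in frontier:
            for nbr in g.neighbors(atom):
                if {atom, nbr} == {bi, bj}:
                    continue
                if nbr not in seen:
                    seen.add(nbr)
                    nxt.append(nbr)
        frontier = nxt
    return tuple(sorted(seen))
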