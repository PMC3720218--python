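"""Independent brute-force oracles used by the tests.

Everything here recomputes quantities from first principles with
networkx breadth-first searches and explicit pair enumeration, sharing no
code path with the library's scipy-based distance table or its tally
machinery.
"""

from __future__ import annotations

from collections import Counter

import networkx as nx


def to_networkx(g) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(g.n_atoms))
    G.add_edges_from((b.i, b.j) for b in g.bonds)
    return G


def nx_distances(g) -> dict[int, dict[int, int]]:
    return dict(nx.all_pairs_shortest_path_length(to_networkx(g)))


def naive_spheres(g, bond) -> list[int]:
    dist = nx_distances(g)
    i, j = bond
    return [min(dist[i][a], dist[j][a]) for a in range(g.n_atoms)]


def naive_fragment_sides(g, bond) -> list[int]:
    """0/1 fragment membership after removing the bond (networkx route)."""
    G = to_networkx(g)
    G.remove_edge(*bond)
    components = list(nx.connected_components(G))
    assert len(components) == 2
    side = [0] * g.n_atoms
    for atom in components[1]:
        side[atom] = 1
    return side


def naive_pair_tallies(g, bond, type_system: str):
    """All (outer sphere, distance, type pair) counts by full enumeration.

    ``type_system`` in {"element", "cn", "none"}; for "none" the key is
    (sphere, distance).
    """
    from bondscope.graph import atom_types

    dist = nx_distances(g)
    spheres = naive_spheres(g, bond)
    types = atom_types(g, type_system) if type_system != "none" else None
    tally: Counter = Counter()
    for a in range(g.n_atoms):
        for b in range(a + 1, g.n_atoms):
            d = dist[a][b]
            s = max(spheres[a], spheres[b])
            if type_system == "none":
                tally[(s, d)] += 1
            else:
                tally[(s, d, tuple(sorted((types[a], types[b]))))] += 1
    return tally


def naive_bb_difference(g, bond, type_system: str):
    """(pairs before) - (same-fragment pairs after), both recomputed from
    scratch: the after-distances come from per-fragment BFS."""
    from bondscope.graph import atom_types

    dist = nx_distances(g)
    side = naive_fragment_sides(g, bond)
    G = to_networkx(g)
    G.remove_edge(*bond)
    dist_after = dict(nx.all_pairs_shortest_path_length(G))
    types = atom_types(g, type_system) if type_system != "none" else None
    before: Counter = Counter()
    after: Counter = Counter()
    for a in range(g.n_atoms):
        for b in range(a + 1, g.n_atoms):
            key_type = (
                None if type_system == "none" else tuple(sorted((types[a], types[b])))
            )
            before[(dist[a][b], key_type)] += 1
            if side[a] == side[b]:
                after[(dist_after[a][b], key_type)] += 1
    return {key: before[key] - after.get(key, 0) for key in before}
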