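"""Descriptor catalog enumeration and per-family value computation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bondscope.dataset import enumerate_bonds
from bondscope.descriptors import (
    DescriptorCatalog,
    DescriptorDefinition,
    bond_breaking_difference,
    build_catalog,
    compute_matrix,
    compute_vector,
    fragment_point_descriptors,
    molecular_descriptors,
    pair_descriptors,
    point_descriptors,
    sphere_distance_feasible,
)
from bondscope.errors import CatalogError, CleavageError
from bondscope.example_molecule import TARGET_BOND, example_molecule
from bondscope.graph import CN_TYPES, ELEMENTS, parse_structure
from bondscope.spheres import assign_spheres
from bondscope.synthdata import generate_molecules

from oracles import naive_pair_tallies


class TestCatalog:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(max_sphere=7), 14 * 7 + 14),                      # 112
            (dict(max_sphere=4, include_molecular=False), 14 * 4),  # 56
            (dict(max_sphere=1, include_molecular=False), 14),
        ],
    )
    def test_cn_point_only_closed_forms(self, kwargs, expected):
        assert len(build_catalog("cn-point-only", **kwargs)) == expected

    def test_selection3_group_counts(self):
        counts = build_catalog("selection3").group_counts()
        assert counts["cn_point"] == 56
        assert counts["element_pair"] == 45
        assert counts["aromatic_fragment_point"] == 10
        # no-type pairs: feasibility-pruned enumeration over spheres 0-3,
        # distances 1-4 (sphere 0 admits only distance 1; sphere 1 at most 3)
        assert counts["no_type_pair"] == 1 + 3 + 4 + 4
        assert counts["pi_total"] == 4

    def test_unknown_preset_and_bad_distance(self):
        with pytest.raises(CatalogError):
            build_catalog("nope")
        with pytest.raises(CatalogError):
            build_catalog("selection3", distances=(1, 5))
        with pytest.raises(CatalogError):
            build_catalog("cn-point-only", max_sphere=0)

    def test_enumeration_is_deterministic_and_duplicate_free(self):
        a = build_catalog("full", max_sphere=5)
        b = build_catalog("full", max_sphere=5)
        assert a.names == b.names
        assert len(set(a.definitions)) == len(a)

    def test_feasibility_rule(self):
        assert sphere_distance_feasible(0, 1)
        assert not sphere_distance_feasible(0, 2)
        assert sphere_distance_feasible(1, 3)
        assert not sphere_distance_feasible(1, 4)
        assert sphere_distance_feasible(2, 4)

    def test_yaml_round_trip(self, tmp_path):
        catalog = build_catalog("selection3")
        path = tmp_path / "preset.yaml"
        catalog.to_yaml(path)
        loaded = DescriptorCatalog.from_yaml(path)
        assert loaded.names == catalog.names
        assert loaded.content_hash() == catalog.content_hash()


class TestPointDescriptors:
    def test_methane_sphere0_cn(self):
        g = parse_structure("C")
        h = next(a for a in range(g.n_atoms) if g.elements[a] == "H")
        env = assign_spheres(g, (0, h))
        counts = point_descriptors(env, "cn", "all", 0)
        assert counts["C4"] == 1 and counts["H1"] == 1
        assert sum(counts.values()) == 2

    def test_methane_sphere1_element(self):
        g = parse_structure("C")
        h = next(a for a in range(g.n_atoms) if g.elements[a] == "H")
        env = assign_spheres(g, (0, h))
        counts = point_descriptors(env, "element", "all", 1)
        assert counts == {"C": 0, "H": 3, "N": 0, "O": 0, "S": 0}

    def test_benzene_aromatic_restricted_sphere1(self):
        g = parse_structure("c1ccccc1")
        ring_bond = next(b for b in g.bonds if b.in_ring)
        env = assign_spheres(g, (ring_bond.i, ring_bond.j))
        counts = point_descriptors(env, "element", "aromatic", 1)
        assert counts["C"] == 2 and counts["H"] == 0

    def test_sphere_size_conservation(self, property_molecules):
        for g in property_molecules[:15]:
            for bond in enumerate_bonds(g)[:3]:
                env = assign_spheres(g, bond)
                for s in range(int(env.spheres.max()) + 1):
                    counts = point_descriptors(env, "cn", "all", s)
                    assert sum(counts.values()) == int((env.spheres == s).sum())


class TestPairDescriptors:
    def test_worked_example_cc_pair(self):
        g = example_molecule()
        env = assign_spheres(g, TARGET_BOND)
        assert pair_descriptors(env, "element", 2, 2)[("C", "C")] == 4

    def test_methane_hh_pairs(self):
        # sphere 1, distance 2: the three pairs among the sphere-1
        # hydrogens plus the three pairs each of them forms with the
        # sphere-0 hydrogen (outer atom in sphere 1, partner in a lower
        # sphere) — six in total by brute-force enumeration
        g = parse_structure("C")
        h = next(a for a in range(g.n_atoms) if g.elements[a] == "H")
        env = assign_spheres(g, (0, h))
        assert pair_descriptors(env, "element", 1, 2)[("H", "H")] == 6

    def test_target_bond_is_the_only_sphere0_pair(self, property_molecules):
        for g in property_molecules[:10]:
            for bond in enumerate_bonds(g)[:2]:
                env = assign_spheres(g, bond)
                assert pair_descriptors(env, "none", 0, 1) == 1

    def test_no_type_equals_sum_of_typed(self, property_molecules):
        for g in property_molecules[:10]:
            for bond in enumerate_bonds(g)[:2]:
                env = assign_spheres(g, bond)
                for sphere in (0, 1, 2):
                    for distance in (1, 2, 3):
                        typed = pair_descriptors(env, "element", sphere, distance)
                        assert pair_descriptors(env, "none", sphere, distance) == sum(
                            typed.values()
                        )


class TestBondBreakingDifference:
    def test_ethane_hand_counts(self):
        g = parse_structure("CC")
        env = assign_spheres(g, (0, 1))
        assert bond_breaking_difference(env, "element", 2)[("C", "H")] == 6
        assert bond_breaking_difference(env, "element", 3)[("H", "H")] == 9
        assert bond_breaking_difference(env, "element", 2)[("H", "H")] == 0

    def test_ring_bond_raises(self):
        g = parse_structure("C1CCCCC1")
        ring_bond = next(b for b in g.bonds if b.in_ring)
        env = assign_spheres(g, (ring_bond.i, ring_bond.j))
        with pytest.raises(CleavageError):
            bond_breaking_difference(env, "none", 2)

    def test_non_negative_and_matches_before_minus_after(self, property_molecules):
        from oracles import naive_bb_difference

        for g in property_molecules[:8]:
            for bond in enumerate_bonds(g)[:2]:
                env = assign_spheres(g, bond)
                oracle = naive_bb_difference(g, bond, "element")
                for distance in (1, 2, 3, 4):
                    values = bond_breaking_difference(env, "element", distance)
                    for pair, count in values.items():
                        assert count >= 0
                        assert count == oracle.get((distance, pair), 0)


class TestFragmentAndMolecular:
    def test_ethane_symmetric_fragments(self):
        g = parse_structure("CC")
        env = assign_spheres(g, (0, 1))
        assert fragment_point_descriptors(env, "element")["H"] == (3, 3)

    def test_ethanol_sorted_hydrogens(self):
        g = parse_structure("CCO")
        o = g.elements.index("O")
        carbon = next(a for a in g.neighbors(o) if g.elements[a] == "C")
        env = assign_spheres(g, (carbon, o))
        assert fragment_point_descriptors(env, "element")["H"] == (5, 1)

    def test_toluene_aromatic_totals(self):
        g = parse_structure("Cc1ccccc1")
        methyl = next(
            i
            for i, e in enumerate(g.elements)
            if e == "C" and not g.aromatic[i]
        )
        h = next(a for a in g.neighbors(methyl) if g.elements[a] == "H")
        env = assign_spheres(g, (methyl, h))
        frag = fragment_point_descriptors(env, "element", "aromatic")
        assert frag["C"] == (6, 0)
        # the merged (pi-total style) value is the whole-molecule count
        assert molecular_descriptors(g, "element", "aromatic")["C"] == 6

    def test_molecular_point_examples(self):
        assert molecular_descriptors(parse_structure("C"), "element") == {
            "C": 1, "H": 4, "N": 0, "O": 0, "S": 0
        }
        benzene = molecular_descriptors(parse_structure("c1ccccc1"), "cn")
        assert benzene["C3"] == 6 and benzene["H1"] == 6

    def test_molecular_pair_edge_enumeration(self):
        counts = molecular_descriptors(parse_structure("CC"), "element", distance=1)
        assert counts[("C", "C")] == 1
        assert counts[("C", "H")] == 6


class TestVectors:
    def test_empty_catalog_gives_empty_vector(self):
        g = parse_structure("CC")
        empty = DescriptorCatalog(definitions=())
        assert compute_vector(g, (0, 1), empty).shape == (0,)

    def test_orientation_invariance(self, property_molecules):
        catalog = build_catalog("selection3", max_sphere=3)
        for g in property_molecules[:10]:
            for bond in enumerate_bonds(g)[:2]:
                fwd = compute_vector(g, bond, catalog)
                rev = compute_vector(g, (bond[1], bond[0]), catalog)
                assert (fwd == rev).all()

    def test_topologically_equivalent_bonds_identical(self):
        # a symmetric amine: the two N-H bonds are related by an
        # automorphism and must be indistinguishable
        g = parse_structure("Nc1ccccc1")
        n = g.elements.index("N")
        h_bonds = [(n, a) for a in g.neighbors(n) if g.elements[a] == "H"]
        assert len(h_bonds) == 2
        catalog = build_catalog("full", max_sphere=7)
        v1 = compute_vector(g, h_bonds[0], catalog)
        v2 = compute_vector(g, h_bonds[1], catalog)
        assert (v1 == v2).all()

    def test_difference_beyond_max_sphere_is_invisible(self):
        # two molecules identical within 3 bonds of the target bond only
        catalog = build_catalog("cn-point-only", max_sphere=4, include_molecular=False)
        vectors = []
        for smiles in ("CCCCO", "CCCCS"):
            g = parse_structure(smiles)
            h = next(a for a in g.neighbors(0) if g.elements[a] == "H")
            vectors.append(compute_vector(g, (0, h), catalog))
        assert (vectors[0] == vectors[1]).all()

    def test_element_rollup_of_cn_points(self, property_molecules):
        for g in property_molecules[:10]:
            for bond in enumerate_bonds(g)[:2]:
                env = assign_spheres(g, bond)
                for s in (0, 1, 2):
                    cn = point_descriptors(env, "cn", "all", s)
                    el = point_descriptors(env, "element", "all", s)
                    for element in ELEMENTS:
                        rolled = sum(
                            count for lbl, count in cn.items()
                            if lbl.rstrip("0123456789") == element
                        )
                        assert el[element] == rolled

    def test_matrix_layout(self, property_molecules):
        catalog = build_catalog("cn-point-only", max_sphere=2)
        g = property_molecules[0]
        entries = [(g, bond) for bond in enumerate_bonds(g)[:3]]
        frame = compute_matrix(entries, catalog)
        assert list(frame.columns) == catalog.names
        assert frame.shape == (len(entries), len(catalog))


class TestOracleEquivalence:
    def test_pair_family_matches_naive_enumeration(self, property_molecules):
        catalog_distances = (1, 2, 3, 4)
        for g in property_molecules[:12]:
            for bond in enumerate_bonds(g)[:3]:
                env = assign_spheres(g, bond)
                oracle = naive_pair_tallies(g, bond, "cn")
                for s in range(4):
                    for d in catalog_distances:
                        values = pair_descriptors(env, "cn", s, d)
                        for pair, count in values.items():
                            assert count == oracle.get((s, d, pair), 0)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_consistency_invariants_hold_on_random_molecules(seed):
    """no-type = sum of typed pair counts and sphere conservation on
    generator-drawn molecules."""
    g = generate_molecules(1, max_heavy_atoms=8, seed=seed)[0]
    bonds = enumerate_bonds(g)
    if not bonds:
        return
    bond = bonds[seed % len(bonds)]
    env = assign_spheres(g, bond)
    for s in (0, 1, 2):
        counts = point_descriptors(env, "cn", "all", s)
        assert sum(counts.values()) == int((env.spheres == s).sum())
        for d in (1, 2, 3):
            typed = pair_descriptors(env, "cn", s, d)
            assert pair_descriptors(env, "none", s, d) == sum(typed.values())
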