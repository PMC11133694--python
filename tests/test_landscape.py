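"""Local minima, basins, disconnectivity tree and state grouping."""

import itertools

import networkx as nx
import numpy as np
import pytest

from energyscape import (
    MEMParams,
    assign_basins,
    boltzmann_distribution,
    build_disconnectivity_tree,
    find_local_minima,
    group_minima_into_states,
    neighbors,
)
from energyscape.landscape import StateDefinition

from conftest import random_params


def minimax_branch_oracle(energies, n, a, b):
    """Threshold-sweep reference: the highest energy value whose removal
    (of all patterns with energy >= threshold) disconnects minima a and b."""
    G = nx.Graph()
    for k in range(2 ** n):
        for i in range(n):
            G.add_edge(k, k ^ (1 << i))
    for eth in np.sort(np.unique(energies))[::-1]:
        keep = [k for k in range(2 ** n) if energies[k] < eth]
        H = G.subgraph(keep)
        if not (a in H and b in H and nx.has_path(H, a, b)):
            return eth
    raise AssertionError("minima never disconnected")


class TestNeighbors:
    def test_small_case(self):
        assert set(neighbors(0, 2)) == {1, 2}

    def test_cardinality_and_exclusion(self):
        for k in (0, 5, 511):
            nb = neighbors(k, 9)
            assert len(nb) == 9 and k not in nb

    def test_symmetry(self):
        for k in range(16):
            for j in neighbors(k, 4):
                assert k in neighbors(int(j), 4)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            neighbors(4, 2)


class TestLocalMinima:
    def test_positive_fields_single_minimum(self, single_well):
        _, table = single_well
        minima = find_local_minima(table)
        assert [k for k, _ in minima] == [7]  # all-active pattern

    def test_double_well(self, double_well):
        _, table = double_well
        assert {k for k, _ in find_local_minima(table)} == {0, 3}

    def test_flat_landscape_has_no_strict_minima(self):
        p = MEMParams(h=np.zeros(3), J=np.zeros((3, 3)))
        with pytest.warns(UserWarning, match="degenerate"):
            assert find_local_minima(boltzmann_distribution(p)) == []

    def test_sorted_by_energy(self):
        table = boltzmann_distribution(random_params(6, seed=20))
        energies = [e for _, e in find_local_minima(table)]
        assert energies == sorted(energies)


class TestBasins:
    def test_single_minimum_takes_everything(self, single_well):
        _, table = single_well
        basins = assign_basins(table)
        assert basins.basin_sizes.tolist() == [1.0]
        assert (basins.basin_of == 7).all()

    def test_symmetric_double_well_splits_evenly(self, double_well):
        _, table = double_well
        basins = assign_basins(table)
        np.testing.assert_allclose(basins.basin_sizes, [0.5, 0.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_is_total(self, seed):
        table = boltzmann_distribution(random_params(5, seed=seed))
        basins = assign_basins(table)
        assert basins.basin_sizes.sum() == pytest.approx(1.0)
        # every pattern's assigned minimum is a true local minimum
        assert set(np.unique(basins.basin_of)) == {k for k, _ in basins.minima}

    def test_descent_respects_energy_ordering(self):
        table = boltzmann_distribution(random_params(4, seed=33))
        basins = assign_basins(table)
        for k in range(16):
            assert table.energies[basins.basin_of[k]] <= table.energies[k]


class TestDisconnectivityTree:
    def test_double_well_tree(self, double_well):
        _, table = double_well
        tree = build_disconnectivity_tree(table)
        assert len(tree.leaves) == 2
        assert len(tree.internal_nodes) == 1
        # both mixed patterns sit at +1; the wells separate there
        assert tree.root.energy == pytest.approx(1.0)
        assert tree.branch_energy(0, 3) == pytest.approx(1.0)

    def test_single_minimum_single_leaf(self, single_well):
        _, table = single_well
        tree = build_disconnectivity_tree(table)
        assert tree.root.is_leaf and tree.internal_nodes == []

    def test_leaf_and_internal_counts(self):
        table = boltzmann_distribution(random_params(6, seed=40))
        minima = find_local_minima(table)
        tree = build_disconnectivity_tree(table, minima)
        assert len(tree.leaves) == len(minima)
        assert len(tree.internal_nodes) == len(minima) - 1

    def test_internal_energies_dominate_leaves(self):
        table = boltzmann_distribution(random_params(5, seed=41))
        tree = build_disconnectivity_tree(table)

        def check(node):
            if node.is_leaf:
                return node.energy
            tops = [check(c) for c in node.children]
            assert node.energy >= max(tops)
            return node.energy

        check(tree.root)

    @pytest.mark.parametrize("seed", range(8))
    def test_branch_energies_match_threshold_sweep_oracle(self, seed):
        n = 3 + seed % 2
        table = boltzmann_distribution(
            random_params(n, seed=100 + seed, coupling_scale=0.6)
        )
        minima = find_local_minima(table)
        if len(minima) < 2:
            pytest.skip("landscape has a single minimum")
        tree = build_disconnectivity_tree(table, minima)
        for (a, _), (b, _) in itertools.combinations(minima, 2):
            expected = minimax_branch_oracle(table.energies, n, a, b)
            assert tree.branch_energy(a, b) == pytest.approx(expected)

    def test_well_deepening_preserves_topology(self):
        # lowering one minimum's basin below its saddle keeps the same tree shape
        table = boltzmann_distribution(random_params(4, seed=55, coupling_scale=0.7))
        minima = find_local_minima(table)
        if len(minima) < 2:
            pytest.skip("needs two wells")
        basins = assign_basins(table)
        target = minima[-1][0]
        e2 = table.energies.copy()
        e2[basins.basin_of == target] -= 0.05  # well below the saddle gap
        from energyscape.mem import LandscapeTable

        w = np.exp(-(e2 - e2.min()))
        table2 = LandscapeTable(e2, w / w.sum(), 4)
        tree1 = build_disconnectivity_tree(table)
        tree2 = build_disconnectivity_tree(table2)

        def shape(node):
            if node.is_leaf:
                return node.minimum
            return tuple(sorted(map(str, (shape(c) for c in node.children))))

        assert shape(tree1.root) == shape(tree2.root)

    def test_newick_round_trip_through_skbio(self):
        skbio = pytest.importorskip("skbio")
        table = boltzmann_distribution(random_params(5, seed=60, coupling_scale=0.6))
        minima = find_local_minima(table)
        if len(minima) < 2:
            pytest.skip("single leaf")
        tree = build_disconnectivity_tree(table, minima)
        import io

        parsed = skbio.TreeNode.read(io.StringIO(tree.to_newick()))
        tips = {t.name for t in parsed.tips()}
        assert tips == {f"min{k}" for k, _ in minima}
        # branch lengths reconstruct leaf depths: root energy minus leaf energy
        root_e = tree.root.energy
        for k, e in minima:
            tip = parsed.find(f"min{k}")
            assert tip.accumulate_to_ancestor(parsed) == pytest.approx(root_e - e, abs=1e-6)


class TestStateGrouping:
    def test_explicit_mapping_honoured(self, double_well):
        _, table = double_well
        tree = build_disconnectivity_tree(table)
        states = group_minima_into_states(tree, mapping={0: "A", 3: "B"})
        assert states.state_of_minimum == {0: "A", 3: "B"}
        assert states.n_states == 2

    def test_incomplete_mapping_rejected(self, double_well):
        _, table = double_well
        tree = build_disconnectivity_tree(table)
        with pytest.raises(ValueError, match="cover"):
            group_minima_into_states(tree, mapping={0: "A"})

    def test_k_equals_one_merges_everything(self, double_well):
        _, table = double_well
        tree = build_disconnectivity_tree(table)
        states = group_minima_into_states(tree, k=1)
        assert states.n_states == 1

    def test_double_well_two_cut(self, double_well):
        _, table = double_well
        tree = build_disconnectivity_tree(table)
        states = group_minima_into_states(tree, k=2)
        assert states.n_states == 2
        assert states.state_of_minimum[0] != states.state_of_minimum[3]

    def test_cut_groups_follow_tree_structure(self):
        table = boltzmann_distribution(random_params(6, seed=70, coupling_scale=0.6))
        minima = find_local_minima(table)
        if len(minima) < 3:
            pytest.skip("needs three minima")
        tree = build_disconnectivity_tree(table, minima)
        states = group_minima_into_states(tree, k=2)
        # cutting at the root splits exactly into the root's two subtrees
        subtree_sets = [
            {leaf.minimum for leaf in child.leaves()} for child in tree.root.children
        ]
        grouped = {}
        for m, s in states.state_of_minimum.items():
            grouped.setdefault(s, set()).add(m)
        assert sorted(map(sorted, grouped.values())) == sorted(
            map(sorted, subtree_sets)
        )

    def test_state_of_pattern_covers_all(self, double_well):
        _, table = double_well
        basins = assign_basins(table)
        tree = build_disconnectivity_tree(table)
        states = group_minima_into_states(tree, k=2)
        codes = states.state_of_pattern(basins)
        assert codes.shape == (4,)
        assert set(codes) == {0, 1}

    def test_relabeling_within_state_preserves_pattern_states(self, double_well):
        _, table = double_well
        basins = assign_basins(table)
        a = StateDefinition({0: "X", 3: "X"})
        codes = a.state_of_pattern(basins)
        assert (codes == codes[0]).all()
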