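"""TES decomposition, differentiation trees and the level-by-level
tree-shape distance."""

import itertools

import networkx as nx
import numpy as np
import pytest

from nrbnkit.dynamics import find_attractors
from nrbnkit.noise import build_atm, AttractorTransitionMatrix, FlipSpec
from nrbnkit.dynamics import Attractor
from nrbnkit.tes import (
    DifferentiationTree,
    TreeNode,
    auto_levels,
    build_tree,
    compute_tes,
    match_ensemble,
    representative_tree,
    shape_table,
    sweep_thresholds,
    threshold_atn,
    tree_distance,
)

from conftest import random_small_net


def atm_from_probs(p: np.ndarray) -> AttractorTransitionMatrix:
    """Wrap a row-stochastic matrix as an ATM with dummy attractors."""
    n = p.shape[0]
    counts = np.rint(p * 1000).astype(np.int64)
    return AttractorTransitionMatrix(
        attractors=[
            Attractor(states=(i,), n_nodes=max(1, n.bit_length()), id=i)
            for i in range(n)
        ],
        counts=counts,
        unresolved=np.zeros(n, dtype=np.int64),
        flip=FlipSpec(),
        n_atlas=n,
    )


def random_atm(rng: np.random.Generator, n: int) -> AttractorTransitionMatrix:
    counts = rng.integers(0, 10, size=(n, n))
    counts[np.arange(n), np.arange(n)] += rng.integers(1, 20, size=n)
    mask = rng.random((n, n)) < 0.5
    counts = counts * (mask | np.eye(n, dtype=bool))
    return AttractorTransitionMatrix(
        attractors=[
            Attractor(states=(i,), n_nodes=8, id=i) for i in range(n)
        ],
        counts=counts.astype(np.int64),
        unresolved=np.zeros(n, dtype=np.int64),
        flip=FlipSpec(),
        n_atlas=n,
    )


class TestThresholding:
    def test_zero_threshold_keeps_every_edge(self, and_net):
        atlas = find_attractors(and_net, mode="exhaustive")
        atm = build_atm(and_net, atlas)
        g = threshold_atn(atm, 0.0)
        assert set(g.edges()) == {(0, 0), (1, 0)}

    def test_threshold_one_keeps_only_certain_transitions(self):
        p = np.array([[0.5, 0.5], [0.0, 1.0]])
        g = threshold_atn(atm_from_probs(p), 1.0)
        assert set(g.edges()) == {(1, 1)}

    def test_and_net_edges_survive_midrange_threshold(self, and_net):
        atlas = find_attractors(and_net, mode="exhaustive")
        atm = build_atm(and_net, atlas)
        g = threshold_atn(atm, 0.5)
        assert set(g.edges()) == {(0, 0), (1, 0)}


class TestComputeTES:
    def test_and_net_single_tes_with_transient(self, and_net):
        atlas = find_attractors(and_net, mode="exhaustive")
        atm = build_atm(and_net, atlas)
        part = compute_tes(threshold_atn(atm, 0.0))
        assert part.tes_list == [frozenset({0})]
        assert part.transient_attractors == frozenset({1})

    def test_isolated_attractors_are_singleton_tes(self):
        g = nx.DiGraph()
        g.add_nodes_from(range(3))
        part = compute_tes(g)
        assert part.tes_list == [frozenset({0}), frozenset({1}), frozenset({2})]

    def test_reciprocal_edges_merge_into_one_tes(self):
        g = nx.DiGraph([(0, 1), (1, 0)])
        part = compute_tes(g)
        assert part.tes_list == [frozenset({0, 1})]

    def test_tes_are_disjoint_and_cover_with_transients(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            atm = random_atm(rng, int(rng.integers(2, 9)))
            for delta in (0.0, 0.1, 0.5, 1.0):
                part = compute_tes(threshold_atn(atm, delta), delta)
                seen = set()
                for s in part.tes_list:
                    assert s, "TES must be non-empty"
                    assert not (s & seen), "TESs must be pairwise disjoint"
                    seen |= s
                assert seen | part.transient_attractors == set(range(atm.n))


class TestSweep:
    def test_explicit_levels_one_partition_each(self):
        p = np.array([[0.9, 0.1], [0.05, 0.95]])
        parts = sweep_thresholds(atm_from_probs(p), [0.0, 0.023, 0.056, 1.0])
        assert [q.threshold for q in parts] == [0.0, 0.023, 0.056, 1.0]

    def test_auto_levels_on_single_probability_atm(self, and_net):
        atlas = find_attractors(and_net, mode="exhaustive")
        atm = build_atm(and_net, atlas)
        assert auto_levels(atm) == [0.0, 1.0]

    def test_tes_count_nondecreasing_in_threshold(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            atm = random_atm(rng, int(rng.integers(2, 9)))
            parts = sweep_thresholds(atm)
            counts = [p.n_tes for p in parts]
            assert counts == sorted(counts)


class TestBuildTree:
    def test_root_to_leaves_progression(self):
        # one TES splits into two, then three singletons
        parts = sweep_thresholds(
            atm_from_probs(
                np.array(
                    [
                        [0.80, 0.10, 0.10],
                        [0.05, 0.90, 0.05],
                        [0.20, 0.20, 0.60],
                    ]
                )
            )
        )
        tree = build_tree(parts)
        assert tree.root.attractors == frozenset({0, 1, 2})
        leaves = [n for n in tree.nodes() if not n.children]
        assert all(len(n.attractors) == 1 for n in leaves)

    def test_single_attractor_yields_single_node_tree(self):
        parts = sweep_thresholds(atm_from_probs(np.array([[1.0]])))
        tree = build_tree(parts)
        assert tree.n_nodes == 1 and tree.depth == 0

    def test_minimal_split_two_leaf_children(self):
        from nrbnkit.tes import TESPartition

        parts = [
            TESPartition(0.0, [frozenset({0, 1})], frozenset()),
            TESPartition(0.5, [frozenset({0}), frozenset({1})], frozenset()),
        ]
        tree = build_tree(parts)
        assert len(tree.root.children) == 2
        assert tree.depth == 1

    def test_identical_tes_across_levels_persist_without_chains(self):
        from nrbnkit.tes import TESPartition

        parts = [
            TESPartition(0.0, [frozenset({0, 1})], frozenset()),
            TESPartition(0.3, [frozenset({0, 1})], frozenset()),
            TESPartition(0.9, [frozenset({0}), frozenset({1})], frozenset()),
        ]
        tree = build_tree(parts)
        assert tree.n_nodes == 3  # no unary duplicate of the root

    def test_split_first_level_gets_virtual_root(self):
        from nrbnkit.tes import TESPartition

        parts = [TESPartition(0.0, [frozenset({0}), frozenset({1})], frozenset())]
        tree = build_tree(parts)
        assert tree.virtual_root and len(tree.root.children) == 2


def leaf(label=None):
    return TreeNode(label=label)


def star(n_children):
    return DifferentiationTree(root=TreeNode(children=[leaf() for _ in range(n_children)]))


def naive_tree_distance(h: DifferentiationTree, t: DifferentiationTree) -> int:
    """Independent two-pass reimplementation over explicit (level, k) grids."""

    def counts(tree):
        rows: dict[tuple[int, int], int] = {}

        def walk(node, level):
            rows[(level, len(node.children))] = rows.get((level, len(node.children)), 0) + 1
            for c in node.children:
                walk(c, level + 1)

        walk(tree.root, 0)
        return rows

    ch, ct = counts(h), counts(t)
    lmax = max(l for l, _ in list(ch) + list(ct))
    kmax = max(k for _, k in list(ch) + list(ct))
    total = 0
    for l in range(lmax + 1):
        for k in range(kmax + 1):
            total += abs(ch.get((l, k), 0) - ct.get((l, k), 0))
    return total


def random_tree(rng: np.random.Generator, max_nodes: int = 20) -> DifferentiationTree:
    root = TreeNode()
    nodes = [root]
    n = int(rng.integers(1, max_nodes))
    for _ in range(n - 1):
        parent = nodes[int(rng.integers(len(nodes)))]
        child = TreeNode()
        parent.children.append(child)
        nodes.append(child)
    return DifferentiationTree(root=root)


class TestTreeDistance:
    def test_self_distance_is_zero(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            t = random_tree(rng)
            assert tree_distance(t, t) == 0

    def test_two_vs_three_leaf_star(self):
        # |n(2,0)-0| + |0-n(3,0)| + |2-3| = 1 + 1 + 1 = 3
        assert tree_distance(star(2), star(3)) == 3

    def test_symmetry_and_oracle_equality(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            a, b = random_tree(rng), random_tree(rng)
            d = tree_distance(a, b)
            assert d == tree_distance(b, a)
            assert d == naive_tree_distance(a, b)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            a, b, c = (random_tree(rng, 12) for _ in range(3))
            assert tree_distance(a, c) <= tree_distance(a, b) + tree_distance(b, c)

    def test_labels_do_not_enter_the_distance(self):
        a = DifferentiationTree(root=TreeNode(label="x", children=[leaf("p"), leaf("q")]))
        b = DifferentiationTree(root=TreeNode(label="y", children=[leaf("r"), leaf("s")]))
        assert tree_distance(a, b) == 0


class TestRepresentativeTree:
    def test_single_probability_atm_has_unique_tree(self, and_net):
        atlas = find_attractors(and_net, mode="exhaustive")
        atm = build_atm(and_net, atlas)
        tree, freq = representative_tree(atm, depth=2, seed=0)
        assert freq == 1.0

    def test_depth_one_returns_minimum_threshold_tree(self):
        atm = atm_from_probs(np.array([[0.7, 0.3], [0.2, 0.8]]))
        tree, freq = representative_tree(atm, depth=1, seed=0)
        base = build_tree(sweep_thresholds(atm, [auto_levels(atm)[0]]))
        assert shape_table(tree) == shape_table(base)

    def test_modal_frequency_stabilises_with_more_samples(self):
        rng = np.random.default_rng(5)
        atm = random_atm(rng, 6)
        f = [
            representative_tree(atm, depth=3, n_threshold_samples=ns, seed=6)[1]
            for ns in (50, 400)
        ]
        # enumerated exactly once the budget covers all combinations
        assert abs(f[0] - f[1]) < 0.35


class TestMatchEnsemble:
    def test_network_matching_its_own_tree(self, and_net):
        atlas = find_attractors(and_net, mode="exhaustive")
        atm = build_atm(and_net, atlas)
        own = build_tree(sweep_thresholds(atm))
        results = match_ensemble([and_net], own, tolerance=0, n_samples=4, seed=0)
        assert results[0].matched and results[0].best_distance == 0

    def test_infinite_tolerance_matches_every_resolved_network(self):
        rng = np.random.default_rng(7)
        nets = [random_small_net(rng, n=8, k=2, bias=0.5) for _ in range(3)]
        results = match_ensemble(
            nets, star(2), tolerance=float("inf"), n_samples=64, seed=1
        )
        for r in results:
            assert r.matched or r.undetermined
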