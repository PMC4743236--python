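"""Threshold Ergodic Sets and emergent differentiation trees.

Pruning the attractor transition network (ATN) at a noise-resistance
threshold delta removes the transitions with probability below delta; the
*Threshold Ergodic Sets* (TESs) at delta are the terminal strongly
connected components of what remains — sets of attractors the noisy
dynamics can wander within but not leave.  Each TES models a cell type;
as delta grows the TESs split, and the hierarchy of splits across an
increasing threshold sweep is the emergent differentiation tree: a single
multi-attractor TES behaves like a multipotent stem cell, single-attractor
TESs like fully differentiated types.

Trees are compared by the level-by-level shape statistic

    d_hat_h(T) = sum_{l=0}^{l*} sum_{k=0}^{k*} | n_h(k,l) - n_T(k,l) |

where n_x(k,l) is the number of nodes of tree x at depth l with exactly k
children, and l*, k* are the maxima over both trees.  The statistic ignores
node labels entirely; it is an L1 distance between shape tables and hence a
pseudometric.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .model import NetworkError
from .noise import AttractorTransitionMatrix

__all__ = [
    "TESPartition",
    "TreeNode",
    "DifferentiationTree",
    "threshold_atn",
    "compute_tes",
    "sweep_thresholds",
    "auto_levels",
    "build_tree",
    "shape_table",
    "tree_distance",
    "representative_tree",
    "match_ensemble",
    "MatchResult",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# TES decomposition
# ---------------------------------------------------------------------------

@dataclass
class TESPartition:
    """TES decomposition of the pruned ATN at one threshold."""

    threshold: float
    tes_list: list[frozenset[int]]
    transient_attractors: frozenset[int]

    @property
    def n_tes(self) -> int:
        return len(self.tes_list)


def threshold_atn(atm: AttractorTransitionMatrix, delta: float) -> nx.DiGraph:
    """Weighted ATN with every transition of probability < delta removed.

    delta = 0 removes nothing; self-transitions obey the same rule (they
    never affect SCC membership anyway).
    """
    if not 0.0 <= delta <= 1.0:
        raise NetworkError("threshold must lie in [0, 1]")
    g = nx.DiGraph()
    g.add_nodes_from(range(atm.n))
    for i, j, p in atm.edge_list():
        if p >= delta:
            g.add_edge(i, j, weight=p)
    return g


def compute_tes(graph: nx.DiGraph, threshold: float = 0.0) -> TESPartition:
    """Terminal strongly connected components of a pruned ATN.

    A component is terminal when no edge leaves it; its attractors can
    wander among themselves but never escape.  Attractors in non-terminal
    components are transient at this threshold.
    """
    condensation = nx.condensation(graph)
    tes_list = []
    transient: set[int] = set()
    for comp_id in condensation.nodes:
        members = condensation.nodes[comp_id]["members"]
        if condensation.out_degree(comp_id) == 0:
            tes_list.append(frozenset(members))
        else:
            transient.update(members)
    tes_list.sort(key=lambda s: min(s))
    return TESPartition(
        threshold=threshold,
        tes_list=tes_list,
        transient_attractors=frozenset(transient),
    )


def auto_levels(atm: AttractorTransitionMatrix) -> list[float]:
    """Sorted distinct off-diagonal transition probabilities, with 0 and 1
    included as sentinels."""
    p = atm.probs
    vals = {0.0, 1.0}
    for i in range(atm.n):
        for j in range(atm.n):
            if i != j and p[i, j] > 0:
                vals.add(float(p[i, j]))
    return sorted(vals)


def sweep_thresholds(
    atm: AttractorTransitionMatrix, levels: list[float] | None = None
) -> list[TESPartition]:
    """One TES partition per threshold level (auto levels when omitted)."""
    if levels is None:
        levels = auto_levels(atm)
    if list(levels) != sorted(set(levels)):
        raise NetworkError("threshold levels must be strictly increasing")
    return [compute_tes(threshold_atn(atm, d), d) for d in levels]


# ---------------------------------------------------------------------------
# Differentiation trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    label: str | None = None
    attractors: frozenset[int] | None = None
    level: float | None = None
    children: list["TreeNode"] = field(default_factory=list)


@dataclass
class DifferentiationTree:
    """Rooted tree of TES splits along an increasing threshold sweep.

    Also used for externally supplied target trees (labels only, no
    attractor annotations).  ``virtual_root`` marks a forest stitched under
    an artificial root because the first sweep level was already split.
    """

    root: TreeNode
    levels: list[float] = field(default_factory=list)
    virtual_root: bool = False

    def nodes(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out

    @property
    def n_nodes(self) -> int:
        return len(self.nodes())

    @property
    def depth(self) -> int:
        def rec(node: TreeNode) -> int:
            return 1 + max((rec(c) for c in node.children), default=-1)

        return rec(self.root)


def build_tree(
    partitions: list[TESPartition], merge_identical: bool = True
) -> DifferentiationTree:
    """Assemble the differentiation tree from a threshold sweep.

    A TES at level t+1 becomes the child of the level-t TES containing it.
    When a TES is unchanged between consecutive levels the node persists
    (no unary chains) unless ``merge_identical=False``.  A child that is no
    subset of any parent (re-entrant transients) attaches to the parent
    with maximal overlap, logged.  If the very first level is already split,
    the forest is stitched under a virtual root and flagged.
    """
    if not partitions:
        raise NetworkError("no partitions to build a tree from")
    if partitions[0].n_tes < 1:
        raise NetworkError("first sweep level yields no TES")
    levels = [p.threshold for p in partitions]

    first = partitions[0]
    frontier: dict[frozenset[int], TreeNode] = {}
    virtual = first.n_tes > 1
    if virtual:
        root = TreeNode(label="root", attractors=None, level=None)
        log.warning("first threshold level already split; adding a virtual root")
        for s in first.tes_list:
            node = TreeNode(attractors=s, level=first.threshold)
            root.children.append(node)
            frontier[s] = node
    else:
        root = TreeNode(attractors=first.tes_list[0], level=first.threshold)
        frontier[first.tes_list[0]] = root

    overlap_attached = 0
    for part in partitions[1:]:
        new_frontier: dict[frozenset[int], TreeNode] = {}
        for s in part.tes_list:
            if merge_identical and s in frontier:
                new_frontier[s] = frontier[s]  # node persists, no duplicate
                continue
            parent = None
            for ps, pnode in frontier.items():
                if s <= ps:
                    parent = pnode
                    break
            if parent is None:
                best, best_overlap = None, -1
                for ps, pnode in frontier.items():
                    ov = len(s & ps)
                    if ov > best_overlap:
                        best, best_overlap = pnode, ov
                parent = best
                overlap_attached += 1
                log.debug(
                    "TES %s at threshold %.6g is no subset of any parent; "
                    "attached by maximal overlap", sorted(s), part.threshold,
                )
            child = TreeNode(attractors=s, level=part.threshold)
            parent.children.append(child)
            new_frontier[s] = child
        frontier = new_frontier

    if overlap_attached:
        # re-entrant transients: an attractor transient at a lower threshold
        # resurfaces as its own terminal component once its escape edge is
        # pruned; refinement is violated and the attachment is by overlap
        log.info(
            "%d TES nodes attached by maximal overlap (re-entrant transients)",
            overlap_attached,
        )
    return DifferentiationTree(root=root, levels=levels, virtual_root=virtual)


# ---------------------------------------------------------------------------
# Shape tables and the level-by-level distance
# ---------------------------------------------------------------------------

def shape_table(tree: DifferentiationTree) -> dict[tuple[int, int], int]:
    """Materialise n_x(k,l): counts of nodes at depth l with k children."""
    table: dict[tuple[int, int], int] = {}

    def rec(node: TreeNode, depth: int) -> None:
        key = (depth, len(node.children))
        table[key] = table.get(key, 0) + 1
        for c in node.children:
            rec(c, depth + 1)

    rec(tree.root, 0)
    return table


def _shape_signature(table: dict[tuple[int, int], int]) -> tuple:
    return tuple(sorted(table.items()))


def tree_distance(h, t) -> int:
    """Level-by-level structural distance between two rooted trees.

    Accepts trees or precomputed shape tables.  Sums |n_h(k,l) - n_T(k,l)|
    over all depths and child counts occurring in either tree; zero iff the
    shape tables are identical.  Labels never enter the comparison.
    """
    th = h if isinstance(h, dict) else shape_table(h)
    tt = t if isinstance(t, dict) else shape_table(t)
    keys = set(th) | set(tt)
    return int(sum(abs(th.get(k, 0) - tt.get(k, 0)) for k in keys))


# ---------------------------------------------------------------------------
# Representative tree and ensemble matching
# ---------------------------------------------------------------------------

def _threshold_combinations(
    levels: list[float], depth: int, budget: int, rng: np.random.Generator
) -> tuple[list[tuple[float, ...]], bool]:
    """Increasing threshold tuples of the given length, always anchored at
    the smallest auto level.  Enumerates exhaustively when feasible within
    the budget, otherwise samples; returns (combos, exhaustive?)."""
    if depth < 1:
        raise NetworkError("tree depth must be >= 1")
    base, rest = levels[0], levels[1:]
    if depth == 1:
        return [(base,)], True
    if depth - 1 > len(rest):
        return [], True  # not enough distinct levels
    from math import comb

    total = comb(len(rest), depth - 1)
    if total <= budget:
        return (
            [(base, *c) for c in itertools.combinations(rest, depth - 1)],
            True,
        )
    combos = []
    for _ in range(budget):
        pick = rng.choice(len(rest), size=depth - 1, replace=False)
        combos.append((base, *[rest[i] for i in sorted(pick)]))
    return combos, False


def representative_tree(
    atm: AttractorTransitionMatrix,
    depth: int,
    n_threshold_samples: int = 200,
    seed: int | None = None,
) -> tuple[DifferentiationTree, float]:
    """The modal emergent tree over threshold combinations of a given depth.

    Trees are grouped by shape table; ties break toward the smaller tree
    and then the lexicographically smaller shape signature.  Returns the
    modal tree and its frequency among the evaluated combinations.
    """
    rng = np.random.default_rng(seed)
    levels = auto_levels(atm)
    combos, _ = _threshold_combinations(levels, depth, n_threshold_samples, rng)
    if not combos:
        raise NetworkError(
            f"no threshold combination of depth {depth} exists "
            f"({len(levels)} distinct levels)"
        )
    groups: dict[tuple, list[DifferentiationTree]] = {}
    for combo in combos:
        tree = build_tree(sweep_thresholds(atm, list(combo)))
        groups.setdefault(_shape_signature(shape_table(tree)), []).append(tree)
    best_sig = min(
        groups,
        key=lambda sig: (
            -len(groups[sig]),
            groups[sig][0].n_nodes,
            sig,
        ),
    )
    return groups[best_sig][0], len(groups[best_sig]) / len(combos)


@dataclass
class MatchResult:
    """Per-network outcome of differentiation-tree matching."""

    index: int
    matched: bool
    best_distance: int | None
    best_thresholds: tuple[float, ...] | None
    undetermined: bool
    n_attractors: int = 0


def best_tree_distance(
    atm: AttractorTransitionMatrix,
    target: DifferentiationTree,
    budget: int = 500,
    seed: int | None = None,
    tolerance: float = 0,
) -> tuple[int | None, tuple[float, ...] | None, bool]:
    """Smallest d_hat between the target and any emergent tree of matching
    depth, evaluating at most ``budget`` threshold combinations.

    Returns (best distance, realizing thresholds, exhausted?) where
    ``exhausted`` means the budget cut the search short of full enumeration
    without reaching the tolerance.
    """
    rng = np.random.default_rng(seed)
    target_table = shape_table(target)
    depth = target.depth + 1  # threshold levels needed to express that depth
    levels = auto_levels(atm)
    combos, exhaustive = _threshold_combinations(
        levels, min(depth, len(levels)), budget, rng
    )
    if not combos:
        return None, None, False
    best: int | None = None
    best_combo = None
    for combo in combos:
        tree = build_tree(sweep_thresholds(atm, list(combo)))
        d = tree_distance(target_table, tree)
        if best is None or d < best:
            best, best_combo = d, combo
        if best <= tolerance:
            return best, best_combo, False
    return best, best_combo, not exhaustive


def match_ensemble(
    networks,
    target: DifferentiationTree,
    tolerance: float = 0,
    budget: int = 500,
    n_samples: int = 500,
    max_steps: int = 1000,
    seed: int | None = None,
    flip=None,
    max_attractors: int = 64,
) -> list[MatchResult]:
    """Select the networks whose emergent differentiation tree comes within
    ``tolerance`` of the target (the ensemble-screening protocol).

    Per network: attractor atlas -> ATM -> candidate trees over threshold
    combinations at the target's depth; a network matches iff some tree has
    d_hat <= tolerance.  Budget exhaustion (combination cap, or atlases
    larger than ``max_attractors``) marks the network undetermined, never
    silently matched.
    """
    from .dynamics import find_attractors
    from .noise import FlipSpec, build_atm

    flip = flip or FlipSpec()
    master = np.random.SeedSequence(seed)
    results: list[MatchResult] = []
    for i, (net, child) in enumerate(zip(networks, master.spawn(len(networks)))):
        s1, s2, s3 = (int(c.generate_state(1)[0] % 2**31) for c in child.spawn(3))
        atlas = find_attractors(
            net, mode="sampled", n_samples=n_samples, max_steps=max_steps, seed=s1
        )
        if len(atlas) == 0 or len(atlas) > max_attractors:
            # nothing resolved, or too many attractors for the budget
            results.append(
                MatchResult(i, False, None, None, True, n_attractors=len(atlas))
            )
            continue
        atm = build_atm(net, atlas, flip=flip, max_steps=max_steps, seed=s2)
        best, combo, exhausted = best_tree_distance(
            atm, target, budget=budget, seed=s3, tolerance=tolerance
        )
        if best is None:
            results.append(
                MatchResult(i, False, None, None, True, n_attractors=len(atlas))
            )
            continue
        matched = best <= tolerance
        results.append(
            MatchResult(
                i,
                matched,
                best,
                combo,
                undetermined=(not matched and exhausted),
                n_attractors=len(atlas),
            )
        )
    return results
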