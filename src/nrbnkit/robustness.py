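"""Knockout/knock-in experiments, avalanches, sensitivity and classical
network-topology measures.

A knockout clamps a gene to 0 (its function is silenced but kept, so the
wild type is recoverable); a knock-in clamps to 1.  The size of a
perturbation is measured by its *avalanche* — the number of genes whose
activation pattern in the perturbed attractor differs from the wild-type
pattern — and per-gene *sensitivity* counts the experiments in which a
gene's pattern was affected.  The knockout tree screen re-runs the whole
atlas -> ATM -> differentiation-tree pipeline for each silenced gene and
scores the emergent tree against a target differentiation tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .dynamics import find_attractors
from .model import NetworkError, RegulatoryNetwork, as_state, trajectory
from .noise import FlipSpec, build_atm
from .tes import DifferentiationTree, best_tree_distance

__all__ = [
    "knockout",
    "knockin",
    "avalanche",
    "sensitivity_matrix",
    "run_flip_experiments",
    "ko_tree_screen",
    "network_measures",
]

log = logging.getLogger(__name__)


def knockout(net: RegulatoryNetwork, gene: str) -> RegulatoryNetwork:
    """Copy of the network with ``gene`` clamped to 0 (function silenced)."""
    if gene not in net.functions:
        raise NetworkError(f"unknown gene {gene!r}")
    return net.with_clamps({gene: 0})


def knockin(net: RegulatoryNetwork, gene: str) -> RegulatoryNetwork:
    """Copy of the network with ``gene`` clamped to 1."""
    if gene not in net.functions:
        raise NetworkError(f"unknown gene {gene!r}")
    return net.with_clamps({gene: 1})


# ---------------------------------------------------------------------------
# Avalanches
# ---------------------------------------------------------------------------

def _cycle_matrix(net: RegulatoryNetwork, state, horizon: int) -> np.ndarray | None:
    traj = trajectory(net, state, horizon)
    if not traj.closed:
        return None
    return np.array(traj.cycle, dtype=np.uint8)


def _affected_nodes(wt: np.ndarray, pert: np.ndarray) -> np.ndarray:
    """Boolean mask of nodes whose attractor pattern differs.

    Equal cycle lengths: patterns are compared under the global cyclic
    rotation minimising total Hamming mismatch (smallest rotation wins
    ties).  Unequal lengths: a node is unaffected only if its pattern is
    constant and equal in both cycles.
    """
    lw, lp = len(wt), len(pert)
    if lw == lp:
        best_mask, best_total = None, None
        for r in range(lw):
            rolled = np.roll(pert, -r, axis=0)
            mism = (wt != rolled).any(axis=0)
            total = int(mism.sum())
            if best_total is None or total < best_total:
                best_total, best_mask = total, mism
        return best_mask
    const_w = (wt == wt[0]).all(axis=0)
    const_p = (pert == pert[0]).all(axis=0)
    same_const = const_w & const_p & (wt[0] == pert[0])
    return ~same_const


def avalanche(
    net: RegulatoryNetwork,
    perturbed: RegulatoryNetwork,
    initial_state,
    horizon: int = 1000,
) -> tuple[set[str], int, bool]:
    """Evolve wild type and perturbed network from the same initial state
    into their attractors and count the genes whose pattern differs.

    Returns (affected gene set, avalanche size, resolved flag); an
    experiment that does not relax within the horizon is unresolved and
    reports an empty set.
    """
    if net.nodes != perturbed.nodes:
        raise NetworkError("networks must share the same node set and order")
    s = as_state(initial_state, net.n_nodes)
    wt = _cycle_matrix(net, s, horizon)
    pt = _cycle_matrix(perturbed, s, horizon)
    if wt is None or pt is None:
        return set(), 0, False
    mask = _affected_nodes(wt, pt)
    affected = {net.nodes[i] for i in np.nonzero(mask)[0]}
    return affected, len(affected), True


def sensitivity_matrix(
    net: RegulatoryNetwork, affected_sets: list[set[str]]
) -> dict[str, int]:
    """sensitivity[v] = number of experiments whose avalanche contains v.

    The conservation identity sum_v sensitivity[v] = sum_e avalanche_e
    holds by construction.
    """
    if not affected_sets:
        raise NetworkError("at least one experiment is required")
    counts = {n: 0 for n in net.nodes}
    for s in affected_sets:
        for v in s:
            counts[v] += 1
    return counts


# ---------------------------------------------------------------------------
# Experiment batches
# ---------------------------------------------------------------------------

def _select_targets(
    net: RegulatoryNetwork, targets, rng: np.random.Generator
) -> list[str]:
    if targets is None or targets == "all":
        return list(net.nodes)
    if isinstance(targets, int):
        if not 1 <= targets <= net.n_nodes:
            raise NetworkError("random target count out of range")
        pick = rng.choice(net.n_nodes, size=targets, replace=False)
        return [net.nodes[i] for i in sorted(pick)]
    unknown = [t for t in targets if t not in net.functions]
    if unknown:
        raise NetworkError(f"unknown targets {unknown}")
    return list(targets)


def run_perturbation_experiments(
    net: RegulatoryNetwork,
    kind: str = "knockout",
    targets=None,
    repetitions: int = 1,
    horizon: int = 1000,
    flip_duration: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Batch of temporary-flip / knockout / knock-in experiments.

    Each repetition draws a random initial state; each target gene is
    perturbed and the avalanche against the wild-type relaxation recorded.
    Returns one row per (repetition, target) with the avalanche size, the
    affected genes and a resolution flag.
    """
    if kind not in ("flip", "knockout", "knockin"):
        raise NetworkError(f"unknown perturbation kind {kind!r}")
    if repetitions < 1:
        raise NetworkError("repetitions must be >= 1")
    rng = np.random.default_rng(seed)
    chosen = _select_targets(net, targets, rng)
    rows = []
    for rep in range(repetitions):
        s0 = rng.integers(0, 2, size=net.n_nodes, dtype=np.uint8)
        for gene in chosen:
            if kind == "flip":
                from .noise import apply_flip

                released = apply_flip(net, s0, gene, duration=flip_duration)
                wt = _cycle_matrix(net, s0, horizon)
                pt = _cycle_matrix(net, released, horizon)
                if wt is None or pt is None:
                    affected, size, ok = set(), 0, False
                else:
                    mask = _affected_nodes(wt, pt)
                    affected = {net.nodes[i] for i in np.nonzero(mask)[0]}
                    size, ok = len(affected), True
            else:
                pert = knockout(net, gene) if kind == "knockout" else knockin(net, gene)
                affected, size, ok = avalanche(net, pert, s0, horizon)
            rows.append(
                {
                    "repetition": rep,
                    "target": gene,
                    "kind": kind,
                    "avalanche": size,
                    "affected": ",".join(sorted(affected)),
                    "resolved": ok,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Knockout differentiation-tree screen
# ---------------------------------------------------------------------------

def ko_tree_screen(
    net: RegulatoryNetwork,
    genes,
    target: DifferentiationTree,
    n_samples: int = 500,
    max_steps: int = 1000,
    budget: int = 200,
    flip: FlipSpec | None = None,
    seed: int | None = None,
    max_attractors: int = 64,
    include_baseline: bool = True,
) -> pd.DataFrame:
    """Knock out each gene in turn and score the emergent differentiation
    tree against the target (the per-gene d_hat distribution).

    Returns a DataFrame with one row per gene (plus a wild-type baseline
    row) holding the best d_hat found within the per-gene budget, the number
    of attractors, and an undetermined flag on budget exhaustion.
    """
    master = np.random.SeedSequence(seed)
    jobs = ([None] if include_baseline else []) + list(genes)
    rows = []
    for gene, child in zip(jobs, master.spawn(len(jobs))):
        s1, s2, s3 = (int(c.generate_state(1)[0] % 2**31) for c in child.spawn(3))
        current = net if gene is None else knockout(net, gene)
        atlas = find_attractors(
            current, mode="sampled", n_samples=n_samples, max_steps=max_steps, seed=s1
        )
        label = "wild-type" if gene is None else gene
        if len(atlas) == 0 or len(atlas) > max_attractors:
            rows.append(
                {"gene": label, "d_hat": np.nan, "n_attractors": len(atlas),
                 "undetermined": True}
            )
            continue
        atm = build_atm(
            current, atlas, flip=flip or FlipSpec(), max_steps=max_steps, seed=s2
        )
        best, _, exhausted = best_tree_distance(
            atm, target, budget=budget, seed=s3, tolerance=0
        )
        rows.append(
            {
                "gene": label,
                "d_hat": np.nan if best is None else best,
                "n_attractors": len(atlas),
                "undetermined": best is None or (exhausted and best > 0),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Classical network measures
# ---------------------------------------------------------------------------

def network_measures(net: RegulatoryNetwork) -> dict:
    """Clustering coefficient, diameter, average path length and degree
    distributions.

    Clustering is the global transitivity of the undirected skeleton.
    Diameter and average shortest-path length are computed with directed
    paths on the largest weakly connected component; ordered pairs with no
    directed path are excluded and flagged.
    """
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(net.edges())
    und = g.to_undirected()

    result: dict = {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "clustering_coefficient": nx.transitivity(und) if net.n_edges else 0.0,
        "in_degree_distribution": dict(
            sorted(
                pd.Series([d for _, d in g.in_degree()]).value_counts().items()
            )
        ),
        "out_degree_distribution": dict(
            sorted(
                pd.Series([d for _, d in g.out_degree()]).value_counts().items()
            )
        ),
    }
    components = list(nx.weakly_connected_components(g))
    result["n_weak_components"] = len(components)
    largest = max(components, key=len)
    sub = g.subgraph(largest)
    dists = []
    unreachable = 0
    for src, lengths in nx.all_pairs_shortest_path_length(sub):
        for dst in largest:
            if dst == src:
                continue
            if dst in lengths:
                dists.append(lengths[dst])
            else:
                unreachable += 1
    if dists:
        result["diameter"] = int(max(dists))
        result["average_path_length"] = float(np.mean(dists))
    else:
        result["diameter"] = None
        result["average_path_length"] = None
    result["unreachable_pairs"] = unreachable
    result["restricted_to_component"] = len(largest) < net.n_nodes
    return result
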