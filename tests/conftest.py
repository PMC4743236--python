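"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's vectorised simulation
path: they evaluate each node's Boolean function directly on tuples of
bits, enumerate the full state space, and follow successor pointers.  They
exist so the fast implementation can be checked against a naive one.
"""

from __future__ import annotations

import numpy as np
import pytest

from nrbnkit.model import BooleanFunction, RegulatoryNetwork


@pytest.fixture
def cycle_net() -> RegulatoryNetwork:
    """Two-gene network with a single 4-cycle: n1 := n2, n2 := NOT n1."""
    return RegulatoryNetwork(
        nodes=("n1", "n2"),
        functions={
            "n1": BooleanFunction.from_table(("n2",), (0, 1)),
            "n2": BooleanFunction.from_expression("NOT n1"),
        },
    )


@pytest.fixture
def and_net() -> RegulatoryNetwork:
    """Two fixed points: n1 := n1 AND n2, n2 := n1 AND n2."""
    return RegulatoryNetwork(
        nodes=("n1", "n2"),
        functions={
            "n1": BooleanFunction.from_expression("n1 AND n2"),
            "n2": BooleanFunction.from_expression("n1 AND n2"),
        },
    )


def random_small_net(rng: np.random.Generator, n: int, k: int, bias: float):
    """Hand-rolled random network used by the oracle tests (independent of
    the package's generators)."""
    names = tuple(f"v{i}" for i in range(n))
    functions = {}
    for i, name in enumerate(names):
        kk = min(k, n - 1)
        pool = [j for j in range(n) if j != i]
        regs = tuple(names[j] for j in rng.choice(pool, size=kk, replace=False))
        table = tuple(int(b) for b in (rng.random(1 << kk) < bias))
        functions[name] = BooleanFunction.from_table(regs, table)
    return RegulatoryNetwork(nodes=names, functions=functions)


# ---------------------------------------------------------------------------
# Naive oracles
# ---------------------------------------------------------------------------

def naive_step(net: RegulatoryNetwork, bits: tuple[int, ...]) -> tuple[int, ...]:
    """Per-node function evaluation on plain tuples; clamps override."""
    env = dict(zip(net.nodes, bits))
    out = []
    for name in net.nodes:
        if name in net.clamps:
            out.append(net.clamps[name])
            continue
        f = net.functions[name]
        out.append(f.evaluate([env[r] for r in f.inputs]))
    return tuple(out)


def naive_attractors(net: RegulatoryNetwork):
    """Exhaustive enumeration: canonical cycles with exact basin sizes.

    Returns a dict mapping the canonical cycle (tuple of state tuples,
    rotated to start at the smallest state) to its basin size.
    """
    n = net.n_nodes
    succ: dict[tuple, tuple] = {}
    all_states = []
    for code in range(1 << n):
        bits = tuple((code >> (n - 1 - i)) & 1 for i in range(n))
        all_states.append(bits)
        succ[bits] = naive_step(net, bits)

    assignment: dict[tuple, tuple] = {}
    basins: dict[tuple, int] = {}
    for s0 in all_states:
        path = []
        pos = {}
        s = s0
        while True:
            if s in assignment:
                cyc = assignment[s]
                break
            if s in pos:
                cycle = path[pos[s]:]
                k = cycle.index(min(cycle))
                cyc = tuple(cycle[k:] + cycle[:k])
                break
            pos[s] = len(path)
            path.append(s)
            s = succ[s]
        for state in path:
            assignment[state] = cyc
        basins[cyc] = basins.get(cyc, 0) + 1
    return basins


def naive_flip_release(
    net: RegulatoryNetwork, bits: tuple[int, ...], node: str, duration: int
) -> tuple[int, ...]:
    idx = net.nodes.index(node)
    held = 1 - bits[idx]
    s = bits
    for _ in range(duration):
        nxt = list(naive_step(net, s))
        nxt[idx] = held
        s = tuple(nxt)
    return s


def naive_relax(net: RegulatoryNetwork, bits: tuple[int, ...]):
    """Follow successors until a state repeats; return the canonical cycle."""
    seen = {}
    path = []
    s = bits
    while s not in seen:
        seen[s] = len(path)
        path.append(s)
        s = naive_step(net, s)
    cycle = path[seen[s]:]
    k = cycle.index(min(cycle))
    return tuple(cycle[k:] + cycle[:k])
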