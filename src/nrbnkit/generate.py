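"""Random generation and augmentation of Boolean regulatory networks.

Ensembles of networks are drawn with user-defined structural parameters
(size, wiring topology, mean connectivity) and functional parameters
(bias-random, canalyzing or random-logic update rules).  A partially
characterised *core* network can be augmented: new genes and regulatory
edges are added around it until a target size is reached, while every core
node, core edge and core function is preserved (up to the input-extension
policy when a core node gains new regulators).

Topology vocabularies:

``fixed-indegree``
    every node receives exactly K regulators, chosen uniformly.
``erdos-renyi``
    M directed edges placed uniformly among the allowed ordered pairs.
``barabasi-preferential``
    undirected preferential attachment, each edge then oriented uniformly
    at random.
``power-law``
    per-node in-degree drawn from a truncated discrete power law with the
    given exponent; regulators chosen uniformly.  The total edge count is
    stochastic under this mode.
``watts-strogatz``
    small-world ring lattice with rewiring; the undirected graph is made
    directed by including both orientations of every edge, so with rewiring
    probability 0 the directed ring lattice is returned exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .model import BooleanFunction, NetworkError, RegulatoryNetwork

__all__ = [
    "GenerationSpec",
    "AugmentationSpec",
    "REGIME_PRESETS",
    "generate_topology",
    "generate_functions",
    "generate_network",
    "generate_ensemble",
    "augment",
    "augment_ensemble",
    "canalyzing_inhibitor",
]

log = logging.getLogger(__name__)

TOPOLOGIES = (
    "fixed-indegree",
    "erdos-renyi",
    "barabasi-preferential",
    "power-law",
    "watts-strogatz",
)
FUNCTION_SCHEMES = ("bias-random", "canalyzing", "logic")

#: Named (K, bias) presets for the classical RBN dynamical regimes.  Two
#: chaotic variants circulate in the literature; both are exposed.
REGIME_PRESETS = {
    "ordered": {"k": 2, "bias": 0.3},
    "critical": {"k": 2, "bias": 0.5},
    "chaotic": {"k": 3, "bias": 0.5},
    "chaotic-low-bias": {"k": 3, "bias": 0.3},
}


class ConfigError(NetworkError):
    """Infeasible or inconsistent generation parameters."""


@dataclass
class GenerationSpec:
    """Parameters of one random-network draw.

    Exactly one of ``k`` (mean in-degree) or ``m_edges`` (total edge count)
    should be given for the edge-count topologies; for ``watts-strogatz``
    use ``ws_k``/``ws_p``; for ``power-law`` use ``exponent``.
    """

    n_nodes: int
    topology: str = "erdos-renyi"
    k: float | None = None
    m_edges: int | None = None
    exponent: float = 2.5
    ws_k: int = 4
    ws_p: float = 0.0
    self_loops: bool = False
    function_scheme: str = "bias-random"
    bias: float = 0.5
    seed: int | None = None
    ensemble_size: int = 1

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ConfigError("n_nodes must be >= 1")
        if self.topology not in TOPOLOGIES:
            raise ConfigError(f"unknown topology {self.topology!r}")
        if self.function_scheme not in FUNCTION_SCHEMES:
            raise ConfigError(f"unknown function scheme {self.function_scheme!r}")
        if not 0.0 <= self.bias <= 1.0:
            raise ConfigError("bias must be in [0, 1]")
        if self.ensemble_size < 1:
            raise ConfigError("ensemble_size must be >= 1")

    def edge_target(self) -> int:
        if self.m_edges is not None:
            return int(self.m_edges)
        if self.k is not None:
            return int(round(self.k * self.n_nodes))
        raise ConfigError("specify either k or m_edges")


@dataclass
class AugmentationSpec:
    """Target size and added-portion parameters for core augmentation.

    ``protect_core_inputs`` forbids new regulators on core nodes (new edges
    then connect new->new, core->new only).  ``core_extension_policy`` is
    how a core function absorbs any new inputs it gains:

    ``duplicate-then-bias`` (default)
        the table is replicated across the new-input combinations and every
        row with at least one new input active is resampled at ``bias``, so
        the all-new-inputs-off behaviour equals the original core function.
    ``silent``
        pure replication; the new inputs are non-functional.
    """

    n_nodes: int
    m_edges: int
    topology: str = "erdos-renyi"
    exponent: float = 2.5
    k: float | None = None
    function_scheme: str = "bias-random"
    bias: float = 0.5
    core_extension_policy: str = "duplicate-then-bias"
    protect_core_inputs: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.topology not in TOPOLOGIES:
            raise ConfigError(f"unknown topology {self.topology!r}")
        if self.function_scheme not in FUNCTION_SCHEMES:
            raise ConfigError(f"unknown function scheme {self.function_scheme!r}")
        if self.core_extension_policy not in ("duplicate-then-bias", "silent"):
            raise ConfigError(
                f"unknown core extension policy {self.core_extension_policy!r}"
            )
        if not 0.0 <= self.bias <= 1.0:
            raise ConfigError("bias must be in [0, 1]")


# ---------------------------------------------------------------------------
# Topology generation
# ---------------------------------------------------------------------------

def _node_names(n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"g{i:0{width}d}" for i in range(n)]


def _pairs_to_net(
    n_nodes: int, names: list[str], regulators: dict[str, list[str]]
) -> RegulatoryNetwork:
    return RegulatoryNetwork(
        nodes=tuple(names),
        functions={n: None for n in names},
        topology_only_inputs={n: tuple(regulators[n]) for n in names},
    )


def _sample_directed_pairs(
    rng: np.random.Generator,
    n: int,
    m: int,
    self_loops: bool,
    forbidden: set[tuple[int, int]] | None = None,
    allowed_pair=None,
) -> list[tuple[int, int]]:
    """Uniformly sample m distinct directed pairs (source, target)."""
    forbidden = forbidden or set()
    max_pairs = n * n if self_loops else n * (n - 1)
    if allowed_pair is None and m > max_pairs - len(forbidden):
        raise ConfigError(f"cannot place {m} edges among {max_pairs} ordered pairs")
    chosen: set[tuple[int, int]] = set()
    # Dense regime: enumerate and draw without replacement for exactness.
    if allowed_pair is None and max_pairs <= 2_000_000:
        pool = [
            (i, j)
            for i in range(n)
            for j in range(n)
            if (self_loops or i != j) and (i, j) not in forbidden
        ]
        if m > len(pool):
            raise ConfigError(f"cannot place {m} edges among {len(pool)} allowed pairs")
        idx = rng.choice(len(pool), size=m, replace=False)
        return [pool[i] for i in sorted(idx)]
    # Sparse regime: rejection sampling.
    guard = 0
    while len(chosen) < m:
        guard += 1
        if guard > 1000 * (m + 10):
            raise ConfigError("edge sampling failed; parameters too dense")
        i = int(rng.integers(n))
        j = int(rng.integers(n))
        if not self_loops and i == j:
            continue
        if (i, j) in forbidden or (i, j) in chosen:
            continue
        if allowed_pair is not None and not allowed_pair(i, j):
            continue
        chosen.add((i, j))
    return sorted(chosen)


def _powerlaw_degrees(
    rng: np.random.Generator, n: int, exponent: float, kmax: int
) -> np.ndarray:
    ks = np.arange(1, kmax + 1, dtype=float)
    probs = ks ** (-exponent)
    probs /= probs.sum()
    return rng.choice(np.arange(1, kmax + 1), size=n, p=probs)


def generate_topology(spec: GenerationSpec) -> RegulatoryNetwork:
    """Draw the wiring of a random network; functions are left unset."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    names = _node_names(n)
    regs: dict[str, list[str]] = {name: [] for name in names}

    if spec.topology == "fixed-indegree":
        if spec.k is None:
            raise ConfigError("fixed-indegree requires k")
        k = int(spec.k)
        cap = n if spec.self_loops else n - 1
        if k > cap:
            raise ConfigError(f"in-degree {k} impossible with {n} nodes")
        for i, name in enumerate(names):
            pool = [j for j in range(n) if spec.self_loops or j != i]
            chosen = rng.choice(len(pool), size=k, replace=False)
            regs[name] = [names[pool[j]] for j in sorted(chosen)]

    elif spec.topology == "erdos-renyi":
        m = spec.edge_target()
        pairs = _sample_directed_pairs(rng, n, m, spec.self_loops)
        for i, j in pairs:
            regs[names[j]].append(names[i])

    elif spec.topology == "barabasi-preferential":
        attach = max(1, int(round(spec.k)) if spec.k is not None else 2)
        if n <= attach:
            raise ConfigError("barabasi-preferential requires n_nodes > attachment m")
        g = nx.barabasi_albert_graph(n, attach, seed=int(rng.integers(2**31)))
        for u, v in sorted(g.edges()):
            # orient each undirected edge uniformly at random
            if rng.random() < 0.5:
                u, v = v, u
            regs[names[v]].append(names[u])

    elif spec.topology == "power-law":
        kmax = n if spec.self_loops else n - 1
        if kmax < 1:
            raise ConfigError("power-law needs at least 2 nodes")
        degs = _powerlaw_degrees(rng, n, spec.exponent, kmax)
        for i, name in enumerate(names):
            pool = [j for j in range(n) if spec.self_loops or j != i]
            chosen = rng.choice(len(pool), size=int(degs[i]), replace=False)
            regs[name] = [names[pool[j]] for j in sorted(chosen)]

    elif spec.topology == "watts-strogatz":
        if spec.ws_k >= n:
            raise ConfigError("watts-strogatz lattice degree must be < n_nodes")
        g = nx.watts_strogatz_graph(
            n, spec.ws_k, spec.ws_p, seed=int(rng.integers(2**31))
        )
        # both orientations: p=0 yields the directed ring lattice exactly
        for u, v in sorted(g.edges()):
            regs[names[v]].append(names[u])
            regs[names[u]].append(names[v])

    for name in names:
        regs[name] = sorted(set(regs[name]), key=names.index)
    return _pairs_to_net(n, names, regs)


# ---------------------------------------------------------------------------
# Function generation
# ---------------------------------------------------------------------------

def _bias_table(rng: np.random.Generator, k: int, bias: float) -> tuple[int, ...]:
    return tuple(int(b) for b in (rng.random(1 << k) < bias).astype(int))


def _canalyzing_table(
    rng: np.random.Generator, inputs: tuple[str, ...], bias: float
) -> BooleanFunction:
    k = len(inputs)
    if k == 0:
        log.warning("canalyzing function requested for a 0-input node; using constant")
        return BooleanFunction.constant(int(rng.random() < bias))
    can_pos = int(rng.integers(k))
    can_val = int(rng.integers(2))
    can_out = int(rng.integers(2))
    table = list(_bias_table(rng, k, bias))
    for row in range(1 << k):
        if (row >> (k - 1 - can_pos)) & 1 == can_val:
            table[row] = can_out
    return BooleanFunction(inputs=inputs, table=tuple(table))


def canalyzing_inhibitor(
    inputs: tuple[str, ...], inhibitor: str, rng=None, bias: float = 0.5
) -> BooleanFunction:
    """Canalyzing inhibitory rule: when the inhibitor is active (1) the
    output is forced to 0; remaining rows are filled bias-randomly.

    Models repressors such as miRNAs acting on their target genes.
    """
    if inhibitor not in inputs:
        raise NetworkError(f"{inhibitor!r} is not among the inputs")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    k = len(inputs)
    pos = inputs.index(inhibitor)
    table = list(_bias_table(rng, k, bias))
    for row in range(1 << k):
        if (row >> (k - 1 - pos)) & 1 == 1:
            table[row] = 0
    return BooleanFunction(inputs=tuple(inputs), table=tuple(table))


def _random_expression(
    rng: np.random.Generator, inputs: tuple[str, ...], p_not: float = 0.3
) -> str:
    """Random AND/OR/NOT formula in which every regulator appears once."""
    if len(inputs) == 0:
        return str(int(rng.integers(2)))
    leaves = list(inputs)
    rng.shuffle(leaves)
    terms = [
        f"NOT {name}" if rng.random() < p_not else name for name in leaves
    ]
    while len(terms) > 1:
        b = terms.pop()
        a = terms.pop()
        op = "AND" if rng.random() < 0.5 else "OR"
        combined = f"({a} {op} {b})"
        if rng.random() < p_not:
            combined = f"NOT {combined}"
        terms.append(combined)
    return terms[0]


def generate_functions(
    net: RegulatoryNetwork,
    scheme: str = "bias-random",
    bias: float = 0.5,
    seed: int | None = None,
    only_nodes: set[str] | None = None,
) -> RegulatoryNetwork:
    """Assign random update rules to a wired network.

    ``only_nodes`` restricts assignment (used by augmentation to leave core
    functions alone); other nodes keep their existing function.
    """
    if scheme not in FUNCTION_SCHEMES:
        raise ConfigError(f"unknown function scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    functions: dict[str, BooleanFunction | None] = dict(net.functions)
    for name in net.nodes:
        if only_nodes is not None and name not in only_nodes:
            continue
        inputs = net.regulators_of(name)
        if scheme == "bias-random":
            functions[name] = BooleanFunction(
                inputs=inputs, table=_bias_table(rng, len(inputs), bias)
            )
        elif scheme == "canalyzing":
            functions[name] = _canalyzing_table(rng, inputs, bias)
        else:  # logic
            expr = _random_expression(rng, inputs)
            functions[name] = BooleanFunction.from_expression(expr, inputs=inputs)
    return replace(
        net,
        functions=functions,
        core_flags=dict(net.core_flags),
        clamps=dict(net.clamps),
        topology_only_inputs={},
    )


def generate_network(spec: GenerationSpec) -> RegulatoryNetwork:
    """One fully specified random network (topology + functions)."""
    ss = np.random.SeedSequence(spec.seed)
    topo_seed, fn_seed = ss.spawn(2)
    topo = generate_topology(replace(spec, seed=topo_seed.generate_state(1)[0] % 2**31))
    return generate_functions(
        topo, spec.function_scheme, spec.bias, seed=fn_seed.generate_state(1)[0] % 2**31
    )


def generate_ensemble(
    spec: GenerationSpec, count: int | None = None, seed: int | None = None
) -> list[RegulatoryNetwork]:
    """``count`` independent networks with per-network seeds derived from the
    master seed, so the ensemble is reproducible as a whole."""
    count = count if count is not None else spec.ensemble_size
    if count < 1:
        raise ConfigError("ensemble count must be >= 1")
    master = np.random.SeedSequence(seed if seed is not None else spec.seed)
    nets = []
    for child in master.spawn(count):
        sub = int(child.generate_state(1)[0] % 2**31)
        nets.append(generate_network(replace(spec, seed=sub)))
    return nets


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _extend_core_function(
    f: BooleanFunction,
    new_inputs: list[str],
    policy: str,
    bias: float,
    rng: np.random.Generator,
) -> BooleanFunction:
    """Extend a core function that gained regulators.

    New inputs are appended after the original ones (least significant
    bits), so row ``orig_row * 2^j + new_row`` replicates the original table
    at ``new_row = 0``.
    """
    j = len(new_inputs)
    if j == 0:
        return f
    inputs = f.inputs + tuple(new_inputs)
    table = []
    for orig_row in range(1 << f.arity):
        for new_row in range(1 << j):
            if new_row == 0 or policy == "silent":
                table.append(f.table[orig_row])
            else:
                table.append(int(rng.random() < bias))
    return BooleanFunction(inputs=inputs, table=tuple(table))


def augment(core: RegulatoryNetwork, spec: AugmentationSpec) -> RegulatoryNetwork:
    """Grow ``core`` to exactly ``spec.n_nodes`` nodes and ``spec.m_edges``
    edges; every core node, edge and function is preserved (functions up to
    the input-extension policy)."""
    n0, m0 = core.n_nodes, core.n_edges
    if spec.n_nodes < n0 or spec.m_edges < m0:
        raise ConfigError(
            f"target size ({spec.n_nodes} nodes, {spec.m_edges} edges) smaller "
            f"than core ({n0} nodes, {m0} edges)"
        )
    if spec.n_nodes == n0 and spec.m_edges == m0:
        return replace(
            core,
            functions=dict(core.functions),
            core_flags={n: True for n in core.nodes},
            clamps=dict(core.clamps),
            topology_only_inputs=dict(core.topology_only_inputs),
        )
    rng = np.random.default_rng(spec.seed)
    n_new = spec.n_nodes - n0
    existing = set(core.nodes)
    width = len(str(max(spec.n_nodes - 1, 1)))
    new_names = []
    i = 0
    while len(new_names) < n_new:
        cand = f"x{i:0{width}d}"
        if cand not in existing:
            new_names.append(cand)
        i += 1
    names = list(core.nodes) + new_names
    index = {name: k for k, name in enumerate(names)}
    n = len(names)
    core_idx = set(range(n0))
    current: set[tuple[int, int]] = {
        (index[u], index[v]) for u, v in core.edges()
    }
    m_add = spec.m_edges - m0

    def allowed(i: int, j: int) -> bool:
        if i == j:
            return False
        if i in core_idx and j in core_idx:
            return False  # never rewire the core itself
        if spec.protect_core_inputs and j in core_idx:
            return False
        return True

    if spec.topology == "erdos-renyi":
        new_pairs = _sample_directed_pairs(
            rng, n, m_add, self_loops=False, forbidden=current, allowed_pair=allowed
        )
    elif spec.topology == "fixed-indegree":
        k = int(spec.k) if spec.k is not None else max(1, m_add // max(n_new, 1))
        new_pairs = []
        chosen: set[tuple[int, int]] = set()
        for j_name in new_names:
            j = index[j_name]
            pool = [i for i in range(n) if allowed(i, j)]
            take = min(k, len(pool))
            picks = rng.choice(len(pool), size=take, replace=False)
            for p in sorted(picks):
                chosen.add((pool[p], j))
        rest = m_add - len(chosen)
        if rest < 0:
            raise ConfigError("fixed-indegree augmentation overshoots edge target")
        if rest > 0:
            extra = _sample_directed_pairs(
                rng, n, rest, self_loops=False,
                forbidden=current | chosen, allowed_pair=allowed,
            )
            chosen.update(extra)
        new_pairs = sorted(chosen)
    elif spec.topology == "barabasi-preferential":
        # attach proportionally to current total degree
        chosen = set()
        deg = np.zeros(n, dtype=float)
        for i, j in current:
            deg[i] += 1
            deg[j] += 1
        deg += 1.0
        guard = 0
        while len(chosen) < m_add:
            guard += 1
            if guard > 1000 * (m_add + 10):
                raise ConfigError("preferential augmentation failed to place edges")
            j = index[new_names[int(rng.integers(n_new))]] if rng.random() < 0.5 else int(
                rng.integers(n)
            )
            probs = deg / deg.sum()
            i = int(rng.choice(n, p=probs))
            if not allowed(i, j) or (i, j) in current or (i, j) in chosen:
                continue
            chosen.add((i, j))
            deg[i] += 1
            deg[j] += 1
        new_pairs = sorted(chosen)
    elif spec.topology == "power-law":
        degs = _powerlaw_degrees(rng, n_new, spec.exponent, max(n - 1, 1))
        chosen = set()
        for pos, j_name in enumerate(new_names):
            j = index[j_name]
            pool = [i for i in range(n) if allowed(i, j)]
            take = min(int(degs[pos]), len(pool))
            picks = rng.choice(len(pool), size=take, replace=False)
            for p in sorted(picks):
                chosen.add((pool[p], j))
        # trim or top up to hit the exact edge budget
        chosen_list = sorted(chosen)
        if len(chosen_list) > m_add:
            keep = rng.choice(len(chosen_list), size=m_add, replace=False)
            chosen = {chosen_list[i] for i in sorted(keep)}
        elif len(chosen_list) < m_add:
            extra = _sample_directed_pairs(
                rng, n, m_add - len(chosen_list), self_loops=False,
                forbidden=current | chosen, allowed_pair=allowed,
            )
            chosen.update(extra)
        new_pairs = sorted(chosen)
    else:  # watts-strogatz: ring lattice over the new nodes, then top up
        chosen = set()
        if n_new >= 3:
            for pos, j_name in enumerate(new_names):
                j = index[j_name]
                left = index[new_names[(pos - 1) % n_new]]
                right = index[new_names[(pos + 1) % n_new]]
                for i in (left, right):
                    if allowed(i, j) and len(chosen) < m_add:
                        chosen.add((i, j))
        if len(chosen) < m_add:
            extra = _sample_directed_pairs(
                rng, n, m_add - len(chosen), self_loops=False,
                forbidden=current | chosen, allowed_pair=allowed,
            )
            chosen.update(extra)
        new_pairs = sorted(chosen)

    # assemble regulator lists
    regs: dict[str, list[str]] = {name: [] for name in names}
    for name in core.nodes:
        regs[name] = list(core.regulators_of(name))
    gained: dict[str, list[str]] = {}
    for i, j in new_pairs:
        src, dst = names[i], names[j]
        regs[dst].append(src)
        if j < n0:
            gained.setdefault(dst, []).append(src)

    functions: dict[str, BooleanFunction | None] = {}
    for name in core.nodes:
        f = core.functions[name]
        if f is not None and name in gained:
            functions[name] = _extend_core_function(
                f, gained[name], spec.core_extension_policy, spec.bias, rng
            )
        else:
            functions[name] = f
    for name in new_names:
        functions[name] = None

    out = RegulatoryNetwork(
        nodes=tuple(names),
        functions=functions,
        core_flags={name: (name in existing) for name in names},
        clamps=dict(core.clamps),
        topology_only_inputs={name: tuple(regs[name]) for name in new_names},
    )
    fn_seed = int(rng.integers(2**31))
    out = generate_functions(
        out, spec.function_scheme, spec.bias, seed=fn_seed, only_nodes=set(new_names)
    )
    assert out.n_nodes == spec.n_nodes and out.n_edges == spec.m_edges
    return out


def augment_ensemble(
    core: RegulatoryNetwork,
    spec: AugmentationSpec,
    count: int,
    seed: int | None = None,
) -> list[RegulatoryNetwork]:
    """``count`` augmented networks sharing the core, differing in the
    randomly generated portion; reproducible from the master seed."""
    if count < 1:
        raise ConfigError("ensemble count must be >= 1")
    master = np.random.SeedSequence(seed if seed is not None else spec.seed)
    nets = []
    for child in master.spawn(count):
        sub = int(child.generate_state(1)[0] % 2**31)
        nets.append(augment(core, replace(spec, seed=sub)))
    return nets
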