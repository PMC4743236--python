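"""Boolean network data model and synchronous update semantics.

A gene regulatory network is modelled as a directed graph of binary genes.
Each gene carries a Boolean function of its regulators; the whole network is
updated synchronously and deterministically, so every trajectory eventually
closes on a state cycle (an attractor).

Conventions fixed here and relied on by the file formats and the dynamics
layer:

* Truth tables are indexed with the *first-listed* regulator as the most
  significant bit: for regulators ``(a, b)`` the row order is
  ``(0,0), (0,1), (1,0), (1,1)``.
* Network states are bit vectors ordered as ``net.nodes``; the integer
  encoding likewise puts the first node in the most significant position,
  so lexicographic order on bit vectors equals numeric order on codes.
* Clamps (knock-out/knock-in overrides) replace a node's next value after
  every update; the wild-type function is kept and recoverable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "BooleanFunction",
    "RegulatoryNetwork",
    "CompiledNetwork",
    "Trajectory",
    "state_to_int",
    "int_to_state",
    "as_state",
    "trajectory",
]

# Node names: alphanumerics plus _ . - (e.g. "PLCg-a").
NAME_RE = re.compile(r"^[A-Za-z0-9_.\-]+$")
_KEYWORDS = {"AND", "OR", "NOT"}


class NetworkError(ValueError):
    """Inconsistent network definition or invalid input."""


# ---------------------------------------------------------------------------
# Boolean functions
# ---------------------------------------------------------------------------

def _tokenize(expr: str) -> list[str]:
    tokens = re.findall(r"\(|\)|[A-Za-z0-9_.\-]+", expr)
    if "".join(tokens).replace("(", "").replace(")", "") != re.sub(r"[\s()]", "", expr):
        raise NetworkError(f"unparseable characters in expression: {expr!r}")
    return tokens


class _ExprParser:
    """Recursive-descent parser for AND/OR/NOT formulas.

    Grammar (OR binds loosest):
        expr   := term (OR term)*
        term   := factor (AND factor)*
        factor := NOT factor | '(' expr ')' | name | '0' | '1'
    """

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise NetworkError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            raise NetworkError(f"trailing tokens in expression at {self.peek()!r}")
        return node

    def expr(self):
        node = self.term()
        while self.peek() is not None and self.peek().upper() == "OR":
            self.take()
            node = ("or", node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek() is not None and self.peek().upper() == "AND":
            self.take()
            node = ("and", node, self.factor())
        return node

    def factor(self):
        tok = self.take()
        if tok.upper() == "NOT":
            return ("not", self.factor())
        if tok == "(":
            node = self.expr()
            if self.take() != ")":
                raise NetworkError("unbalanced parentheses")
            return node
        if tok in ("0", "1"):
            return ("const", int(tok))
        if tok == ")" or tok.upper() in _KEYWORDS:
            raise NetworkError(f"unexpected token {tok!r}")
        if not NAME_RE.match(tok):
            raise NetworkError(f"invalid name {tok!r}")
        return ("var", tok)


def _expr_vars(ast, acc: list[str]) -> None:
    kind = ast[0]
    if kind == "var":
        if ast[1] not in acc:
            acc.append(ast[1])
    elif kind == "not":
        _expr_vars(ast[1], acc)
    elif kind in ("and", "or"):
        _expr_vars(ast[1], acc)
        _expr_vars(ast[2], acc)


def _expr_eval(ast, env: Mapping[str, int]) -> int:
    kind = ast[0]
    if kind == "var":
        return env[ast[1]]
    if kind == "const":
        return ast[1]
    if kind == "not":
        return 1 - _expr_eval(ast[1], env)
    if kind == "and":
        return _expr_eval(ast[1], env) & _expr_eval(ast[2], env)
    return _expr_eval(ast[1], env) | _expr_eval(ast[2], env)


@dataclass(frozen=True)
class BooleanFunction:
    """One gene's update rule: a truth table over an ordered regulator list.

    ``table[i]`` is the output for the input combination whose binary
    expansion (first regulator = most significant bit) equals ``i``.
    ``expression`` is kept when the function was written in AND/OR/NOT form;
    the compiled table is always authoritative for evaluation.
    """

    inputs: tuple[str, ...]
    table: tuple[int, ...]
    expression: str | None = None

    def __post_init__(self):
        if len(set(self.inputs)) != len(self.inputs):
            raise NetworkError(f"duplicate regulator in {self.inputs}")
        if len(self.table) != 1 << len(self.inputs):
            raise NetworkError(
                f"table length {len(self.table)} != 2^{len(self.inputs)}"
            )
        if any(b not in (0, 1) for b in self.table):
            raise NetworkError("table entries must be 0/1")

    @property
    def arity(self) -> int:
        return len(self.inputs)

    @property
    def form(self) -> str:
        return "logic-expression" if self.expression is not None else "table"

    @property
    def bias(self) -> float:
        """Fraction of 1-outputs in the truth table."""
        return float(sum(self.table)) / len(self.table)

    @staticmethod
    def row_index(values: Sequence[int]) -> int:
        idx = 0
        for v in values:
            idx = (idx << 1) | int(v)
        return idx

    def evaluate(self, values: Sequence[int]) -> int:
        if len(values) != self.arity:
            raise NetworkError(
                f"expected {self.arity} regulator values, got {len(values)}"
            )
        return self.table[self.row_index(values)]

    __call__ = evaluate

    @classmethod
    def constant(cls, value: int) -> "BooleanFunction":
        return cls(inputs=(), table=(int(value),))

    @classmethod
    def from_table(
        cls, inputs: Iterable[str], table: Iterable[int]
    ) -> "BooleanFunction":
        return cls(inputs=tuple(inputs), table=tuple(int(b) for b in table))

    @classmethod
    def from_expression(
        cls, expression: str, inputs: Sequence[str] | None = None
    ) -> "BooleanFunction":
        """Compile an AND/OR/NOT formula into a truth table.

        When ``inputs`` is omitted, regulators are taken in order of first
        appearance in the formula.
        """
        ast = _ExprParser(_tokenize(expression)).parse()
        seen: list[str] = []
        _expr_vars(ast, seen)
        if inputs is None:
            inputs = seen
        else:
            missing = set(seen) - set(inputs)
            if missing:
                raise NetworkError(
                    f"expression uses regulators not in the input list: {sorted(missing)}"
                )
        inputs = tuple(inputs)
        k = len(inputs)
        table = []
        for row in range(1 << k):
            env = {
                name: (row >> (k - 1 - i)) & 1 for i, name in enumerate(inputs)
            }
            table.append(_expr_eval(ast, env))
        return cls(inputs=inputs, table=tuple(table), expression=expression)


# ---------------------------------------------------------------------------
# Network states
# ---------------------------------------------------------------------------

def state_to_int(bits: Sequence[int]) -> int:
    """Encode a bit vector as an integer, first node = most significant bit."""
    code = 0
    for b in bits:
        code = (code << 1) | int(b)
    return code


def int_to_state(code: int, n: int) -> np.ndarray:
    """Decode an integer state code into a uint8 bit vector of length n."""
    if code < 0 or code >= (1 << n):
        raise NetworkError(f"state code {code} out of range for {n} nodes")
    return np.array([(code >> (n - 1 - i)) & 1 for i in range(n)], dtype=np.uint8)


def as_state(obj, n: int) -> np.ndarray:
    """Coerce an int code or a bit sequence into a validated uint8 vector."""
    if isinstance(obj, (int, np.integer)):
        return int_to_state(int(obj), n)
    arr = np.asarray(obj, dtype=np.uint8)
    if arr.shape != (n,):
        raise NetworkError(f"state has shape {arr.shape}, expected ({n},)")
    if arr.max(initial=0) > 1:
        raise NetworkError("state bits must be 0/1")
    return arr


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

@dataclass
class RegulatoryNetwork:
    """Directed Boolean network: nodes, per-node functions, optional clamps.

    ``functions[name]`` may be ``None`` for topology-only imports (e.g. SIF);
    such networks cannot be simulated until every function is set.
    ``core_flags`` marks nodes that belong to an imported core, for
    augmentation bookkeeping.  ``clamps`` force a node's value to 0/1 at
    every step regardless of its function (knock-out / knock-in).
    """

    nodes: tuple[str, ...]
    functions: dict[str, BooleanFunction | None]
    core_flags: dict[str, bool] = field(default_factory=dict)
    clamps: dict[str, int] = field(default_factory=dict)
    topology_only_inputs: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = tuple(self.nodes)
        if len(self.nodes) < 1:
            raise NetworkError("a network needs at least one node")
        if len(set(self.nodes)) != len(self.nodes):
            raise NetworkError("duplicate node names")
        for name in self.nodes:
            if not NAME_RE.match(name):
                raise NetworkError(f"invalid node name {name!r}")
        if set(self.functions) != set(self.nodes):
            raise NetworkError("functions must be keyed exactly by the node set")
        node_set = set(self.nodes)
        for name, f in self.functions.items():
            regs = f.inputs if f is not None else self.topology_only_inputs.get(name, ())
            unknown = set(regs) - node_set
            if unknown:
                raise NetworkError(
                    f"function of {name!r} references unknown regulators {sorted(unknown)}"
                )
        for name, v in self.clamps.items():
            if name not in node_set:
                raise NetworkError(f"clamp on unknown node {name!r}")
            if v not in (0, 1):
                raise NetworkError(f"clamp value for {name!r} must be 0/1")
        self.core_flags = {n: bool(self.core_flags.get(n, False)) for n in self.nodes}

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def fully_specified(self) -> bool:
        return all(f is not None for f in self.functions.values())

    def regulators_of(self, node: str) -> tuple[str, ...]:
        f = self.functions[node]
        if f is not None:
            return f.inputs
        return self.topology_only_inputs.get(node, ())

    def edges(self) -> list[tuple[str, str]]:
        """Directed edges (regulator, target) in canonical order."""
        out = []
        for target in self.nodes:
            for reg in self.regulators_of(target):
                out.append((reg, target))
        return out

    @property
    def n_edges(self) -> int:
        return sum(len(self.regulators_of(n)) for n in self.nodes)

    def in_degrees(self) -> dict[str, int]:
        return {n: len(self.regulators_of(n)) for n in self.nodes}

    @property
    def core_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self.core_flags[n])

    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    # -- derived networks --------------------------------------------------

    def with_clamps(self, clamps: Mapping[str, int]) -> "RegulatoryNetwork":
        """A copy with additional clamp overrides (functions shared)."""
        merged = dict(self.clamps)
        merged.update({k: int(v) for k, v in clamps.items()})
        return replace(
            self,
            functions=dict(self.functions),
            core_flags=dict(self.core_flags),
            clamps=merged,
            topology_only_inputs=dict(self.topology_only_inputs),
        )

    def without_clamps(self) -> "RegulatoryNetwork":
        return replace(
            self,
            functions=dict(self.functions),
            core_flags=dict(self.core_flags),
            clamps={},
            topology_only_inputs=dict(self.topology_only_inputs),
        )

    # -- dynamics (convenience; hot paths use CompiledNetwork) -------------

    def compiled(self) -> "CompiledNetwork":
        return CompiledNetwork(self)

    def step(self, state) -> np.ndarray:
        return self.compiled().step(as_state(state, self.n_nodes))


class CompiledNetwork:
    """Vectorised synchronous stepper for a fully specified network.

    The per-node truth tables are concatenated into one flat array and the
    regulator wiring into a sparse weight matrix whose row-sums compute each
    node's table row index in a single sparse mat-vec, so one synchronous
    step is O(edges) in numpy rather than a Python loop over nodes.
    """

    def __init__(self, net: RegulatoryNetwork):
        if not net.fully_specified:
            raise NetworkError("cannot simulate a topology-only network")
        self.net = net
        self.n = net.n_nodes
        index = net.node_index()
        rows: list[int] = []
        cols: list[int] = []
        data: list[int] = []
        offsets = np.zeros(self.n, dtype=np.int64)
        flat: list[int] = []
        for i, name in enumerate(net.nodes):
            f = net.functions[name]
            k = f.arity
            for pos, reg in enumerate(f.inputs):
                rows.append(i)
                cols.append(index[reg])
                data.append(1 << (k - 1 - pos))
            offsets[i] = len(flat)
            flat.extend(f.table)
        self._weights = sp.csr_matrix(
            (data, (rows, cols)), shape=(self.n, self.n), dtype=np.int64
        )
        self._offsets = offsets
        self._table = np.array(flat, dtype=np.uint8)
        if net.clamps:
            self._clamp_idx = np.array(
                [index[n] for n in net.nodes if n in net.clamps], dtype=np.intp
            )
            self._clamp_val = np.array(
                [net.clamps[n] for n in net.nodes if n in net.clamps], dtype=np.uint8
            )
        else:
            self._clamp_idx = None
            self._clamp_val = None

    def step(self, state: np.ndarray) -> np.ndarray:
        idx = self._weights.dot(state.astype(np.int64, copy=False))
        out = self._table[self._offsets + idx]
        if self._clamp_idx is not None:
            out[self._clamp_idx] = self._clamp_val
        return out

    def step_with_override(
        self, state: np.ndarray, node_idx: int, value: int
    ) -> np.ndarray:
        """One synchronous step with one node's next value forced."""
        out = self.step(state)
        out[node_idx] = value
        return out

    @staticmethod
    def key(state: np.ndarray) -> bytes:
        return state.tobytes()

    def encode(self, state: np.ndarray) -> int:
        return state_to_int(state)

    def decode(self, code: int) -> np.ndarray:
        return int_to_state(code, self.n)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """An iterated synchronous orbit, possibly closed on a revisited state.

    ``states`` holds the visited states including the start; when
    ``closed``, the final state equals ``states[cycle_start]`` and the cycle
    is ``states[cycle_start:-1]``.
    """

    states: list[np.ndarray]
    closed: bool
    cycle_start: int | None

    @property
    def cycle(self) -> list[np.ndarray]:
        if not self.closed:
            raise NetworkError("trajectory did not close on a cycle")
        return self.states[self.cycle_start : -1]


def trajectory(net: RegulatoryNetwork, s0, max_steps: int) -> Trajectory:
    """Iterate the synchronous dynamics from ``s0`` for at most ``max_steps``.

    Stops as soon as a previously visited state recurs.  Non-closure within
    the cut-off is reported via the ``closed`` flag, not an exception.
    """
    if max_steps < 1:
        raise NetworkError("max_steps must be >= 1")
    cn = net.compiled()
    s = as_state(s0, net.n_nodes)
    seen: dict[bytes, int] = {}
    states = [s]
    for _ in range(max_steps):
        seen[cn.key(s)] = len(states) - 1
        s = cn.step(s)
        states.append(s)
        pos = seen.get(cn.key(s))
        if pos is not None:
            return Trajectory(states=states, closed=True, cycle_start=pos)
    return Trajectory(states=states, closed=False, cycle_start=None)
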