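"""Readers and writers for networks, trees and analysis artifacts.

Network text format (documented, round-trip tested; one network per file)::

    nodes 3
    node a core
    node b augmented
    node c augmented
    fn a b,c table 0001
    fn b - table 1
    fn c expr a AND NOT b

* ``node <name> core|augmented`` declares a node and its core flag.
* ``fn <name> <reg1,reg2,...> table <bits>`` gives a truth table whose
  rows are ordered with the first-listed regulator as the most significant
  bit; ``-`` denotes an empty regulator list (a constant gene).
* ``fn <name> expr <formula>`` gives an AND/OR/NOT formula; regulators are
  taken in order of first appearance.
* lines starting with ``#`` are comments.

Export-only writers produce SIF edge lists (``<source> regulates
<target>``) and GraphML for external graph viewers.  Target differentiation
trees are read/written as tab-separated parent->child edge lists with a
declared root, or as (topology-only) Newick.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx

from .model import BooleanFunction, NetworkError, RegulatoryNetwork
from .tes import DifferentiationTree, TreeNode

__all__ = [
    "read_network",
    "write_network",
    "network_to_text",
    "read_sif",
    "write_sif",
    "write_graphml",
    "read_tree",
    "write_tree",
    "tree_to_newick",
    "read_newick",
    "ParseError",
]

log = logging.getLogger(__name__)


class ParseError(NetworkError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


# ---------------------------------------------------------------------------
# Network text format
# ---------------------------------------------------------------------------

def network_to_text(net: RegulatoryNetwork) -> str:
    """Canonical textual form (stable ordering, byte-reproducible)."""
    lines = [f"nodes {net.n_nodes}"]
    for name in net.nodes:
        flag = "core" if net.core_flags.get(name) else "augmented"
        lines.append(f"node {name} {flag}")
    for name in net.nodes:
        f = net.functions[name]
        if f is None:
            regs = ",".join(net.regulators_of(name)) or "-"
            lines.append(f"fn {name} {regs} table ?")
        elif f.expression is not None:
            lines.append(f"fn {name} expr {f.expression}")
        else:
            regs = ",".join(f.inputs) or "-"
            bits = "".join(str(b) for b in f.table)
            lines.append(f"fn {name} {regs} table {bits}")
    return "\n".join(lines) + "\n"


def write_network(net: RegulatoryNetwork, path) -> None:
    Path(path).write_text(network_to_text(net))


def _parse_network_text(text: str) -> RegulatoryNetwork:
    nodes: list[str] = []
    core: dict[str, bool] = {}
    functions: dict[str, BooleanFunction | None] = {}
    topo_inputs: dict[str, tuple[str, ...]] = {}
    declared_n: int | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        kind = parts[0]
        if kind == "nodes":
            if len(parts) != 2 or not parts[1].isdigit():
                raise ParseError("expected 'nodes <N>'", lineno)
            declared_n = int(parts[1])
        elif kind == "node":
            if len(parts) != 3 or parts[2] not in ("core", "augmented"):
                raise ParseError("expected 'node <name> core|augmented'", lineno)
            nodes.append(parts[1])
            core[parts[1]] = parts[2] == "core"
            functions.setdefault(parts[1], None)
        elif kind == "fn":
            if len(parts) < 4:
                raise ParseError("truncated fn line", lineno)
            name = parts[1]
            if name not in core:
                raise ParseError(f"fn for undeclared node {name!r}", lineno)
            if parts[2] == "expr":
                expr = line.split(None, 3)[3]
                try:
                    functions[name] = BooleanFunction.from_expression(expr)
                except NetworkError as e:
                    raise ParseError(str(e), lineno) from e
            else:
                regs = () if parts[2] == "-" else tuple(parts[2].split(","))
                if parts[3] != "table" or len(parts) != 5:
                    raise ParseError(
                        "expected 'fn <name> <regs> table <bits>'", lineno
                    )
                bits = parts[4]
                if bits == "?":
                    topo_inputs[name] = regs
                    continue
                if set(bits) - {"0", "1"}:
                    raise ParseError("table must be a 0/1 bitstring", lineno)
                if len(bits) != 1 << len(regs):
                    raise ParseError(
                        f"table length {len(bits)} != 2^{len(regs)}", lineno
                    )
                try:
                    functions[name] = BooleanFunction.from_table(regs, map(int, bits))
                except NetworkError as e:
                    raise ParseError(str(e), lineno) from e
        else:
            raise ParseError(f"unknown directive {kind!r}", lineno)
    if declared_n is not None and declared_n != len(nodes):
        raise ParseError(
            f"header declares {declared_n} nodes but {len(nodes)} were defined"
        )
    try:
        return RegulatoryNetwork(
            nodes=tuple(nodes),
            functions=functions,
            core_flags=core,
            topology_only_inputs=topo_inputs,
        )
    except NetworkError as e:
        raise ParseError(str(e)) from e


def read_network(path) -> RegulatoryNetwork:
    path = Path(path)
    if path.suffix.lower() in (".sbml", ".xml"):
        raise NotImplementedError(
            "SBML Qual import/export is not supported yet; "
            "use the documented plain-text network format"
        )
    return _parse_network_text(path.read_text())


# ---------------------------------------------------------------------------
# SIF and GraphML (topology only)
# ---------------------------------------------------------------------------

def write_sif(net: RegulatoryNetwork, path) -> None:
    lines = [f"{src}\tregulates\t{dst}" for src, dst in net.edges()]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_sif(path) -> RegulatoryNetwork:
    """Topology-only import; functions are flagged unset."""
    nodes: list[str] = []
    regs: dict[str, list[str]] = {}

    def ensure(name: str) -> None:
        if name not in regs:
            nodes.append(name)
            regs[name] = []

    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 3:
            raise ParseError("expected '<source> <relation> <target>'", lineno)
        src, _, dst = parts
        ensure(src)
        ensure(dst)
        if src not in regs[dst]:
            regs[dst].append(src)
    if not nodes:
        raise ParseError("empty SIF file")
    return RegulatoryNetwork(
        nodes=tuple(nodes),
        functions={n: None for n in nodes},
        topology_only_inputs={n: tuple(regs[n]) for n in nodes},
    )


def write_graphml(net: RegulatoryNetwork, path) -> None:
    g = nx.DiGraph()
    for name in net.nodes:
        g.add_node(
            name,
            core=bool(net.core_flags.get(name, False)),
            bias=(net.functions[name].bias if net.functions[name] else -1.0),
        )
    g.add_edges_from(net.edges())
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Trees: TSV edge lists and Newick
# ---------------------------------------------------------------------------

def write_tree(tree: DifferentiationTree, path) -> None:
    """Tab-separated parent->child edge list with a declared root."""
    lines = []

    def label(node: TreeNode, idx: dict) -> str:
        if node.label:
            return node.label
        if id(node) not in idx:
            idx[id(node)] = f"n{len(idx)}"
        return idx[id(node)]

    idx: dict = {}
    lines.append(f"root\t{label(tree.root, idx)}")
    stack = [tree.root]
    while stack:
        node = stack.pop(0)
        for child in node.children:
            lines.append(f"{label(node, idx)}\t{label(child, idx)}")
            stack.append(child)
    Path(path).write_text("\n".join(lines) + "\n")


def read_tree(path) -> DifferentiationTree:
    """Read a parent->child TSV tree (first line may declare the root)."""
    edges: list[tuple[str, str]] = []
    declared_root: str | None = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ParseError("expected '<parent>\\t<child>'", lineno)
        if parts[0] == "root" and declared_root is None and not edges:
            declared_root = parts[1]
            continue
        edges.append((parts[0], parts[1]))
    return _tree_from_edges(edges, declared_root)


def _tree_from_edges(
    edges: list[tuple[str, str]], declared_root: str | None
) -> DifferentiationTree:
    children: dict[str, list[str]] = {}
    parents: dict[str, str] = {}
    names: list[str] = []
    for p, c in edges:
        for n in (p, c):
            if n not in children:
                children[n] = []
                names.append(n)
        if c in parents:
            raise ParseError(f"node {c!r} has multiple parents")
        parents[c] = p
        children[p].append(c)
    if declared_root is not None and declared_root not in children:
        children[declared_root] = []
        names.append(declared_root)
    roots = [n for n in names if n not in parents]
    if declared_root is not None:
        if declared_root in parents:
            raise ParseError(f"declared root {declared_root!r} has a parent")
        roots = [declared_root]
    if len(roots) != 1:
        raise ParseError(f"expected exactly one root, found {roots}")
    # cycle check: all nodes must be reachable from the root
    def build(name: str, seen: set[str]) -> TreeNode:
        if name in seen:
            raise ParseError(f"cycle detected at {name!r}")
        seen.add(name)
        return TreeNode(
            label=name, children=[build(c, seen) for c in children[name]]
        )

    seen: set[str] = set()
    root = build(roots[0], seen)
    if len(seen) != len(names):
        raise ParseError("tree contains nodes unreachable from the root")
    return DifferentiationTree(root=root)


def _escape_newick(label: str | None) -> str:
    if not label:
        return ""
    if any(ch in label for ch in " (),:;'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def tree_to_newick(tree: DifferentiationTree) -> str:
    def rec(node: TreeNode) -> str:
        lab = _escape_newick(node.label)
        if not node.children:
            return lab
        return "(" + ",".join(rec(c) for c in node.children) + ")" + lab

    return rec(tree.root) + ";"


def read_newick(source: str | Path) -> DifferentiationTree:
    """Parse a (topology-only) Newick string or file into a tree; branch
    lengths are ignored, labels kept where present."""
    text = str(source)
    p = Path(text) if len(text) < 4096 else None
    if p is not None and p.exists():
        text = p.read_text()
    text = text.strip()
    if not text.endswith(";"):
        raise ParseError("Newick input must end with ';'")
    pos = 0

    def parse_label() -> str | None:
        nonlocal pos
        if pos < len(text) and text[pos] == "'":
            pos += 1
            out = []
            while pos < len(text):
                if text[pos] == "'":
                    if pos + 1 < len(text) and text[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    break
                out.append(text[pos])
                pos += 1
            label = "".join(out)
        else:
            start = pos
            while pos < len(text) and text[pos] not in "(),:;":
                pos += 1
            label = text[start:pos].strip()
        if pos < len(text) and text[pos] == ":":  # skip branch length
            pos += 1
            while pos < len(text) and text[pos] not in "(),;":
                pos += 1
        return label or None

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(text):
                    raise ParseError("unbalanced parentheses in Newick")
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise ParseError(f"unexpected character {text[pos]!r} in Newick")
        node.label = parse_label()
        return node

    root = parse_node()
    if pos >= len(text) or text[pos] != ";":
        raise ParseError("trailing content in Newick input")
    return DifferentiationTree(root=root)
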