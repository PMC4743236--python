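"""Built-in worked-example inputs.

Two first-class fixtures ship with the package:

* a *synthetic* 40-gene / 51-interaction core network — an Erdos-Renyi
  wired, bias-0.5 Boolean network regenerated deterministically from a
  fixed seed.  It matches the published T-helper signalling core in size
  only (that network's wiring is not reproduced here); it exists so the
  augmentation/selection protocol can be exercised end to end without
  external data.
* the hematopoietic differentiation tree: MPP splitting into the myeloid
  (CMP -> MEP/GMP -> EC, MK, M, N/E/B) and lymphoid (CLP -> B PROG,
  T/NK PROG -> B, T, NK) lineages.  The MEP->{EC,MK} and GMP->{M,N/E/B}
  parent assignment follows the standard hematopoiesis scheme
  (curator-supplied).

Checked-in copies under ``nrbnkit/data`` are byte-stable regenerations of
these objects.
"""

from __future__ import annotations

from importlib import resources

from .generate import GenerationSpec, generate_network
from .model import RegulatoryNetwork
from .netio import _parse_network_text, _tree_from_edges
from .tes import DifferentiationTree

__all__ = [
    "synthetic_core",
    "synthetic_core_from_data",
    "hematopoietic_tree",
    "HEMATOPOIETIC_EDGES",
    "SYNTHETIC_CORE_SEED",
]

SYNTHETIC_CORE_SEED = 51040  # fixed once; regenerations are byte-identical

#: Parent -> child edges of the hematopoietic differentiation scheme.
HEMATOPOIETIC_EDGES: tuple[tuple[str, str], ...] = (
    ("MPP", "CMP"),
    ("MPP", "CLP"),
    ("CMP", "MEP"),
    ("CMP", "GMP"),
    ("MEP", "EC"),
    ("MEP", "MK"),
    ("GMP", "M"),
    ("GMP", "N-E-B"),
    ("CLP", "B_PROG"),
    ("CLP", "T-NK_PROG"),
    ("B_PROG", "B"),
    ("T-NK_PROG", "T"),
    ("T-NK_PROG", "NK"),
)


def synthetic_core(seed: int = SYNTHETIC_CORE_SEED) -> RegulatoryNetwork:
    """Regenerate the synthetic 40-gene / 51-edge core from its seed.

    All nodes are flagged as core so augmentation bookkeeping treats the
    whole network as the imported portion.
    """
    net = generate_network(
        GenerationSpec(
            n_nodes=40,
            topology="erdos-renyi",
            m_edges=51,
            function_scheme="bias-random",
            bias=0.5,
            seed=seed,
        )
    )
    net.core_flags = {n: True for n in net.nodes}
    return net


def synthetic_core_from_data() -> RegulatoryNetwork:
    """The checked-in copy of the synthetic core (byte-stable)."""
    text = (
        resources.files("nrbnkit") / "data" / "synthetic_core_40x51.net"
    ).read_text()
    return _parse_network_text(text)


def hematopoietic_tree() -> DifferentiationTree:
    """The 14-node hematopoietic differentiation tree (depth 4, root MPP)."""
    return _tree_from_edges(list(HEMATOPOIETIC_EDGES), declared_root="MPP")
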