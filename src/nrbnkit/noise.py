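"""Flip perturbations and the Attractor Transition Matrix (ATM/ATN).

Biological noise is modelled as *flips*: a single node's activation value
is inverted and held at the inverted value for a fixed number of
synchronous steps, after which the deterministic dynamics resumes.  Flipping
every node in every phase (cycle state) of every attractor and recording
where the system relaxes yields a row-stochastic matrix of noise-induced
attractor-to-attractor transition probabilities — the stability matrix that
the Threshold Ergodic Set analysis thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import Attractor, AttractorAtlas, AttractorEngine
from .model import NetworkError, RegulatoryNetwork, as_state

__all__ = ["FlipSpec", "AttractorTransitionMatrix", "apply_flip", "build_atm"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FlipSpec:
    """Flip-experiment protocol.

    ``duration``: steps the inverted value is held (default 1).
    ``targets``: node names to flip, or None for all nodes.
    ``phases``: cycle states per attractor to perturb, or None for all.
    Sampling targets/phases is intended for large networks; the default is
    the exact all-phases x all-nodes enumeration.
    """

    duration: int = 1
    targets: tuple[str, ...] | None = None
    phases: int | None = None

    def __post_init__(self):
        if self.duration < 1:
            raise NetworkError("flip duration must be >= 1")
        if self.phases is not None and self.phases < 1:
            raise NetworkError("phase sample count must be >= 1")


@dataclass
class AttractorTransitionMatrix:
    """Counts and row-normalised probabilities of flip-induced transitions.

    Rows/columns follow ``attractors`` (the atlas ordering, extended with
    any attractors first reached through a flip when extension is enabled).
    ``unresolved[a]`` counts experiments from attractor ``a`` that did not
    relax within the step budget.
    """

    attractors: list[Attractor]
    counts: np.ndarray
    unresolved: np.ndarray
    flip: FlipSpec
    n_atlas: int  # attractors that came from the original atlas

    @property
    def n(self) -> int:
        return len(self.attractors)

    @property
    def probs(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(totals > 0, self.counts / totals, 0.0)
        return p

    def to_frame(self, probabilities: bool = True) -> pd.DataFrame:
        labels = [f"A{a.id}" for a in self.attractors]
        data = self.probs if probabilities else self.counts
        return pd.DataFrame(data, index=labels, columns=labels)

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Weighted ATN edges (source id, target id, probability > 0)."""
        p = self.probs
        out = []
        for i in range(self.n):
            for j in range(self.n):
                if p[i, j] > 0:
                    out.append((i, j, float(p[i, j])))
        return out


def apply_flip(
    net: RegulatoryNetwork, state, node: str, duration: int = 1
) -> np.ndarray:
    """Invert ``node`` and hold the inverted value for ``duration``
    synchronous steps while every other node updates normally; returns the
    state at release time."""
    if node not in net.functions:
        raise NetworkError(f"unknown node {node!r}")
    cn = net.compiled()
    s = as_state(state, net.n_nodes)
    idx = net.node_index()[node]
    return _apply_flip_compiled(cn, s, idx, duration)


def _apply_flip_compiled(cn, state: np.ndarray, node_idx: int, duration: int):
    held = 1 - int(state[node_idx])
    s = state
    for _ in range(duration):
        s = cn.step_with_override(s, node_idx, held)
    return s


def build_atm(
    net: RegulatoryNetwork,
    atlas: AttractorAtlas,
    flip: FlipSpec = FlipSpec(),
    max_steps: int = 1000,
    seed: int | None = None,
    extend_atlas: bool = True,
    max_new_attractors: int = 200,
) -> AttractorTransitionMatrix:
    """Run the flip protocol over an atlas and tally the destinations.

    For every attractor, every selected phase state and every target node,
    the node is flipped (held inverted for ``flip.duration`` steps) and the
    released state is relaxed with the same semantics as attractor search.
    Destinations outside the atlas are either appended as genuinely new
    attractors (default, with a warning — sampled atlases are incomplete by
    construction) or counted as unresolved when ``extend_atlas=False``.
    Newly appended attractors get flip rows of their own so the matrix stays
    square and row-stochastic.
    """
    if len(atlas) == 0:
        raise NetworkError("cannot build an ATM from an empty atlas")
    if atlas.n_nodes != net.n_nodes:
        raise NetworkError("atlas was not computed on this network")
    rng = np.random.default_rng(seed)
    engine = AttractorEngine(net, max_steps=max_steps)
    engine.seed_attractors(atlas.attractors)
    n_atlas = len(atlas)

    index = net.node_index()
    if flip.targets is None:
        target_idx = list(range(net.n_nodes))
    else:
        unknown = [t for t in flip.targets if t not in index]
        if unknown:
            raise NetworkError(f"unknown flip targets {unknown}")
        target_idx = [index[t] for t in flip.targets]

    rows: list[dict[int, int]] = []
    unresolved: list[int] = []
    attractors: list[Attractor] = list(atlas.attractors)
    new_warned = False

    a = 0
    while a < len(attractors):
        att = attractors[a]
        phases = att.state_matrix()
        if flip.phases is not None and flip.phases < att.length:
            pick = rng.choice(att.length, size=flip.phases, replace=False)
            phases = phases[np.sort(pick)]
        tally: dict[int, int] = {}
        miss = 0
        for phase in phases:
            for ni in target_idx:
                released = _apply_flip_compiled(engine.cn, phase, ni, flip.duration)
                dest = engine.relax(released)
                if dest is None:
                    miss += 1
                    continue
                if dest >= len(attractors):
                    # the flip reached an attractor absent from the atlas
                    if (not extend_atlas) or (
                        len(attractors) - n_atlas >= max_new_attractors
                    ):
                        miss += 1
                        continue
                    if not new_warned:
                        log.warning(
                            "flip protocol reached attractors absent from the "
                            "atlas; extending (sampled atlases are incomplete)"
                        )
                        new_warned = True
                    while len(attractors) <= dest:
                        canonical = engine.attractors[len(attractors)]
                        attractors.append(
                            Attractor(
                                states=canonical,
                                n_nodes=net.n_nodes,
                                basin_size=0,
                                id=len(attractors),
                            )
                        )
                tally[dest] = tally.get(dest, 0) + 1
        rows.append(tally)
        unresolved.append(miss)
        a += 1

    m = len(attractors)
    counts = np.zeros((m, m), dtype=np.int64)
    for i, tally in enumerate(rows):
        for j, c in tally.items():
            if j < m:
                counts[i, j] = c
    return AttractorTransitionMatrix(
        attractors=attractors,
        counts=counts,
        unresolved=np.array(unresolved, dtype=np.int64),
        flip=flip,
        n_atlas=n_atlas,
    )
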