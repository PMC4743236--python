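"""Attractor discovery and attractor-level statistics.

Under synchronous deterministic updating every trajectory ends in a state
cycle.  This module finds those cycles either exhaustively (all 2^N initial
states, small N) or by uniform sampling of initial conditions, assigns each
resolved initial state to its attractor (basins), and summarises lengths,
reachability and frozen/oscillating node proportions.

Attractors are canonicalised by rotating the cycle so that it starts at the
lexicographically smallest state (equivalently, the smallest integer code
with the first node as the most significant bit); atlases are sorted by
(length, canonical states) so ids are stable across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import (
    CompiledNetwork,
    NetworkError,
    RegulatoryNetwork,
    state_to_int,
)

__all__ = [
    "Attractor",
    "AttractorAtlas",
    "AttractorEngine",
    "find_attractors",
    "canonicalize",
    "attractor_statistics",
]

log = logging.getLogger(__name__)

EXHAUSTIVE_CAP = 20  # default upper N for exhaustive search


@dataclass(frozen=True)
class Attractor:
    """A canonicalised state cycle.

    ``states`` are the integer-encoded cycle states in dynamical order,
    rotated to start at the smallest code.  ``basin_size`` counts the
    initial states (all of them in exhaustive mode, sampled draws otherwise)
    whose trajectory relaxed here.
    """

    states: tuple[int, ...]
    n_nodes: int
    basin_size: int = 0
    id: int = -1

    @property
    def length(self) -> int:
        return len(self.states)

    def state_matrix(self) -> np.ndarray:
        """Cycle as a (length, N) uint8 matrix, rows in dynamical order."""
        n = self.n_nodes
        return np.array(
            [[(code >> (n - 1 - i)) & 1 for i in range(n)] for code in self.states],
            dtype=np.uint8,
        )

    def frozen_mask(self) -> np.ndarray:
        """Boolean vector: node value constant across the whole cycle."""
        m = self.state_matrix()
        return (m == m[0]).all(axis=0)


@dataclass
class AttractorAtlas:
    """The attractor set found for one network plus discovery bookkeeping."""

    attractors: list[Attractor]
    mode: str  # "exhaustive" | "sampled"
    n_initial_states: int
    max_steps: int
    unresolved_count: int = 0
    seed: int | None = None
    n_nodes: int = 0

    def __len__(self) -> int:
        return len(self.attractors)

    def basin_total(self) -> int:
        return sum(a.basin_size for a in self.attractors)


def canonicalize(cycle) -> tuple[int, ...]:
    """Canonical rotation of a closed orbit: start at the smallest encoded
    state.  Accepts a list of bit vectors or of integer codes."""
    if len(cycle) == 0:
        raise NetworkError("empty cycle")
    codes = [
        int(c) if isinstance(c, (int, np.integer)) else state_to_int(c) for c in cycle
    ]
    if len(set(codes)) != len(codes):
        raise NetworkError("cycle states are not pairwise distinct")
    k = codes.index(min(codes))
    return tuple(codes[k:] + codes[:k])


class AttractorEngine:
    """Shared-cache relaxation machinery.

    Every state ever visited on a resolved trajectory is mapped to its
    attractor index, so later relaxations stop as soon as they touch any
    previously seen state.  The same engine serves attractor search and the
    flip-perturbation protocol (which must relax thousands of released
    states on the same network).
    """

    def __init__(self, net: RegulatoryNetwork, max_steps: int = 1000):
        self.net = net
        self.cn = CompiledNetwork(net)
        self.max_steps = max_steps
        self.cache: dict[bytes, int] = {}
        self.attractors: list[tuple[int, ...]] = []  # canonical code tuples
        self._canon_index: dict[tuple[int, ...], int] = {}

    def register_cycle(self, canonical: tuple[int, ...]) -> int:
        idx = self._canon_index.get(canonical)
        if idx is not None:
            return idx
        idx = len(self.attractors)
        self.attractors.append(canonical)
        self._canon_index[canonical] = idx
        for code in canonical:
            self.cache[self.cn.decode(code).tobytes()] = idx
        return idx

    def seed_attractors(self, attractors: list[Attractor]) -> None:
        for a in attractors:
            self.register_cycle(tuple(a.states))

    def relax(self, state: np.ndarray) -> int | None:
        """Run the deterministic dynamics until a known state or a new cycle
        is reached; returns the attractor index, or None if the trajectory
        did not resolve within max_steps."""
        cn = self.cn
        s = state
        path_keys: list[bytes] = []
        path_pos: dict[bytes, int] = {}
        path_states: list[np.ndarray] = []
        for _ in range(self.max_steps + 1):
            key = cn.key(s)
            hit = self.cache.get(key)
            if hit is not None:
                for k in path_keys:
                    self.cache[k] = hit
                return hit
            pos = path_pos.get(key)
            if pos is not None:
                cycle = [state_to_int(x) for x in path_states[pos:]]
                idx = self.register_cycle(canonicalize(cycle))
                for k in path_keys:
                    self.cache[k] = idx
                return idx
            path_pos[key] = len(path_keys)
            path_keys.append(key)
            path_states.append(s)
            s = cn.step(s)
        return None


def _sample_initial_states(
    rng: np.random.Generator, n: int, n_samples: int, replace: bool
) -> np.ndarray:
    """Uniform initial conditions as an (n_samples, n) uint8 matrix.

    With-replacement draws fill the matrix row-major from the bit stream,
    so a longer run extends a shorter one with the same seed (monotone
    discovery).  Without replacement is available for small N only.
    """
    if replace:
        return rng.integers(0, 2, size=(n_samples, n), dtype=np.uint8)
    if n > 30:
        raise NetworkError("without-replacement sampling only supported for N <= 30")
    total = 1 << n
    if n_samples > total:
        raise NetworkError("cannot sample more distinct states than exist")
    codes = rng.choice(total, size=n_samples, replace=False)
    return np.array(
        [[(int(c) >> (n - 1 - i)) & 1 for i in range(n)] for c in codes],
        dtype=np.uint8,
    )


def find_attractors(
    net: RegulatoryNetwork,
    mode: str = "sampled",
    n_samples: int | None = None,
    max_steps: int = 1000,
    seed: int | None = None,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
    with_replacement: bool = True,
) -> AttractorAtlas:
    """Discover attractors from exhaustive or uniformly sampled initial
    conditions.

    Trajectories that neither close nor touch a known state within
    ``max_steps`` are counted in ``unresolved_count`` (and logged), never
    silently dropped.
    """
    n = net.n_nodes
    if mode not in ("exhaustive", "sampled"):
        raise NetworkError(f"unknown search mode {mode!r}")
    engine = AttractorEngine(net, max_steps=max_steps)
    basins: dict[int, int] = {}
    unresolved = 0

    if mode == "exhaustive":
        if n > exhaustive_cap:
            raise NetworkError(
                f"exhaustive search refused for N={n} > cap {exhaustive_cap}; "
                "use sampled mode or raise the cap explicitly"
            )
        n_initial = 1 << n
        for code in range(n_initial):
            idx = engine.relax(engine.cn.decode(code))
            if idx is None:
                unresolved += 1
            else:
                basins[idx] = basins.get(idx, 0) + 1
    else:
        if n_samples is None or n_samples < 1:
            raise NetworkError("sampled mode requires n_samples >= 1")
        n_initial = n_samples
        rng = np.random.default_rng(seed)
        samples = _sample_initial_states(rng, n, n_samples, with_replacement)
        for row in samples:
            idx = engine.relax(row)
            if idx is None:
                unresolved += 1
            else:
                basins[idx] = basins.get(idx, 0) + 1

    if unresolved:
        log.warning(
            "%d of %d trajectories did not resolve within %d steps",
            unresolved, n_initial, max_steps,
        )

    order = sorted(
        range(len(engine.attractors)),
        key=lambda i: (len(engine.attractors[i]), engine.attractors[i]),
    )
    attractors = [
        Attractor(
            states=engine.attractors[old],
            n_nodes=n,
            basin_size=basins.get(old, 0),
            id=new,
        )
        for new, old in enumerate(order)
    ]
    return AttractorAtlas(
        attractors=attractors,
        mode=mode,
        n_initial_states=n_initial,
        max_steps=max_steps,
        unresolved_count=unresolved,
        seed=seed,
        n_nodes=n,
    )


def attractor_statistics(atlas: AttractorAtlas) -> dict:
    """Summary of an atlas: count, length histogram, basins, reachability
    and frozen-node proportions.

    A node is *frozen* in an attractor iff its value is constant across the
    cycle; otherwise it oscillates.  Reachability is the basin fraction of
    the resolved initial states.
    """
    if len(atlas) == 0:
        raise NetworkError("empty atlas")
    lengths: dict[int, int] = {}
    for a in atlas.attractors:
        lengths[a.length] = lengths.get(a.length, 0) + 1
    resolved = atlas.basin_total()
    frozen = {
        a.id: float(a.frozen_mask().mean()) for a in atlas.attractors
    }
    return {
        "n_attractors": len(atlas),
        "length_histogram": dict(sorted(lengths.items())),
        "basin_sizes": {a.id: a.basin_size for a in atlas.attractors},
        "reachability": {
            a.id: (a.basin_size / resolved if resolved else float("nan"))
            for a in atlas.attractors
        },
        "frozen_proportion": frozen,
        "mean_frozen_proportion": float(np.mean(list(frozen.values()))),
        "unresolved_count": atlas.unresolved_count,
    }
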