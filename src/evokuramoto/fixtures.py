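"""Synthetic test inputs: connectome-like graphs, order-parameter traces, states.

``synth_connectome`` produces a random weighted, directed graph whose
structural census matches the published tally of the C. elegans chemical
connectome exactly — 300 nodes, 38 self-loops, 669 bidirectional edge pairs,
2,331 unpaired edges (3,707 directed edges in total) and 5 dangling nodes —
while everything else (which nodes connect, the weight values) is random.
It is a synthetic stand-in for the real connectome: census-exact, but not
claimed to reproduce its degree or weight distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import InteractionGraph
from .moran import PopulationState

__all__ = ["ConnectomeSpec", "TraceSpec", "synth_connectome", "synth_rho_traces",
           "random_state", "max_chimera_traces", "alternating_traces"]


@dataclass(frozen=True)
class ConnectomeSpec:
    """Target census for the connectome-like generator.

    ``weight_mean`` sets the mean of the 1 + geometric integer weight law
    (the real connectome's weight distribution is unpublished; heavy-tailed
    integers with mean ~3 are a generator choice, not biology).
    """

    n_nodes: int = 300
    n_self_loops: int = 38
    n_bidirectional_pairs: int = 669
    n_unpaired: int = 2331
    n_dangling: int = 5
    weight_mean: float = 3.0

    def __post_init__(self):
        n_free = self.n_nodes - self.n_dangling
        if n_free < 2:
            raise ValueError("too many dangling nodes")
        if self.n_self_loops > n_free:
            raise ValueError("more self-loops than non-dangling nodes")
        if self.n_bidirectional_pairs > n_free * (n_free - 1) // 2:
            raise ValueError("too many bidirectional pairs")
        cap = n_free * (self.n_nodes - 1) - 2 * self.n_bidirectional_pairs
        if self.n_unpaired > cap:
            raise ValueError("too many unpaired edges for the node budget")
        if self.weight_mean < 1.0:
            raise ValueError("weight_mean must be >= 1")


def synth_connectome(spec: ConnectomeSpec | None = None,
                     seed: int | np.random.Generator = 0) -> InteractionGraph:
    """Random graph hitting the census of ``spec`` exactly.

    Construction: designate the dangling nodes (they emit nothing — a
    self-loop would make a node its own out-neighbour); scatter self-loops,
    reciprocal pairs and unpaired edges uniformly at random among the rest
    without collisions; then repair any non-dangling node left with
    out-degree 0 by re-sourcing one unpaired edge, which preserves every
    census count.  Weights are i.i.d. 1 + Geometric.
    """
    spec = spec or ConnectomeSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_nodes
    nodes = np.arange(n)
    dangling = set(rng.choice(n, size=spec.n_dangling, replace=False).tolist())
    free = np.array([i for i in nodes if i not in dangling])

    loops = set(rng.choice(free, size=spec.n_self_loops, replace=False).tolist())
    directed: set[tuple[int, int]] = {(u, u) for u in loops}

    pairs: set[tuple[int, int]] = set()
    while len(pairs) < spec.n_bidirectional_pairs:
        u, v = rng.choice(free, size=2, replace=False)
        key = (min(u, v), max(u, v))
        pairs.add(key)
    for u, v in pairs:
        directed.add((u, v))
        directed.add((v, u))

    unpaired: list[tuple[int, int]] = []
    have = set(directed)
    while len(unpaired) < spec.n_unpaired:
        u = int(free[rng.integers(len(free))])
        v = int(rng.integers(n))
        if u == v or (u, v) in have or (v, u) in have:
            continue
        have.add((u, v))
        unpaired.append((u, v))

    # repair: every non-dangling node must emit at least one edge
    out_deg = np.zeros(n, dtype=np.int64)
    for u, v in have:
        out_deg[u] += 1
    needy = [int(i) for i in free if out_deg[i] == 0]
    for x in needy:
        for idx in rng.permutation(len(unpaired)):
            u, v = unpaired[idx]
            if out_deg[u] < 2:
                continue
            # replace (u, v) with an edge out of x, keeping all counts
            for _ in range(10 * n):
                t = int(rng.integers(n))
                if t != x and (x, t) not in have and (t, x) not in have:
                    have.discard((u, v))
                    have.add((x, t))
                    unpaired[idx] = (x, t)
                    out_deg[u] -= 1
                    out_deg[x] += 1
                    break
            else:  # pragma: no cover - astronomically unlikely
                continue
            break
        else:  # pragma: no cover
            raise RuntimeError(f"could not repair out-degree of node {x}")

    edges = sorted(have)
    src = np.array([u for u, _ in edges], dtype=np.int64)
    dst = np.array([v for _, v in edges], dtype=np.int64)
    # geometric on {1, 2, ...} with mean = weight_mean (all-ones if mean is 1)
    if spec.weight_mean > 1.0:
        wts = rng.geometric(1.0 / spec.weight_mean, size=len(edges))
    else:
        wts = np.ones(len(edges), dtype=np.int64)
    return InteractionGraph([f"n{i:03d}" for i in range(n)], src, dst,
                            np.asarray(wts, dtype=np.int64))


@dataclass(frozen=True)
class TraceSpec:
    """Synthetic per-community order-parameter traces.

    ``patterns`` holds one tuple per community: ("constant", v),
    ("alternating", v1, v2) or ("noisy", mean, sd).  Values are clipped to
    [0, 1].
    """

    M: int
    T: int
    patterns: tuple[tuple, ...] = field(default=())

    def __post_init__(self):
        if self.M < 1 or self.T < 1:
            raise ValueError("M and T must be >= 1")
        if self.patterns and len(self.patterns) != self.M:
            raise ValueError("need one pattern per community")


def synth_rho_traces(spec: TraceSpec, seed: int = 0) -> np.ndarray:
    """T x M matrix of order-parameter traces following ``spec``."""
    rng = np.random.default_rng(seed)
    patterns = spec.patterns or tuple(("constant", 1.0) for _ in range(spec.M))
    cols = []
    for pat in patterns:
        kind = pat[0]
        if kind == "constant":
            col = np.full(spec.T, float(pat[1]))
        elif kind == "alternating":
            v1, v2 = float(pat[1]), float(pat[2])
            col = np.where(np.arange(spec.T) % 2 == 0, v1, v2)
        elif kind == "noisy":
            mean, sd = float(pat[1]), float(pat[2])
            col = rng.normal(mean, sd, size=spec.T)
        else:
            raise ValueError(f"unknown trace pattern {kind!r}")
        cols.append(np.clip(col, 0.0, 1.0))
    return np.column_stack(cols)


def max_chimera_traces(T: int = 100, M: int = 6) -> np.ndarray:
    """Half the communities pinned at 1, half at 0 — the maximal-chimera trace."""
    if M % 2:
        raise ValueError("need an even community count")
    spec = TraceSpec(M, T, tuple(("constant", 1.0) for _ in range(M // 2))
                     + tuple(("constant", 0.0) for _ in range(M // 2)))
    return synth_rho_traces(spec)


def alternating_traces(T: int = 10_000, M: int = 6) -> np.ndarray:
    """Every community alternating 0/1 with equal occupancy (T even)."""
    spec = TraceSpec(M, T, tuple(("alternating", 0.0, 1.0) for _ in range(M)))
    return synth_rho_traces(spec)


def random_state(N: int, m: int, seed: int = 0) -> PopulationState:
    """Uniform i.i.d. population state over all 2m strategies, seeded."""
    if N < 1 or m < 1:
        raise ValueError("N and m must be >= 1")
    rng = np.random.default_rng(seed)
    return PopulationState(rng.integers(0, 2, size=N).astype(np.uint8),
                           rng.integers(0, m, size=N), m)
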