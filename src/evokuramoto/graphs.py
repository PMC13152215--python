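"""Weighted, directed interaction and reproduction graphs.

Players sit on the nodes of a directed graph whose integer edge weights count
the number of games played along that edge (for a connectome: the number of
chemical synapses).  Two closely related graphs drive the dynamics:

* the **interaction graph** says *from whom* a node receives payoffs — every
  edge ``tail -> head`` awards its (weight-scaled) game payoff to the head;
* the **reproduction graph** says *to whom* a node can spread its strategy —
  a birth node replaces one of its out-neighbours.

The reproduction graph is the interaction graph with a single weight-1
self-loop added to every dangling node (out-degree 0), so the birth-death
update is always well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionGraph",
    "ReproductionGraph",
    "GraphCensus",
    "load_edge_list",
    "write_edge_list",
    "load_graphml",
    "write_graphml",
    "complete_graph",
    "derive_reproduction_graph",
    "strip_weights",
    "symmetrize",
    "graph_census",
]

Edge = tuple[str, str, int]


@dataclass(frozen=True)
class GraphCensus:
    """Structural tally of a directed graph.

    ``n_bidirectional_pairs`` counts unordered pairs {u, v}, u != v, with
    edges in both directions; ``n_unpaired_edges`` counts non-self-loop edges
    whose reverse is absent; ``n_dangling`` counts nodes with no
    out-neighbours (a self-loop makes a node its own out-neighbour).
    """

    n_nodes: int
    n_self_loops: int
    n_bidirectional_pairs: int
    n_unpaired_edges: int
    n_dangling: int
    total_weight: int

    @property
    def n_edges(self) -> int:
        """Total directed edge count implied by the census identity."""
        return 2 * self.n_bidirectional_pairs + self.n_unpaired_edges + self.n_self_loops


class InteractionGraph:
    """A weighted, directed graph with opaque string node labels.

    Invariants enforced at construction: integer weights >= 1, no parallel
    duplicate (source, target) edges, at least two nodes.  Node order is the
    order of first appearance (explicit ``node_ids`` first), which fixes the
    0-based internal index used by the simulation engine.
    """

    def __init__(
        self,
        node_ids: Sequence[str],
        src: np.ndarray,
        dst: np.ndarray,
        weight: np.ndarray,
        directed: bool = True,
    ):
        self.node_ids: tuple[str, ...] = tuple(str(n) for n in node_ids)
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node ids")
        if len(self.node_ids) < 2:
            raise ValueError(f"graph needs at least 2 nodes, got {len(self.node_ids)}")
        self.src = np.asarray(src, dtype=np.int64)
        self.dst = np.asarray(dst, dtype=np.int64)
        self.weight = np.asarray(weight, dtype=np.int64)
        self.directed = directed
        self._index = {n: i for i, n in enumerate(self.node_ids)}
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int]] | Iterable[tuple[str, str]],
        node_ids: Sequence[str] | None = None,
        directed: bool = True,
        merge_duplicates: bool = False,
    ) -> "InteractionGraph":
        """Build a graph from (source, target[, weight]) label triples.

        Missing weights default to 1.  Duplicate (source, target) rows raise
        unless ``merge_duplicates`` is set, in which case their weights are
        summed and a warning is logged.
        """
        order: list[str] = list(node_ids) if node_ids is not None else []
        seen = set(order)
        merged: dict[tuple[str, str], int] = {}
        n_dup = 0
        for row in edges:
            if len(row) == 2:
                u, v = row  # type: ignore[misc]
                w = 1
            else:
                u, v, w = row  # type: ignore[misc]
            u, v = str(u), str(v)
            for n in (u, v):
                if n not in seen:
                    seen.add(n)
                    order.append(n)
            key = (u, v)
            if key in merged:
                if not merge_duplicates:
                    raise ValueError(f"duplicate edge {key}")
                n_dup += 1
            _check_weight(w, key)
            merged[key] = merged.get(key, 0) + int(w)
        if n_dup:
            logger.warning("merged %d duplicate edge rows by summing weights", n_dup)
        idx = {n: i for i, n in enumerate(order)}
        src = np.array([idx[u] for u, _ in merged], dtype=np.int64)
        dst = np.array([idx[v] for _, v in merged], dtype=np.int64)
        wts = np.array(list(merged.values()), dtype=np.int64)
        return cls(order, src, dst, wts, directed=directed)

    def _validate(self) -> None:
        n = self.n_nodes
        if not (len(self.src) == len(self.dst) == len(self.weight)):
            raise ValueError("edge arrays have mismatched lengths")
        if len(self.src) and (self.src.min() < 0 or self.src.max() >= n):
            raise ValueError("edge source index out of range")
        if len(self.dst) and (self.dst.min() < 0 or self.dst.max() >= n):
            raise ValueError("edge target index out of range")
        if len(self.weight) and self.weight.min() < 1:
            raise ValueError("edge weights must be integers >= 1")
        pairs = set(zip(self.src.tolist(), self.dst.tolist()))
        if len(pairs) != len(self.src):
            raise ValueError("parallel duplicate (source,target) edges are forbidden")

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.src)

    def index_of(self, node: str) -> int:
        return self._index[node]

    def edges(self) -> list[Edge]:
        """Edges as (source_label, target_label, weight) triples."""
        return [
            (self.node_ids[u], self.node_ids[v], int(w))
            for u, v, w in zip(self.src, self.dst, self.weight)
        ]

    def out_degrees(self) -> np.ndarray:
        """Out-degree (edge count, self-loops included) per node index."""
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.src, 1)
        return deg

    def in_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.dst, 1)
        return deg

    # -- transforms --------------------------------------------------------

    def relabel(self, mapping: Mapping[str, str]) -> "InteractionGraph":
        """Rename nodes; the index order is preserved."""
        new_ids = [mapping.get(n, n) for n in self.node_ids]
        return type(self)(new_ids, self.src.copy(), self.dst.copy(), self.weight.copy(),
                          directed=self.directed)

    def copy(self) -> "InteractionGraph":
        return type(self)(self.node_ids, self.src.copy(), self.dst.copy(),
                          self.weight.copy(), directed=self.directed)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<{type(self).__name__} N={self.n_nodes} E={self.n_edges}>"


class ReproductionGraph(InteractionGraph):
    """Interaction graph plus weight-1 self-loops on originally dangling nodes."""

    def __init__(self, *args, added_self_loops: tuple[str, ...] = (), **kwargs):
        super().__init__(*args, **kwargs)
        self.added_self_loops = tuple(added_self_loops)
        if (self.out_degrees() < 1).any():
            raise ValueError("reproduction graph must have out-degree >= 1 everywhere")


def _check_weight(w, key) -> None:
    if isinstance(w, float) and not w.is_integer():
        raise ValueError(f"non-integer weight {w!r} on edge {key}")
    if int(w) < 1:
        raise ValueError(f"non-positive weight {w!r} on edge {key}")


# ---------------------------------------------------------------------------
# File I/O


def load_edge_list(path: str | Path, directed: bool = True) -> InteractionGraph:
    """Read a TSV/CSV edge list with header ``source, target[, weight]``.

    The delimiter is auto-detected from the header (tab preferred, comma
    otherwise).  Duplicate (source, target) rows are merged by summing
    weights, with a logged warning.  Malformed rows raise ``ValueError``
    naming the offending line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty edge-list file")
    header = lines[0]
    sep = "\t" if "\t" in header else ","
    cols = [c.strip().lower() for c in header.split(sep)]
    if cols[:2] != ["source", "target"]:
        raise ValueError(f"{path}: header must start with 'source{sep}target', got {header!r}")
    has_weight = len(cols) > 2 and cols[2] == "weight"
    edges: list[tuple[str, str, int]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in ln.split(sep)]
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise ValueError(f"{path}:{lineno}: malformed row {ln!r}")
        if has_weight and len(parts) > 2 and parts[2]:
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
            if not w.is_integer() or w < 1:
                raise ValueError(
                    f"{path}:{lineno}: weight must be a positive integer, got {parts[2]!r}"
                )
            w = int(w)
        else:
            w = 1
        edges.append((parts[0], parts[1], w))
    if not edges:
        raise ValueError(f"{path}: no edges")
    return InteractionGraph.from_edges(edges, directed=directed, merge_duplicates=True)


def write_edge_list(g: InteractionGraph, path: str | Path, sep: str = "\t") -> None:
    """Write ``source sep target sep weight`` with a header row."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(sep.join(("source", "target", "weight")) + "\n")
        for u, v, w in g.edges():
            fh.write(f"{u}{sep}{v}{sep}{w}\n")


def write_graphml(g: InteractionGraph, path: str | Path) -> None:
    """Export to GraphML with weights on the numeric edge attribute ``weight``."""
    import networkx as nx

    nxg = nx.DiGraph()
    nxg.add_nodes_from(g.node_ids)
    for u, v, w in g.edges():
        nxg.add_edge(u, v, weight=int(w))
    nx.write_graphml(nxg, str(path))


def load_graphml(path: str | Path) -> InteractionGraph:
    """Import a directed GraphML file; missing weights default to 1."""
    import networkx as nx

    nxg = nx.read_graphml(str(path))
    if not nxg.is_directed():
        nxg = nxg.to_directed()
    edges = []
    for u, v, data in nxg.edges(data=True):
        w = data.get("weight", 1)
        if isinstance(w, float) and not w.is_integer():
            raise ValueError(f"non-integer weight {w} on edge ({u}, {v})")
        edges.append((str(u), str(v), int(w)))
    return InteractionGraph.from_edges(
        edges, node_ids=[str(n) for n in nxg.nodes], merge_duplicates=True
    )


# ---------------------------------------------------------------------------
# Generators and transforms


def complete_graph(n: int) -> InteractionGraph:
    """Well-mixed population: every ordered pair of distinct nodes, weight 1."""
    if n < 2:
        raise ValueError(f"complete graph needs N >= 2, got {n}")
    idx = np.arange(n)
    src = np.repeat(idx, n - 1)
    dst = np.concatenate([np.delete(idx, i) for i in range(n)])
    return InteractionGraph([str(i) for i in range(n)], src, dst,
                            np.ones(n * (n - 1), dtype=np.int64))


def derive_reproduction_graph(g: InteractionGraph) -> ReproductionGraph:
    """Copy of ``g`` with a weight-1 self-loop on each dangling node."""
    dangling = np.flatnonzero(g.out_degrees() == 0)
    src = np.concatenate([g.src, dangling])
    dst = np.concatenate([g.dst, dangling])
    wts = np.concatenate([g.weight, np.ones(len(dangling), dtype=np.int64)])
    return ReproductionGraph(
        g.node_ids, src, dst, wts, directed=g.directed,
        added_self_loops=tuple(g.node_ids[i] for i in dangling),
    )


def strip_weights(g: InteractionGraph) -> InteractionGraph:
    """Identical topology with every weight set to 1 (idempotent)."""
    return InteractionGraph(g.node_ids, g.src.copy(), g.dst.copy(),
                            np.ones(g.n_edges, dtype=np.int64), directed=g.directed)


def symmetrize(g: InteractionGraph, combine: str = "sum") -> InteractionGraph:
    """Undirected view encoded as reciprocal directed edge pairs.

    For every unordered pair {u, v} carrying any edge, both directions get
    weight ``combine(w_uv, w_vu)`` where an absent direction counts 0 for
    ``sum`` and is ignored for ``max``/``mean``.  Self-loops keep their
    weight.  Note that with ``sum`` (the default, which preserves the total
    game count) an already-symmetric pair of weight w becomes 2w in each
    direction.
    """
    if combine not in ("sum", "max", "mean"):
        raise ValueError(f"unknown combine rule {combine!r}")
    w_of: dict[tuple[int, int], int] = {
        (int(u), int(v)): int(w) for u, v, w in zip(g.src, g.dst, g.weight)
    }
    loops = {u: w for (u, v), w in w_of.items() if u == v}
    pairs = {(min(u, v), max(u, v)) for (u, v) in w_of if u != v}
    src, dst, wts = [], [], []
    for u, w in sorted(loops.items()):
        src.append(u); dst.append(u); wts.append(w)
    for u, v in sorted(pairs):
        a, b = w_of.get((u, v)), w_of.get((v, u))
        present = [x for x in (a, b) if x is not None]
        if combine == "sum":
            w = (a or 0) + (b or 0)
        elif combine == "max":
            w = max(present)
        else:
            w = max(1, round(sum(present) / len(present)))
        src += [u, v]; dst += [v, u]; wts += [w, w]
    return InteractionGraph(g.node_ids, np.array(src), np.array(dst), np.array(wts),
                            directed=g.directed)


def graph_census(g: InteractionGraph) -> GraphCensus:
    """Count self-loops, bidirectional pairs, unpaired edges and dangling nodes."""
    loops = int((g.src == g.dst).sum())
    nonloop = {(int(u), int(v)) for u, v in zip(g.src, g.dst) if u != v}
    bidir = sum(1 for (u, v) in nonloop if u < v and (v, u) in nonloop)
    unpaired = len(nonloop) - 2 * bidir
    dangling = int((g.out_degrees() == 0).sum())
    return GraphCensus(
        n_nodes=g.n_nodes,
        n_self_loops=loops,
        n_bidirectional_pairs=bidir,
        n_unpaired_edges=unpaired,
        n_dangling=dangling,
        total_weight=int(g.weight.sum()),
    )
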