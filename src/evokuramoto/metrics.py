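"""Synchronization, chimera and game-census metrics.

The global Kuramoto order parameter ``rho = |sum_j exp(i*phi_j)| / N``
measures population coherence.  Splitting the nodes into M disjoint
communities gives per-community order parameters ``rho_m(t)``, from which
two scalar summaries follow:

* the **chimera-like index** ``chi``: time average of the across-community
  sample variance of ``rho_m`` (1/(M-1) normalisation).  It is 0 for
  homogeneous communities and reaches M/[4(M-1)] when half the communities
  are fully coherent and half fully disordered at all times;
* the **metastability index** ``lambda``: community average of the temporal
  sample variance of ``rho_m`` (1/(T-1)).  It is 0 for communities that are
  always coherent or always disordered and approaches 1/4 for communities
  spending equal time at rho_m = 0 and 1 (the sample-variance form attains
  1/4 only in the large-T limit).

Communities come from constant Potts model (CPM) optimisation with the
Leiden algorithm, or from a file for exact reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .games import GameParams, interaction_game_table
from .graphs import InteractionGraph

__all__ = [
    "CommunityAssignment",
    "ChimeraSummary",
    "communicative_fraction",
    "order_parameter",
    "community_order",
    "chimera_index",
    "metastability_index",
    "chimera_summary",
    "game_census",
    "plurality_game",
    "plurality_mixed_game",
    "detect_communities",
]


@dataclass
class CommunityAssignment:
    """Node -> community map as a dense membership array (ids 0..M-1)."""

    membership: np.ndarray

    def __post_init__(self):
        self.membership = np.asarray(self.membership, dtype=np.int64)
        if self.membership.ndim != 1 or len(self.membership) == 0:
            raise ValueError("membership must be a nonempty 1-D array")
        if self.membership.min() < 0:
            raise ValueError("community ids must be non-negative")
        # compact ids so that communities are 0..M-1 with no gaps
        uniq, compact = np.unique(self.membership, return_inverse=True)
        self.membership = compact.astype(np.int64)
        self.M = len(uniq)
        self.sizes = np.bincount(self.membership, minlength=self.M)

    @property
    def n(self) -> int:
        return len(self.membership)

    @classmethod
    def from_file(cls, path: str | Path, node_ids=None) -> "CommunityAssignment":
        """Read a ``node<TAB>community`` TSV (header optional).

        With ``node_ids`` the rows are aligned to that node order and must
        cover it exactly; otherwise file order is used.
        """
        rows: dict[str, int] = {}
        for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'node\\tcommunity'")
            if lineno == 1 and parts[0].strip().lower() == "node":
                continue
            rows[parts[0].strip()] = int(parts[1])
        if node_ids is not None:
            missing = [n for n in node_ids if n not in rows]
            if missing:
                raise ValueError(f"nodes without community assignment: {missing[:5]}")
            return cls(np.array([rows[n] for n in node_ids]))
        return cls(np.array(list(rows.values())))

    def to_file(self, path: str | Path, node_ids=None) -> None:
        ids = node_ids if node_ids is not None else [str(i) for i in range(self.n)]
        with Path(path).open("w") as fh:
            fh.write("node\tcommunity\n")
            for n, c in zip(ids, self.membership):
                fh.write(f"{n}\t{int(c)}\n")


@dataclass(frozen=True)
class ChimeraSummary:
    chi: float
    lam: float
    sigma_chi: np.ndarray  # per-step across-community variance
    sigma_met: np.ndarray  # per-community temporal variance


def communicative_fraction(s) -> float:
    """Fraction of players with the communicative label (phases ignored)."""
    labels = np.asarray(s.labels)
    if labels.size == 0:
        raise ValueError("empty population")
    return float(labels.mean())


def order_parameter(s) -> float:
    """Global coherence rho = |sum_j exp(i*phi_j)| / N in [0, 1]."""
    if s.n == 0:
        raise ValueError("empty population")
    phases = 2.0 * np.pi * s.ks / s.m
    return float(np.abs(np.exp(1j * phases).mean()))


def community_order(s, comm: CommunityAssignment) -> np.ndarray:
    """Per-community order parameter, each with its own community size."""
    if comm.n != s.n:
        raise ValueError("community assignment does not cover the population")
    phases = 2.0 * np.pi * s.ks / s.m
    z = np.exp(1j * phases)
    sums = np.zeros(comm.M, dtype=complex)
    np.add.at(sums, comm.membership, z)
    return np.abs(sums) / comm.sizes


def _as_trace_matrix(rho_m_series: np.ndarray) -> np.ndarray:
    mat = np.asarray(rho_m_series, dtype=float)
    if mat.ndim != 2:
        raise ValueError(f"expected a T x M matrix, got shape {mat.shape}")
    return mat


def chimera_index(rho_m_series: np.ndarray) -> float:
    """Time mean of the across-community sample variance (ddof = 1)."""
    mat = _as_trace_matrix(rho_m_series)
    if mat.shape[1] < 2:
        raise ValueError("chimera index needs at least 2 communities")
    return float(mat.var(axis=1, ddof=1).mean())


def metastability_index(rho_m_series: np.ndarray) -> float:
    """Community mean of the temporal sample variance (ddof = 1)."""
    mat = _as_trace_matrix(rho_m_series)
    if mat.shape[0] < 2:
        raise ValueError("metastability index needs at least 2 time samples")
    return float(mat.var(axis=0, ddof=1).mean())


def chimera_summary(rho_m_series: np.ndarray) -> ChimeraSummary:
    mat = _as_trace_matrix(rho_m_series)
    return ChimeraSummary(
        chi=chimera_index(mat),
        lam=metastability_index(mat),
        sigma_chi=mat.var(axis=1, ddof=1),
        sigma_met=mat.var(axis=0, ddof=1),
    )


# ---------------------------------------------------------------------------
# Game census


def game_census(
    g: InteractionGraph,
    s,
    p: GameParams,
    mixed_only: bool = False,
    tol: float = 1e-9,
) -> dict[str, float]:
    """Weight fraction of each game type over the graph's directed edges.

    Every edge is classified from its endpoint pair (joint-C pairs are
    cooperation games, joint-N pairs neutral games, mixed pairs consult the
    ordinal taxonomy) and accumulates its edge weight.  Fractions are of the
    total weight of the counted edges; with ``mixed_only`` only C/N edges
    are counted (empty dict if there are none).
    """
    names, tab = interaction_game_table(p, tol=tol)
    g_idx = tab[s.labels[g.dst], s.labels[g.src], (s.ks[g.src] - s.ks[g.dst]) % p.m]
    w = g.weight.astype(float)
    if mixed_only:
        mask = s.labels[g.dst] != s.labels[g.src]
        g_idx, w = g_idx[mask], w[mask]
    total = w.sum()
    if total == 0:
        return {}
    wsum = np.bincount(g_idx, weights=w, minlength=len(names))
    return {n: float(ws / total) for n, ws in zip(names, wsum) if ws > 0}


def _plurality(census: dict[str, float]) -> str:
    best = max(census.values())
    return min(n for n, w in census.items() if w == best)


def plurality_game(census: dict[str, float], s) -> str:
    """Heaviest game type; fully-labelled populations short-circuit to
    "all-C"/"all-N".  Exact ties break alphabetically."""
    if s.labels.all():
        return "all-C"
    if not s.labels.any():
        return "all-N"
    return _plurality(census)


def plurality_mixed_game(census_mixed: dict[str, float], s) -> str:
    """As :func:`plurality_game` over mixed C/N edges only; "none" when a
    mixed population has no mixed edge."""
    if s.labels.all():
        return "all-C"
    if not s.labels.any():
        return "all-N"
    if not census_mixed:
        return "none"
    return _plurality(census_mixed)


# ---------------------------------------------------------------------------
# Community detection


def detect_communities(
    g: InteractionGraph,
    resolution: float = 0.1,
    beta: float = 0.01,
    iterations: int = 2,
    seed: int = 0,
) -> CommunityAssignment:
    """Constant Potts model communities via igraph's Leiden implementation.

    Uses ``community_leiden(objective_function="CPM")`` with the given
    resolution, refinement randomness ``beta`` and iteration count.  The
    Leiden backend works on undirected graphs, so directed input is
    collapsed to weighted-undirected with reciprocal weights summed (and
    self-loops dropped).  Seeded for reproducibility; for strict
    backend-version independence persist the assignment with
    :meth:`CommunityAssignment.to_file`.
    """
    import random as _random

    import igraph as ig

    ig.set_random_number_generator(_random.Random(seed))
    edges = [(int(u), int(v)) for u, v in zip(g.src, g.dst) if u != v]
    weights = [float(w) for u, v, w in zip(g.src, g.dst, g.weight) if u != v]
    graph = ig.Graph(n=g.n_nodes, edges=edges, directed=True)
    graph.es["weight"] = weights
    und = graph.as_undirected(combine_edges={"weight": "sum"})
    clustering = und.community_leiden(
        objective_function="CPM",
        weights="weight",
        resolution=resolution,
        beta=beta,
        n_iterations=iterations,
    )
    return CommunityAssignment(np.array(clustering.membership))
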