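"""Birth-death Moran process with exponential fitness on a graph pair.

Each turn: every node's payoff is the weighted sum over its in-edges of the
pairwise game payoffs; a birth node is drawn proportionally to
``exp(delta * total_payoff)``; a death node is drawn among the birth node's
reproduction out-neighbours proportionally to edge weight; the death node
then copies the birth node's strategy, or — with probability mu — receives a
strategy drawn uniformly at random from all 2m strategies (the current one
included).  A node whose only out-edge is its own reproduction self-loop
replaces itself, i.e. it mutates with probability mu and otherwise nothing
changes.

Total (not degree-averaged) payoff feeds fitness, so high in-degree nodes
are favoured under selection.  Selection weights are computed from
payoff differences (shift-invariant softmax), which keeps ``exp`` in range
for any payoff scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .games import GameParams, PhaseStrategy, edge_payoff, interaction_game_table, payoff_table
from .graphs import InteractionGraph, ReproductionGraph

__all__ = [
    "PopulationState",
    "SimulationConfig",
    "MetricsRecord",
    "TimeSeries",
    "total_payoff",
    "fitness",
    "moran_step",
    "run_simulation",
    "MoranEngine",
]


@dataclass
class PopulationState:
    """Strategies of all players: label array (1 = C, 0 = N) and phase indices."""

    labels: np.ndarray  # uint8, 1 = communicative
    ks: np.ndarray      # int64 phase indices in [0, m)
    m: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        self.ks = np.asarray(self.ks, dtype=np.int64)
        if self.labels.shape != self.ks.shape:
            raise ValueError("labels and phase arrays must have equal length")
        if len(self.ks) and (self.ks.min() < 0 or self.ks.max() >= self.m):
            raise ValueError("phase index out of range")

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def from_strategies(cls, strategies: Sequence[PhaseStrategy], m: int) -> "PopulationState":
        labels = np.array([1 if s.label == "C" else 0 for s in strategies], dtype=np.uint8)
        ks = np.array([s.k for s in strategies], dtype=np.int64)
        return cls(labels, ks, m)

    def strategy(self, i: int) -> PhaseStrategy:
        return PhaseStrategy("C" if self.labels[i] else "N", int(self.ks[i]))

    def copy(self) -> "PopulationState":
        return PopulationState(self.labels.copy(), self.ks.copy(), self.m)


@dataclass(frozen=True)
class SimulationConfig:
    """Run configuration.  ``sample_every`` matches the usual 800-step plotting
    decimation; ``burn_in`` samples are excluded from the record."""

    params: GameParams
    steps: int
    seed: int
    sample_every: int = 800
    burn_in: int = 0
    snapshot_steps: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


@dataclass(frozen=True)
class MetricsRecord:
    step: int
    f_comm: float
    rho: float
    plurality_game: str
    plurality_mixed_game: str
    rho_m: np.ndarray | None = None


@dataclass
class TimeSeries:
    """Sampled metrics of one run, plus optional full state snapshots."""

    config: SimulationConfig
    records: list[MetricsRecord]
    snapshots: dict[int, PopulationState] = field(default_factory=dict)
    community_sizes: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        base = {
            "step": [r.step for r in self.records],
            "f_comm": [r.f_comm for r in self.records],
            "rho": [r.rho for r in self.records],
            "plurality_game": [r.plurality_game for r in self.records],
            "plurality_mixed_game": [r.plurality_mixed_game for r in self.records],
        }
        if self.records and self.records[0].rho_m is not None:
            mat = np.vstack([r.rho_m for r in self.records])
            for mcol in range(mat.shape[1]):
                base[f"rho_m{mcol + 1}"] = mat[:, mcol]
        return pd.DataFrame(base)

    def rho_m_matrix(self) -> np.ndarray:
        """T x M matrix of community order parameters (requires communities)."""
        if not self.records or self.records[0].rho_m is None:
            raise ValueError("run was recorded without community assignments")
        return np.vstack([r.rho_m for r in self.records])

    def write_tsv(self, path_or_file) -> None:
        """Audit-headed TSV: ``# key=value`` config block, then the records."""
        p = self.config.params
        head = {
            "B0": p.B0, "beta0": p.beta0, "c": p.c, "alpha": p.alpha,
            "delta": p.delta, "mu": p.mu, "m": p.m, "cc_coupling": p.cc_coupling,
            "steps": self.config.steps, "seed": self.config.seed,
            "sample_every": self.config.sample_every, "burn_in": self.config.burn_in,
        }

        def _emit(fh):
            for k, v in head.items():
                fh.write(f"# {k}={v}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, lineterminator="\n")

        if hasattr(path_or_file, "write"):
            _emit(path_or_file)
        else:
            with Path(path_or_file).open("w") as fh:
                _emit(fh)


# ---------------------------------------------------------------------------
# Reference payoff/fitness definitions (the engine must agree with these)


def total_payoff(g: InteractionGraph, s: PopulationState, p: GameParams, node: int) -> float:
    """Payoff of ``node``: sum over in-edges (tail -> node) of w * edge payoff.

    A self-loop contributes its weight times the same-label, zero-phase-
    difference payoff.  This is the plain-definition implementation used as
    the consistency oracle for the engine's incremental bookkeeping.
    """
    mask = g.dst == node
    head = s.strategy(node)
    out = 0.0
    for tail, w in zip(g.src[mask], g.weight[mask]):
        out += float(w) * edge_payoff(head, s.strategy(int(tail)), p)
    return out


def fitness(payoff: float, delta: float) -> float:
    """Exponential fitness exp(delta * payoff)."""
    return float(np.exp(delta * payoff))


# ---------------------------------------------------------------------------
# Engine


class _BufferedRng:
    """Blocks of uniforms from one seeded Generator; cheap scalar draws."""

    def __init__(self, rng: np.random.Generator, block: int = 8192):
        self._rng = rng
        self._block = block
        self._buf = rng.random(block)
        self._i = 0

    def random(self) -> float:
        if self._i >= self._block:
            self._buf = self._rng.random(self._block)
            self._i = 0
        v = self._buf[self._i]
        self._i += 1
        return v


class MoranEngine:
    """Stateful simulator holding incremental payoffs and cached fitness.

    Payoffs are maintained incrementally: when the death node's state
    changes, its own payoff is recomputed from its in-edges and each
    downstream head's payoff is adjusted by the payoff delta of the single
    affected edge.  The cumulative-fitness vector is cached between state
    changes, so the long monomorphic stretches of the rare-mutation regime
    cost only a couple of uniform draws per step.
    """

    def __init__(
        self,
        gi: InteractionGraph,
        gr: ReproductionGraph,
        params: GameParams,
        state: PopulationState,
        rng: np.random.Generator,
    ):
        if gi.n_nodes != gr.n_nodes or gi.node_ids != gr.node_ids:
            raise ValueError("interaction and reproduction graphs must share nodes")
        if state.n != gi.n_nodes:
            raise ValueError("state length must equal node count")
        if state.m != params.m:
            raise ValueError("state phase count must match params.m")
        self.gi = gi
        self.gr = gr
        self.p = params
        self.state = state
        self.rng = rng
        self._u = _BufferedRng(rng)
        self.m = params.m
        self.n = gi.n_nodes
        self.ptable = payoff_table(params)

        # in-adjacency of the interaction graph (for full recompute of one node)
        order_in = np.argsort(gi.dst, kind="stable")
        self._in_src = gi.src[order_in]
        self._in_w = gi.weight[order_in].astype(float)
        self._in_ptr = np.searchsorted(gi.dst[order_in], np.arange(self.n + 1))
        # out-adjacency of the interaction graph (for downstream payoff deltas)
        order_out = np.argsort(gi.src, kind="stable")
        self._out_dst = gi.dst[order_out]
        self._out_w = gi.weight[order_out].astype(float)
        self._out_ptr = np.searchsorted(gi.src[order_out], np.arange(self.n + 1))
        # reproduction out-neighbour lists with cumulative weights
        order_r = np.argsort(gr.src, kind="stable")
        rdst = gr.dst[order_r]
        rw = gr.weight[order_r].astype(float)
        rptr = np.searchsorted(gr.src[order_r], np.arange(self.n + 1))
        self._repro_nbrs = [rdst[rptr[i]:rptr[i + 1]] for i in range(self.n)]
        self._repro_cum = [np.cumsum(rw[rptr[i]:rptr[i + 1]]) for i in range(self.n)]
        for i, nbrs in enumerate(self._repro_nbrs):
            if len(nbrs) == 0:
                raise ValueError(f"node {i} has no reproduction out-neighbours")

        self.payoffs = self.full_payoffs()
        self._cum_fitness: np.ndarray | None = None

    # -- payoffs -----------------------------------------------------------

    def full_payoffs(self) -> np.ndarray:
        """Recompute every node's payoff from scratch (vectorized)."""
        s = self.state
        gi = self.gi
        pays = self.ptable[
            s.labels[gi.dst], s.labels[gi.src], (s.ks[gi.src] - s.ks[gi.dst]) % self.m
        ] * gi.weight
        out = np.zeros(self.n)
        np.add.at(out, gi.dst, pays)
        return out

    def _node_payoff(self, i: int) -> float:
        s = self.state
        lo, hi = self._in_ptr[i], self._in_ptr[i + 1]
        tails = self._in_src[lo:hi]
        return float(np.dot(
            self._in_w[lo:hi],
            self.ptable[s.labels[i], s.labels[tails], (s.ks[tails] - s.ks[i]) % self.m],
        ))

    def payoff_drift(self) -> float:
        """Max |incremental - from-scratch| payoff; consistency diagnostic."""
        return float(np.max(np.abs(self.payoffs - self.full_payoffs())))

    def _apply(self, d: int, new_label: int, new_k: int) -> None:
        s = self.state
        old_label, old_k = int(s.labels[d]), int(s.ks[d])
        lo, hi = self._out_ptr[d], self._out_ptr[d + 1]
        heads = self._out_dst[lo:hi]
        w = self._out_w[lo:hi]
        hl = s.labels[heads]
        hk = s.ks[heads]
        delta = w * (
            self.ptable[hl, new_label, (new_k - hk) % self.m]
            - self.ptable[hl, old_label, (old_k - hk) % self.m]
        )
        keep = heads != d  # d's own payoff is recomputed in full below
        np.add.at(self.payoffs, heads[keep], delta[keep])
        s.labels[d] = new_label
        s.ks[d] = new_k
        self.payoffs[d] = self._node_payoff(d)
        self._cum_fitness = None

    # -- stepping ----------------------------------------------------------

    def step(self) -> None:
        """One birth-death-mutation turn (at most one node's state changes)."""
        if self._cum_fitness is None:
            pay = self.payoffs
            if self.p.delta == 0.0:
                w = np.ones(self.n)
            else:
                w = np.exp(self.p.delta * (pay - pay.max()))
            self._cum_fitness = np.cumsum(w)
        cum = self._cum_fitness
        birth = int(np.searchsorted(cum, self._u.random() * cum[-1], side="right"))
        rc = self._repro_cum[birth]
        j = int(np.searchsorted(rc, self._u.random() * rc[-1], side="right"))
        death = int(self._repro_nbrs[birth][j])
        if self._u.random() < self.p.mu:
            new_label = int(self._u.random() * 2)
            new_k = min(int(self._u.random() * self.m), self.m - 1)
        else:
            new_label = int(self.state.labels[birth])
            new_k = int(self.state.ks[birth])
        if new_label != self.state.labels[death] or new_k != self.state.ks[death]:
            self._apply(death, new_label, new_k)

    def run(self, steps: int) -> None:
        for _ in range(steps):
            self.step()


def moran_step(
    gi: InteractionGraph,
    gr: ReproductionGraph,
    s: PopulationState,
    p: GameParams,
    rng: np.random.Generator,
) -> PopulationState:
    """Single functional Moran turn; returns the updated state (copy).

    Convenience wrapper over :class:`MoranEngine` for one-off stepping; long
    runs should use :func:`run_simulation`, which keeps incremental payoffs.
    """
    eng = MoranEngine(gi, gr, p, s.copy(), rng)
    eng.step()
    return eng.state


# ---------------------------------------------------------------------------
# Full runs


def random_initial_state(n: int, m: int, rng: np.random.Generator) -> PopulationState:
    """Independent uniform draw over all 2m strategies for each node."""
    return PopulationState(rng.integers(0, 2, size=n).astype(np.uint8),
                           rng.integers(0, m, size=n), m)


def run_simulation(
    gi: InteractionGraph,
    gr: ReproductionGraph,
    cfg: SimulationConfig,
    communities: np.ndarray | None = None,
    initial_state: PopulationState | None = None,
) -> TimeSeries:
    """Run the seeded Moran process, recording metrics every ``sample_every``.

    Step 0 (the random initial state) is recorded unless excluded by
    ``burn_in``.  Identical inputs and seed give bit-identical output.  If a
    ``communities`` membership array is given, per-community order
    parameters are recorded as well.
    """
    from .metrics import CommunityAssignment, community_order, order_parameter

    p = cfg.params
    rng = np.random.default_rng(cfg.seed)
    state = initial_state.copy() if initial_state is not None else random_initial_state(
        gi.n_nodes, p.m, rng)
    eng = MoranEngine(gi, gr, p, state, rng)
    names, gtable = interaction_game_table(p)
    comm = None
    if communities is not None:
        comm = CommunityAssignment(np.asarray(communities, dtype=np.int64))
        if comm.n != gi.n_nodes:
            raise ValueError("community assignment does not cover the graph")

    edge_w = gi.weight.astype(float)
    snapshot_at = set(cfg.snapshot_steps or ())
    records: list[MetricsRecord] = []
    snapshots: dict[int, PopulationState] = {}

    def _record(step: int) -> None:
        s = eng.state
        f_comm = float(s.labels.mean())
        rho = order_parameter(s)
        rho_m = community_order(s, comm) if comm is not None else None
        g_idx = gtable[s.labels[gi.dst], s.labels[gi.src], (s.ks[gi.src] - s.ks[gi.dst]) % p.m]
        wsum = np.bincount(g_idx, weights=edge_w, minlength=len(names))
        if s.labels.all():
            plur, plur_mixed = "all-C", "all-C"
        elif not s.labels.any():
            plur, plur_mixed = "all-N", "all-N"
        else:
            plur = _argmax_name(names, wsum)
            mixed_mask = s.labels[gi.dst] != s.labels[gi.src]
            if mixed_mask.any():
                wm = np.bincount(g_idx[mixed_mask], weights=edge_w[mixed_mask],
                                 minlength=len(names))
                plur_mixed = _argmax_name(names, wm)
            else:
                plur_mixed = "none"
        records.append(MetricsRecord(step, f_comm, rho, plur, plur_mixed, rho_m))

    if 0 >= cfg.burn_in:
        _record(0)
    if 0 in snapshot_at:
        snapshots[0] = eng.state.copy()
    for step in range(1, cfg.steps + 1):
        eng.step()
        if step % cfg.sample_every == 0 and step >= cfg.burn_in:
            _record(step)
        if step in snapshot_at:
            snapshots[step] = eng.state.copy()

    return TimeSeries(cfg, records, snapshots,
                      community_sizes=comm.sizes if comm is not None else None)


def _argmax_name(names: list[str], weights: np.ndarray) -> str:
    """Heaviest game name; exact ties break alphabetically (deterministic)."""
    best = weights.max()
    return min(n for n, w in zip(names, weights) if w == best)
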