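"""Payoffs and ordinal game-type classification for the evolutionary Kuramoto game.

Each player carries a communicative strategy (``C`` pays a cost c and can earn
phase-dependent benefits, ``N`` pays nothing) and a discrete phase
``phi = 2*pi*k/m``.  A directed edge awards a payoff to its head node that
depends on both endpoint states through the shifted Kuramoto coupling
``f(dphi) = (1 + cos dphi) / 2``:

==============  =======================================
head receives   payoff
==============  =======================================
C from C        B0 * f(dphi) - c
C from N        2*alpha  * beta0 * f(dphi) - c
N from C        2*(1-alpha) * beta0 * f(dphi)
N from N        0
==============  =======================================

The asymmetry ``alpha`` splits the mixed-interaction benefit between the
communicator (factor 2*alpha) and the non-communicator (factor 2*(1-alpha));
alpha = 1/2 recovers the symmetric game with benefit beta0 * f(dphi).

Every pairwise interaction also defines a hypothetical 2x2 "switch" game in
which either player may adopt the other's strategy-and-phase; its four
row-player payoffs, ranked ordinally, name the game type (dilemma, chicken,
staghunt, ...) using the standard topological taxonomy of symmetric 2x2
ordinal games.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "GameParams",
    "PhaseStrategy",
    "GameType",
    "coupling",
    "edge_payoff",
    "payoff_table",
    "switch_game_matrix",
    "classify_ordinal",
    "classify_game",
    "classify_interaction",
    "game_region",
    "interaction_game_table",
    "STRICT_GAME_NAMES",
]


@dataclass(frozen=True)
class GameParams:
    """Parameters of the game and its evolutionary dynamics.

    Defaults are the standard operating point: cost c = 0.1, maximum joint
    benefit B0 = 0.15 (B0/c = 1.5, slightly below the well-mixed break-even
    ratio of about 2.1), maximum mixed benefit beta0 = 0.95 * B0, selection
    strength delta = 0.2, mutation rate mu = 1e-4 and m = 20 phases.

    ``cc_coupling`` selects whether a live C-C interaction uses the actual
    phase difference ("actual", the default, i.e. genuine Kuramoto coupling)
    or is pinned to f(0) ("zero").  The switch-game matrix is unaffected:
    there the joint-C cell always has both players on one phase.
    """

    B0: float = 0.15
    beta0: float | None = None
    c: float = 0.1
    alpha: float = 0.5
    delta: float = 0.2
    mu: float = 1e-4
    m: int = 20
    cc_coupling: str = "actual"

    def __post_init__(self):
        if self.beta0 is None:
            object.__setattr__(self, "beta0", 0.95 * self.B0)
        if self.B0 <= 0 or self.beta0 <= 0 or self.c <= 0:
            raise ValueError("B0, beta0 and c must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if self.m < 2:
            raise ValueError(f"need at least 2 phases, got m={self.m}")
        if self.cc_coupling not in ("actual", "zero"):
            raise ValueError(f"cc_coupling must be 'actual' or 'zero'")

    @property
    def beta0_ratio(self) -> float:
        return self.beta0 / self.B0

    def with_B0(self, B0: float) -> "GameParams":
        """New params at a different B0, keeping the beta0/B0 ratio fixed."""
        return replace(self, B0=B0, beta0=self.beta0_ratio * B0)


class PhaseStrategy(NamedTuple):
    """A player's state: communicative label ('C' or 'N') and phase index k."""

    label: str
    k: int

    def phase(self, m: int) -> float:
        return 2.0 * math.pi * self.k / m


@dataclass(frozen=True)
class GameType:
    """A named 2x2 ordinal game class.

    ``collapsed`` is set when the payoff matrix had ties (within tolerance)
    and the non-strict tie name was collapsed onto the adjacent strict game
    per the taxonomy's binomial convention (e.g. "mid hunt" -> staghunt).
    """

    name: str
    collapsed: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def coupling(delta_phi: float) -> float:
    """Shifted Kuramoto coupling f(dphi) = (1 + cos dphi) / 2, in [0, 1]."""
    return 0.5 * (1.0 + np.cos(delta_phi))


def _check_state(s: PhaseStrategy, m: int) -> None:
    if s.label not in ("C", "N"):
        raise ValueError(f"label must be 'C' or 'N', got {s.label!r}")
    if not 0 <= s.k < m:
        raise ValueError(f"phase index {s.k} out of range for m={m}")


def edge_payoff(head: PhaseStrategy, tail: PhaseStrategy, p: GameParams) -> float:
    """Payoff delivered to ``head`` by the single game with ``tail``.

    The phase difference convention is dphi = phi_tail - phi_head (f is even,
    so this only matters for log reproducibility).
    """
    _check_state(head, p.m)
    _check_state(tail, p.m)
    dphi = 2.0 * math.pi * (tail.k - head.k) / p.m
    f = coupling(dphi)
    if head.label == "C":
        if tail.label == "C":
            fcc = 1.0 if p.cc_coupling == "zero" else f
            return p.B0 * fcc - p.c
        return 2.0 * p.alpha * p.beta0 * f - p.c
    if tail.label == "C":
        return 2.0 * (1.0 - p.alpha) * p.beta0 * f
    return 0.0


def payoff_table(p: GameParams) -> np.ndarray:
    """Vectorized edge payoffs, indexed ``[head_label, tail_label, dk]``.

    Label index 0 is N, 1 is C; ``dk = (k_tail - k_head) mod m``.  The engine
    uses this table so that a step never re-derives trigonometry.
    """
    dk = np.arange(p.m)
    f = 0.5 * (1.0 + np.cos(2.0 * np.pi * dk / p.m))
    tab = np.zeros((2, 2, p.m))
    fcc = np.ones(p.m) if p.cc_coupling == "zero" else f
    tab[1, 1] = p.B0 * fcc - p.c
    tab[1, 0] = 2.0 * p.alpha * p.beta0 * f - p.c
    tab[0, 1] = 2.0 * (1.0 - p.alpha) * p.beta0 * f
    return tab


def switch_game_matrix(i: PhaseStrategy, j: PhaseStrategy, p: GameParams) -> np.ndarray:
    """Hypothetical 2x2 switch game between players ``i`` (row) and ``j``.

    Rows are i's options (keep own state / switch to j's state), columns are
    j's options in the same order; each cell is the edge payoff the row
    player receives from the column player.  When both players end up on the
    same state the phase difference is 0, which is where the f(0) joint-C
    cell of the condensed matrix comes from.
    """
    return np.array([
        [edge_payoff(i, j, p), edge_payoff(i, i, p)],
        [edge_payoff(j, j, p), edge_payoff(j, i, p)],
    ])


# ---------------------------------------------------------------------------
# Ordinal taxonomy
#
# Row-player payoffs of a symmetric 2x2 game in standard form [[R, S], [T, P]]:
# R = joint first strategy, S = first vs second, T = second vs first,
# P = joint second.  For the mixed C/N interaction: R = C-from-C at dphi=0,
# S = C-from-N, T = N-from-C, P = N-from-N = 0.  The 12 strict symmetric
# games are canonically written with R or T maximal; orderings with S or P on
# top are the same games with the two strategies listed in the other order
# and are mapped back by the relabel involution (R,S,T,P) -> (P,T,S,R).

STRICT_GAME_NAMES: dict[tuple[str, str, str, str], str] = {
    ("R", "S", "T", "P"): "harmony",
    ("R", "S", "P", "T"): "peace",
    ("R", "T", "S", "P"): "concord",
    ("R", "T", "P", "S"): "staghunt",
    ("R", "P", "T", "S"): "assurance",
    ("R", "P", "S", "T"): "coordination",
    ("T", "R", "S", "P"): "chicken",
    ("T", "R", "P", "S"): "dilemma",
    ("T", "S", "R", "P"): "battle",
    ("T", "S", "P", "R"): "hero",
    ("T", "P", "R", "S"): "deadlock",
    ("T", "P", "S", "R"): "compromise",
}

# Tie collapse: when two payoffs tie within tolerance the taxonomy's binomial
# tie names are collapsed onto a strict neighbour by ranking tied entries in
# the priority order R, T, S, P.  This reproduces the documented collapses:
# R>T=P>S ("mid hunt") -> staghunt, T>P>R=S ("low lock") -> deadlock,
# R>S>T=P ("mid harmony") -> harmony.
_TIE_PRIORITY = {"R": 0, "T": 1, "S": 2, "P": 3}


def classify_ordinal(R: float, S: float, T: float, P: float,
                     tol: float = 1e-9) -> GameType:
    """Name the symmetric 2x2 game with row-player payoffs (R, S, T, P)."""
    vals = {"R": float(R), "S": float(S), "T": float(T), "P": float(P)}
    for k, v in vals.items():
        if not math.isfinite(v):
            raise ValueError(f"non-finite payoff {k}={v}")
    mx = max(vals.values())
    if vals["R"] < mx - tol and vals["T"] < mx - tol:
        # strategy-relabel involution puts R or T on top
        vals = {"R": vals["P"], "S": vals["T"], "T": vals["S"], "P": vals["R"]}
    # sort descending by value, clustering ties within tol
    by_val = sorted(vals, key=lambda k: -vals[k])
    groups: list[list[str]] = [[by_val[0]]]
    for k in by_val[1:]:
        if vals[groups[-1][-1]] - vals[k] <= tol:
            groups[-1].append(k)
        else:
            groups.append([k])
    collapsed = any(len(grp) > 1 for grp in groups)
    pattern = tuple(k for grp in groups for k in sorted(grp, key=_TIE_PRIORITY.get))
    return GameType(STRICT_GAME_NAMES[pattern], collapsed=collapsed)


def classify_game(mat: np.ndarray, tol: float = 1e-9) -> GameType:
    """Classify a mixed-pair switch matrix from :func:`switch_game_matrix`.

    In the keep/switch layout the four role payoffs sit at fixed positions:
    with row player C the matrix reads [[S, R], [P, T]]; with row player N it
    reads [[T, P], [R, S]], which the relabel involution maps to the same
    ordinal class.  Classification is invariant to adding a constant to all
    four entries and to positive rescaling.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (2, 2):
        raise ValueError(f"expected a 2x2 matrix, got shape {mat.shape}")
    return classify_ordinal(mat[0, 1], mat[0, 0], mat[1, 1], mat[1, 0], tol=tol)


def classify_interaction(i: PhaseStrategy, j: PhaseStrategy, p: GameParams,
                         tol: float = 1e-9) -> GameType:
    """Game type of the interaction between players i and j.

    Joint-C pairs always play a (double) cooperation game and joint-N pairs a
    neutral game; only mixed C/N pairs consult the ordinal taxonomy.
    """
    if i.label == j.label:
        return GameType("cooperation" if i.label == "C" else "neutral")
    return classify_game(switch_game_matrix(i, j, p), tol=tol)


def game_region(B0_over_c: float, beta_over_c: float, alpha: float,
                tol: float = 1e-9) -> GameType:
    """Mixed-game classification at a point of the (B0/c, beta/c, alpha) space.

    ``beta = beta0 * f(dphi)`` is treated as a free axis, so this rasterizes
    the game-region phase diagram directly (payoffs in units of c):
    R = B0/c - 1, S = 2*alpha*beta/c - 1, T = 2*(1-alpha)*beta/c, P = 0.
    """
    if B0_over_c <= 0 or beta_over_c < 0:
        raise ValueError("B0/c must be positive and beta/c non-negative")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return classify_ordinal(
        B0_over_c - 1.0,
        2.0 * alpha * beta_over_c - 1.0,
        2.0 * (1.0 - alpha) * beta_over_c,
        0.0,
        tol=tol,
    )


def interaction_game_table(p: GameParams, tol: float = 1e-9) -> tuple[list[str], np.ndarray]:
    """Per-edge game lookup: names list and index table ``[lh, lt, dk]``.

    Classification of an edge depends only on the unordered label pair and
    the phase offset, so a (2, 2, m) table covers every edge of any graph.
    Used by the game census to classify thousands of edges per sampled step
    without per-edge Python work.
    """
    names: list[str] = []
    idx_of: dict[str, int] = {}

    def _idx(name: str) -> int:
        if name not in idx_of:
            idx_of[name] = len(names)
            names.append(name)
        return idx_of[name]

    tab = np.zeros((2, 2, p.m), dtype=np.int64)
    tab[0, 0, :] = _idx("neutral")
    tab[1, 1, :] = _idx("cooperation")
    for dk in range(p.m):
        cn = classify_interaction(PhaseStrategy("C", 0), PhaseStrategy("N", dk), p, tol=tol)
        nc = classify_interaction(PhaseStrategy("N", 0), PhaseStrategy("C", dk), p, tol=tol)
        tab[1, 0, dk] = _idx(cn.name)
        tab[0, 1, dk] = _idx(nc.name)
    return names, tab
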