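"""Rare-mutation analytics for well-mixed (complete-graph) populations.

Under mutation rates mu << 1 the population is monomorphic almost all of the
time: a mutant either fixates or vanishes long before the next mutation.
The long-run behaviour is then captured by an embedded Markov chain over the
2m monomorphic strategy states whose transition rates are proportional to
the single-mutant fixation probabilities.  The time-averaged communicative
fraction is the stationary weight of the C-labelled states, and the
break-even joint benefit B0 is where that fraction crosses one half (for
N -> infinity at alpha = 1/2 this approaches the closed form 2(N-1)c/(N-2)
... evaluated at finite N the closed form is the weak-selection anchor).

Fixation probabilities are the exact birth-death expressions for the Moran
process with exponential fitness on a complete graph without self-loops:

    rho(res -> mut) = 1 / (1 + sum_{k=1}^{N-1} prod_{j=1}^{k} gamma_j),
    gamma_j = exp(delta * (pi_res(j) - pi_mut(j)))

with, at j mutants, pi_mut(j) = (j-1)*a_MM + (N-j)*a_MR and
pi_res(j) = j*a_RM + (N-j-1)*a_RR, where a_XY is the per-game payoff to an
X-player receiving from a Y-player.  Sums are evaluated in log space.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import bisect
from scipy.special import logsumexp

from .games import GameParams, PhaseStrategy, edge_payoff

__all__ = [
    "pairwise_fixation",
    "fixation_table",
    "enumerate_strategies",
    "stationary_distribution",
    "stationary_fcomm",
    "break_even_B0",
    "closed_form_break_even",
]


def pairwise_fixation(resident: PhaseStrategy, mutant: PhaseStrategy,
                      N: int, p: GameParams) -> float:
    """Fixation probability of one mutant in a resident complete-graph
    population of size N (no self-interaction).

    At delta = 0 this is exactly the neutral 1/N.
    """
    if N < 2:
        raise ValueError(f"population size must be >= 2, got {N}")
    a_mm = edge_payoff(mutant, mutant, p)
    a_mr = edge_payoff(mutant, resident, p)
    a_rm = edge_payoff(resident, mutant, p)
    a_rr = edge_payoff(resident, resident, p)
    j = np.arange(1, N, dtype=float)  # number of mutants
    pi_mut = (j - 1.0) * a_mm + (N - j) * a_mr
    pi_res = j * a_rm + (N - j - 1.0) * a_rr
    log_gamma = p.delta * (pi_res - pi_mut)
    # denominator 1 + sum_k exp(S_k), S_k = sum_{j<=k} log gamma_j
    log_terms = np.concatenate(([0.0], np.cumsum(log_gamma)))
    return float(np.exp(-logsumexp(log_terms)))


def enumerate_strategies(m: int) -> list[PhaseStrategy]:
    """The 2m pure strategies, N-labelled block first, phases ascending."""
    return [PhaseStrategy(lbl, k) for lbl in ("N", "C") for k in range(m)]


def fixation_table(N: int, p: GameParams) -> np.ndarray:
    """(2m x 2m) matrix; entry (A, B) = fixation of one B mutant among A residents.

    Payoffs depend only on the labels and the phase offset, so only
    2*2*m distinct fixation problems are solved and broadcast.
    """
    strategies = enumerate_strategies(p.m)
    by_offset = np.empty((2, 2, p.m))
    labels = ("N", "C")
    for li, lr in enumerate(labels):
        for lj, lm in enumerate(labels):
            for dk in range(p.m):
                by_offset[li, lj, dk] = pairwise_fixation(
                    PhaseStrategy(lr, 0), PhaseStrategy(lm, dk), N, p)
    tab = np.empty((2 * p.m, 2 * p.m))
    for a, sa in enumerate(strategies):
        for b, sb in enumerate(strategies):
            la = 1 if sa.label == "C" else 0
            lb = 1 if sb.label == "C" else 0
            tab[a, b] = by_offset[la, lb, (sb.k - sa.k) % p.m]
    return tab


def stationary_distribution(N: int, p: GameParams) -> np.ndarray:
    """Stationary law of the embedded monomorphic chain.

    Off-diagonal rate A -> B is (1/2m) * rho(A -> B) (the uniform mutation
    kernel over all 2m strategies; drawing the current strategy is a
    self-loop and drops out).  Solved by null space of the rate matrix.
    """
    tab = fixation_table(N, p)
    n_states = tab.shape[0]
    Q = tab / n_states
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    ns = null_space(Q.T)
    if ns.shape[1] != 1:
        raise ValueError(
            f"embedded chain is not uniquely ergodic (null space dim {ns.shape[1]}); "
            "check the parameters (very large delta can underflow fixation rates)")
    pi = ns[:, 0]
    pi = np.abs(pi) / np.abs(pi).sum()
    return pi


def stationary_fcomm(N: int, p: GameParams) -> float:
    """Predicted time-averaged communicative fraction, in [0, 1]."""
    pi = stationary_distribution(N, p)
    labels = np.array([1 if s.label == "C" else 0 for s in enumerate_strategies(p.m)])
    return float(pi[labels == 1].sum())


def break_even_B0(N: int, p: GameParams, bracket: tuple[float, float] | None = None,
                  tol: float = 1e-4) -> float:
    """B0 at which the theory curve crosses f_comm = 1/2, by bisection.

    The beta0/B0 ratio of ``p`` is held fixed along the sweep.  The default
    bracket is [c/2, 4c]; the curve is checked to actually cross (and be
    ordered) across the bracket before bisecting.
    """
    lo, hi = bracket if bracket is not None else (p.c / 2.0, 4.0 * p.c)

    def f(B0: float) -> float:
        return stationary_fcomm(N, p.with_B0(B0)) - 0.5

    f_lo, f_hi = f(lo), f(hi)
    if f_lo >= 0 or f_hi <= 0:
        raise ValueError(
            f"no upward 1/2 crossing in bracket [{lo}, {hi}]: "
            f"f_comm({lo})={f_lo + 0.5:.4f}, f_comm({hi})={f_hi + 0.5:.4f}")
    return float(bisect(f, lo, hi, xtol=tol))


def closed_form_break_even(N: int, c: float) -> float:
    """Weak-selection break-even anchor 2(N-1)c/(N-2) for the symmetric case."""
    if N < 3:
        raise ValueError(f"closed form needs N >= 3, got {N}")
    return 2.0 * (N - 1) * c / (N - 2)
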