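# Methods

## Model and conventions

The package implements an asymmetric evolutionary Kuramoto game on a pair of
weighted, directed graphs.  Conventions that the code fixes once and uses
everywhere:

* **Edge direction.**  An interaction edge `u → v` awards its payoff to the
  head `v`, computed from `v`'s (head) and `u`'s (tail) states and scaled by
  the integer weight `w_uv`; a node's total payoff sums over its in-edges.
  Reproduction flows the other way along the same arrows: a birth node
  replaces one of its out-neighbours in the reproduction graph,
  proportionally to edge weight.  This is the only pairing of the two roles
  in which "payoff to the head" and "replacement among the birth node's
  out-neighbours" are simultaneously satisfiable on one edge set.
* **Phase difference.**  `Δϕ = ϕ_tail − ϕ_head`; the coupling
  `f(Δϕ) = (1 + cos Δϕ)/2` is even, so the sign convention only affects
  logs, not payoffs.
* **Reproduction graph.**  Identical to the interaction graph plus one
  weight-1 self-loop on every dangling node, where *dangling* means
  out-degree zero (a self-loop makes a node its own out-neighbour).  The
  published description motivates the self-loops with "positive indegree",
  but the quantity the birth–death update actually requires is positive
  out-degree, which is what the construction provides.  A node whose only
  out-edge is its own self-loop replaces itself: it mutates with
  probability μ and otherwise nothing changes.
* **Joint-C coupling.**  A live C–C interaction uses the actual phase
  difference (genuine Kuramoto coupling); the condensed-matrix `f(0)` term
  appears only in the switch-game cell where both players adopt one state,
  where it arises automatically from a zero phase difference.  A
  `cc_coupling="zero"` toggle pins live C–C payoffs to `f(0)` for
  comparison.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `c` | communication cost (payoff units) | 0.1 | standard operating point |
| `B0` | maximum joint C–C benefit | 0.15 | `B0/c = 1.5`, slightly below the well-mixed break-even ratio ≈ 2.1, biasing toward non-communication |
| `beta0` | maximum mixed C/N benefit | `0.95·B0` | mixed communication slightly less rewarding than joint |
| `alpha` | benefit asymmetry in [0,1] | 0.5 | symmetric mixed game; swept in experiments |
| `delta` | selection strength | 0.2 | weak selection; strong enough to order fitnesses, small enough for the rare-mutation analytics to track simulations |
| `mu` | mutation probability per turn | 1e-4 | rare-mutation regime: fixation or extinction completes well within 1/μ turns |
| `m` | number of discrete phases | 20 | the communicative fraction is already converged in m at this value |

Only the combinations `B0/c`, `beta0/B0`, `alpha` and `delta·c` matter for
the dynamics, plus μ and m.

Other numerical choices: selection probabilities are computed from
payoff-shifted exponentials (shift-invariant, overflow-safe); mutation draws
uniformly over all 2m strategies *including* the current one (the simplest
reading of a uniformly random replacement); the initial state is i.i.d.
uniform over the 2m strategies; step 0 is recorded; one global RNG stream
per run makes reruns bit-identical.  The engine keeps payoffs incrementally
(recomputing the changed node from its in-edges and adjusting downstream
heads by single-edge deltas) and caches the cumulative fitness vector
between state changes; the test suite pins the incremental totals to a
from-scratch recomputation at 1e-12.

## Game-type taxonomy

Each pair interaction defines a 2×2 switch game whose row-player payoffs in
standard form are `R` (joint C at zero phase lag), `S` (C receiving from N),
`T` (N receiving from C) and `P = 0` (joint N).  Strict orderings of these
four values name the twelve symmetric ordinal game types; orderings with
`S` or `P` maximal are the same games with the strategies listed in the
other order and are mapped back by the relabel involution
`(R,S,T,P) → (P,T,S,R)`.  The name table is anchored by the classical
definitions (dilemma `T>R>P>S`, chicken `T>R>S>P`, staghunt `R>T>P>S`,
battle `T>S>R>P`, hero = battle with the two lowest entries swapped) and by
the documented boundary behaviour of the mixed-game phase diagram, which
fixes the remaining names (harmony `R>S>T>P` adjacent to peace across the
`T = P` line, concord `R>T>S>P`, assurance `R>P>T>S`, coordination
`R>P>S>T`, deadlock `T>P>R>S` adjacent to compromise across `R = S`).

Ties within a tolerance of 1e-9 (exact ties such as `T = P` at `Δϕ = π`
must be caught) are collapsed onto a strict neighbour by ranking tied
entries in the priority order R, T, S, P; this reproduces all three
documented collapses ("mid hunt" → staghunt, "low lock" → deadlock,
"mid harmony" → harmony) and flags the result as `collapsed`.  C–C pairs
always classify as cooperation and N–N pairs as neutral.

## Rare-mutation analytics

For complete graphs the time-averaged communicative fraction is predicted by
an embedded Markov chain over the 2m monomorphic states.  The transition
rate A → B is proportional to the fixation probability of a single B mutant
in an A population,

    ρ_{A→B} = 1 / (1 + Σ_{k=1}^{N−1} Π_{j=1}^{k} γ_j),
    γ_j = exp(δ [π_res(j) − π_mut(j)]),

with the exact exponential-fitness payoffs at j mutants, evaluated in log
space.  The stationary law of the chain (null-space solve) gives `f_comm`
as the summed weight of C-labelled states; the break-even `B₀` is found by
bisection of `f_comm(B₀) − ½` on `[c/2, 4c]` to 1e-4, holding `β₀/B₀`
fixed.  The derivation assumes the complete graph and μ ≪ 1 (each mutation
resolves before the next); the test suite checks the whole construction
against a brute-force absorbing-chain fixation oracle (1e-10, N ≤ 10) and
against the exact stationary law of the full `(2m)^N` configuration chain
at N = 3, m = 2, where the discrepancy is O(μ) (measured ≈ 0.014 μ).  Exact
exponential-fitness probabilities are used rather than a weak-selection
expansion; at δ = 0.2, N = 20 the resulting symmetric break-even is 0.2111,
within 4×10⁻⁵ of the weak-selection closed form `2(N−1)c/(N−2)`.

## Chimera and metastability indices

`σ_chi(t)` is the across-community *sample* variance (1/(M−1)) of the
community order parameters at time t, and χ its time mean; `σ_met(m)` is
the temporal sample variance (1/(T−1)) of community m's trace, and λ its
community mean.  With these normalisations χ attains `M/[4(M−1)]` exactly
on half-coherent/half-disordered traces, while λ attains ¼ only in the
large-T limit (an equal-occupancy 0/1 trace of length T gives
`T/[4(T−1)]`, e.g. 0.250025 at T = 10⁴); metrics operate on sampled steps
(default every 800).  Community detection delegates to igraph's Leiden
implementation of the constant Potts model with resolution 0.1, refinement
randomness β = 0.01 and 2 iterations, seeded; the backend works on
undirected graphs, so directed input is collapsed to weighted-undirected
with summed reciprocal weights.  Because community structure can vary
across backend versions, assignments can be persisted to and read from a
plain TSV, which is the reproducibility path.

## Synthetic fixtures and their limits

`synth_connectome` generates a random weighted directed graph whose census
equals the published tally of the *C. elegans* chemical connectome exactly:
300 nodes, 38 self-loops, 669 bidirectional pairs, 2,331 unpaired edges
(3,707 directed edges) and 5 dangling nodes.  Edge placement is uniform
subject to those counts, with a repair pass that re-sources unpaired edges
until exactly the designated nodes have out-degree zero (a fixture artifact,
not biology); weights are i.i.d. geometric on {1, 2, …} with mean 3
(configurable) — the real weight distribution is unpublished and not
claimed.  What the fixture does *not* emulate: degree heterogeneity, the
rich-club/community structure of the real connectome, and weight–topology
correlations.  Consequently CPM communities on the fixture are mostly one
large block plus singletons, and the published chimera values (χ ≈ 0.1,
λ < 0.03) are *not* reproduced by it; fixture-based tests therefore assert
only structural bounds (χ ≤ M/[4(M−1)], λ ≪ ¼) and qualitative game-type
behaviour.  Passing tests validate the machinery, not claims about the real
connectome, which requires the real edge list via `load_edge_list`.

## Problem sizes used in the checks

The packaged checks are scaled to desk hardware: well-mixed synchrony runs
use 8×10⁵ steps × 3 seeds × 5 asymmetries (the source experiments used
8×10⁶ and 10 seeds); at this length the per-α monomorphic sample fraction
reaches ≈ 99.4–99.7% — the initial random state and the handful of
fixation crossings are a fixed per-run cost, so the published ≥ 99.6%
bound is met at 8×10⁶ but can fall ~0.15 percentage points short at 8×10⁵.
Simulation-vs-theory agreement is checked at N = 8, m = 4, μ = 2×10⁻³
(6 seeds × 3×10⁵ steps, three B₀ values, 3 sample-sd tolerance), neutral
fixation at N = 10 over 2×10⁴ replicates (binomial 99% CI), and the exact
configuration-chain oracle at N = 3, m = 2.

## Known limitations

* Only the birth–death update rule with total (not averaged) payoff is
  implemented; no death–birth, pairwise-comparison or continuous-time
  variants.
* The analytics cover complete graphs only; no structured-population
  theory is provided.
* All nodes are treated identically — no neuron-type-specific parameters,
  and only a single (chemical-style) edge set; no gap-junction layer.
* m is finite by construction; no continuous-phase limit.
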