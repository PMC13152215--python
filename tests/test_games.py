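"""Payoffs, switch matrices and the ordinal game taxonomy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evokuramoto import (
    GameParams,
    PhaseStrategy,
    classify_game,
    classify_interaction,
    classify_ordinal,
    coupling,
    edge_payoff,
    game_region,
    switch_game_matrix,
)
from evokuramoto.games import interaction_game_table, payoff_table

C, N = "C", "N"


class TestCoupling:
    @pytest.mark.parametrize("dphi,expected", [(0.0, 1.0), (np.pi, 0.0), (np.pi / 2, 0.5)])
    def test_values(self, dphi, expected):
        assert coupling(dphi) == pytest.approx(expected, abs=1e-15)

    def test_bounds_even_periodic(self):
        x = np.linspace(-12.0, 12.0, 10_000)
        f = np.array([coupling(v) for v in x])
        assert ((0.0 <= f) & (f <= 1.0)).all()
        assert np.allclose(f, [coupling(-v) for v in x], atol=1e-12)
        assert np.allclose(f, [coupling(v + 2 * np.pi) for v in x], atol=1e-12)


class TestEdgePayoff:
    def test_joint_communication(self, default_params):
        got = edge_payoff(PhaseStrategy(C, 0), PhaseStrategy(C, 0), default_params)
        assert got == pytest.approx(0.05)  # B0*f(0) - c

    def test_nn_always_zero(self, default_params):
        for k1 in range(0, 20, 5):
            for k2 in range(0, 20, 7):
                assert edge_payoff(PhaseStrategy(N, k1), PhaseStrategy(N, k2),
                                   default_params) == 0.0

    def test_symmetric_mixed_reduces_to_beta0_f(self, default_params):
        # at alpha = 1/2 both mixed payoffs carry the plain beta0*f benefit
        p = default_params
        got_n = edge_payoff(PhaseStrategy(N, 0), PhaseStrategy(C, 0), p)
        got_c = edge_payoff(PhaseStrategy(C, 0), PhaseStrategy(N, 0), p)
        assert got_n == pytest.approx(p.beta0)
        assert got_c == pytest.approx(p.beta0 - p.c)

    @pytest.mark.parametrize("alpha", [0.0, 0.2, 0.35, 0.8, 1.0])
    def test_alpha_symmetry_swaps_mixed_roles(self, alpha):
        p1, p2 = GameParams(alpha=alpha), GameParams(alpha=1 - alpha)
        for dk in (0, 3, 9):
            i, j = PhaseStrategy(C, 0), PhaseStrategy(N, dk)
            # communicator benefit at alpha equals non-communicator benefit at 1-alpha
            assert edge_payoff(i, j, p1) + p1.c == pytest.approx(
                edge_payoff(PhaseStrategy(N, 0), PhaseStrategy(C, dk), p2))

    def test_cc_coupling_zero_pins_f0(self):
        p = GameParams(cc_coupling="zero")
        assert edge_payoff(PhaseStrategy(C, 0), PhaseStrategy(C, 10), p) == \
            pytest.approx(p.B0 - p.c)

    def test_payoff_table_matches_scalar(self, default_params):
        tab = payoff_table(default_params)
        for lh, ln_ in ((1, C), (0, N)):
            for lt, lt_ in ((1, C), (0, N)):
                for dk in range(20):
                    assert tab[lh, lt, dk] == pytest.approx(
                        edge_payoff(PhaseStrategy(ln_, 0), PhaseStrategy(lt_, dk),
                                    default_params), abs=1e-14)


class TestSwitchMatrix:
    def test_mixed_pair_cells(self, default_params):
        mat = switch_game_matrix(PhaseStrategy(C, 0), PhaseStrategy(N, 0), default_params)
        # keep/keep = 2*alpha*beta0 - c, keep/switch = B0 - c,
        # switch/keep = 0 (joint N), switch/switch = 2*(1-alpha)*beta0
        assert mat == pytest.approx(np.array([[0.0425, 0.05], [0.0, 0.1425]]))

    def test_degenerate_self_pair(self, default_params):
        mat = switch_game_matrix(PhaseStrategy(C, 3), PhaseStrategy(C, 3), default_params)
        assert np.allclose(mat, mat[0, 0])

    def test_role_swap_rotates_matrix(self, default_params):
        i, j = PhaseStrategy(C, 0), PhaseStrategy(N, 4)
        mi = switch_game_matrix(i, j, default_params)
        mj = switch_game_matrix(j, i, default_params)
        # swapping who is the row player relabels both options: 180-degree turn
        assert np.allclose(mj, mi[::-1, ::-1])

    def test_symmetric_alpha_mixed_benefit(self, default_params):
        # at alpha = 1/2 both mixed roles earn the same benefit (up to the cost)
        mat = switch_game_matrix(PhaseStrategy(C, 0), PhaseStrategy(N, 4), default_params)
        assert mat[0, 0] + default_params.c == pytest.approx(mat[1, 1])


class TestClassification:
    @pytest.mark.parametrize("dk,name", [(0, "chicken"), (5, "dilemma"), (10, "staghunt")])
    def test_phase_sweep_anchors(self, default_params, dk, name):
        gt = classify_interaction(PhaseStrategy(C, 0), PhaseStrategy(N, dk), default_params)
        assert gt.name == name

    def test_row_player_label_irrelevant(self, default_params):
        for dk in range(20):
            a = classify_interaction(PhaseStrategy(C, 0), PhaseStrategy(N, dk), default_params)
            b = classify_interaction(PhaseStrategy(N, dk), PhaseStrategy(C, 0), default_params)
            assert a.name == b.name

    def test_same_label_pairs(self, default_params):
        assert classify_interaction(PhaseStrategy(C, 0), PhaseStrategy(C, 9),
                                    default_params).name == "cooperation"
        assert classify_interaction(PhaseStrategy(N, 0), PhaseStrategy(N, 9),
                                    default_params).name == "neutral"

    def test_tie_collapses(self):
        # alpha=1, large mixed benefit: T=P=0 exactly, S on top -> "low lock"
        gt = classify_interaction(PhaseStrategy(C, 0), PhaseStrategy(N, 0),
                                  GameParams(alpha=1.0))
        assert gt.name == "deadlock" and gt.collapsed
        # alpha=1, small mixed benefit: R>S>T=P -> "mid harmony"
        gt = game_region(1.5, 0.6, 1.0)
        assert gt.name == "harmony" and gt.collapsed
        # beta=0: R>T=P>S -> "mid hunt"
        gt = game_region(1.5, 0.0, 0.5)
        assert gt.name == "staghunt" and gt.collapsed

    def test_strict_matrix_never_collapsed(self, default_params):
        gt = classify_interaction(PhaseStrategy(C, 0), PhaseStrategy(N, 3), default_params)
        assert not gt.collapsed

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_game(np.array([[np.nan, 0.0], [0.0, 1.0]]))

    @given(
        st.tuples(*(st.floats(-2, 2).filter(lambda v: abs(v) > 1e-6) for _ in range(4))),
        st.floats(-5, 5),
        st.floats(0.01, 100.0),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_ordinal_invariance_shift_scale(self, vals, shift, scale):
        r, s, t, p = vals
        base = classify_ordinal(r, s, t, p, tol=0.0)
        moved = classify_ordinal(*(scale * v + shift for v in (r, s, t, p)), tol=0.0)
        assert moved.name == base.name

    def test_hero_and_concord_reachable(self):
        # alpha = 0.75, B0/c = 1.5 crosses hero then concord as beta shrinks
        assert game_region(1.5, 1.2, 0.75).name == "hero"
        assert game_region(1.5, 0.8, 0.75).name == "concord"


class TestGameRegion:
    def test_symmetric_slice_transitions(self):
        # along B0/c = 1.5, alpha = 0.5: chicken -> dilemma -> staghunt
        names = [game_region(1.5, b, 0.5).name for b in (1.4, 0.8, 0.3)]
        assert names == ["chicken", "dilemma", "staghunt"]

    def test_beta_zero_alpha_independent(self):
        names = {game_region(1.5, 0.0, a).name for a in (0.0, 0.25, 0.5, 0.75, 1.0)}
        assert names == {"staghunt"}

    def test_boundaries_match_bruteforce_scan(self):
        """Classification changes exactly where two payoff entries cross."""
        alpha, b0c = 0.5, 1.5

        def entries(beta):
            return (b0c - 1.0, 2 * alpha * beta - 1.0, 2 * (1 - alpha) * beta, 0.0)

        # brute-force over the accessible mixed-benefit range beta <= beta0/c
        # (beta = beta0 * f(dphi) with beta0/B0 = 0.95 and B0/c = 1.5)
        grid = np.linspace(1e-6, 0.95 * b0c, 20_001)
        crossings = []
        for a_i in range(4):
            for b_i in range(a_i + 1, 4):
                d = np.array([entries(b)[a_i] - entries(b)[b_i] for b in grid])
                sign = np.sign(d)
                for idx in np.flatnonzero(sign[:-1] * sign[1:] < 0):
                    lo, hi = grid[idx], grid[idx + 1]
                    for _ in range(60):  # bisect the equality point
                        mid = 0.5 * (lo + hi)
                        if (entries(lo)[a_i] - entries(lo)[b_i]) * \
                           (entries(mid)[a_i] - entries(mid)[b_i]) <= 0:
                            hi = mid
                        else:
                            lo = mid
                    crossings.append(0.5 * (lo + hi))
        # classification changes: bisect each change point
        names = [game_region(b0c, b, alpha, tol=0.0).name for b in grid]
        changes = []
        for idx in range(len(grid) - 1):
            if names[idx] != names[idx + 1]:
                lo, hi = grid[idx], grid[idx + 1]
                for _ in range(60):
                    mid = 0.5 * (lo + hi)
                    if game_region(b0c, mid, alpha, tol=0.0).name == names[idx]:
                        lo = mid
                    else:
                        hi = mid
                changes.append(0.5 * (lo + hi))
        assert len(changes) == 2  # chicken|dilemma and dilemma|staghunt
        for ch in changes:
            assert min(abs(ch - c) for c in crossings) < 1e-9
        assert changes[0] == pytest.approx(0.5, abs=1e-6)   # T = R
        assert changes[1] == pytest.approx(1.0, abs=1e-6)   # S = P


class TestGameTable:
    def test_table_matches_pairwise_classification(self, default_params):
        names, tab = interaction_game_table(default_params)
        for dk in range(20):
            expect = classify_interaction(PhaseStrategy(C, 0), PhaseStrategy(N, dk),
                                          default_params).name
            assert names[tab[1, 0, dk]] == expect
        assert names[tab[1, 1, 0]] == "cooperation"
        assert names[tab[0, 0, 0]] == "neutral"
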