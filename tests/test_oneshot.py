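import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

import transparentgames as tg
from transparentgames.games import PayoffMatrix, get_preset
from transparentgames.oneshot import (anticoordination_equilibria,
                                      lf_vs_alld_risk,
                                      one_shot_expected_payoff,
                                      pd_cooperator_defector_relation,
                                      pd_ne_defection_bound,
                                      pd_unequal_rt_bistability_threshold,
                                      pd_unequal_rt_classification,
                                      pd_unequal_rt_payoffs)
from transparentgames.pairwise import Relation, classify_pair
from transparentgames.strategies import OneShotStrategy

IPD = get_preset("ipd").payoff
ACG = get_preset("iacg").payoff

GRID = np.linspace(0.0, 1.0, 21)


def _grid_best_response(opponent: OneShotStrategy, p12: float, p21: float,
                        payoff: PayoffMatrix) -> float:
    """Vectorised maximum payoff over the 21^3 strategy grid (the deviating
    player sees with probability p12)."""
    R, S, T, P = payoff.as_vector()
    a1, a2, a3 = np.meshgrid(GRID, GRID, GRID, indexing="ij")
    b1, b2, b3 = opponent.as_tuple()
    blind = (a1 * b1 * R + a1 * (1 - b1) * S
             + (1 - a1) * b1 * T + (1 - a1) * (1 - b1) * P)
    j_sees = a1 * (b2 * R + (1 - b2) * S) + (1 - a1) * (b3 * T + (1 - b3) * P)
    i_sees = (b1 * (a2 * R + (1 - a2) * T)
              + (1 - b1) * (a3 * S + (1 - a3) * P))
    return float(((1 - p12 - p21) * blind + p21 * j_sees + p12 * i_sees).max())


class TestExpectedPayoff:
    def test_mutual_defection_pays_P(self):
        d = OneShotStrategy(0, 0, 0)
        for p in (0.0, 0.2, 0.5):
            assert one_shot_expected_payoff(d, d, p, p, IPD) == pytest.approx(1.0)

    def test_conditional_cooperators_closed_form(self):
        # (1;0;0) against itself: E = R + p_see (T - 2R) + p_see S
        c = OneShotStrategy(1, 0, 0)
        assert one_shot_expected_payoff(c, c, 0.4, 0.4, IPD) == pytest.approx(2.6)

    def test_zero_visibility_reduces_to_bilinear(self, rng):
        for _ in range(20):
            a = OneShotStrategy(*rng.random(3))
            b = OneShotStrategy(*rng.random(3))
            R, S, T, P = IPD.as_vector()
            bilinear = (a.s1 * b.s1 * R + a.s1 * (1 - b.s1) * S
                        + (1 - a.s1) * b.s1 * T + (1 - a.s1) * (1 - b.s1) * P)
            assert one_shot_expected_payoff(a, b, 0, 0, IPD) == pytest.approx(bilinear)

    def test_bilinearity_in_own_entries(self, rng):
        # E(lambda a + (1-lambda) a', b) = lambda E(a, b) + (1-lambda) E(a', b)
        for _ in range(10):
            a, a2, b = (OneShotStrategy(*rng.random(3)) for _ in range(3))
            lam = rng.random()
            mix = OneShotStrategy(*(lam * np.array(a.as_tuple())
                                    + (1 - lam) * np.array(a2.as_tuple())))
            lhs = one_shot_expected_payoff(mix, b, 0.3, 0.2, IPD)
            rhs = (lam * one_shot_expected_payoff(a, b, 0.3, 0.2, IPD)
                   + (1 - lam) * one_shot_expected_payoff(a2, b, 0.3, 0.2, IPD))
            assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_invalid_visibility_rejected(self):
        a = OneShotStrategy(0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            one_shot_expected_payoff(a, a, 0.6, 0.6, IPD)

    @pytest.mark.parametrize("payoff, s3_target", [(IPD, 0.0), (ACG, 1.0)])
    def test_seen_response_dominance(self, payoff, s3_target, rng):
        # conditional-response dominance: in the Prisoner's Dilemma it never
        # pays to cooperate with a seen defector (s3 -> 0); in the
        # anti-coordination class it never pays to insist against a seen
        # accommodation partner's A2 (s3 -> 1)
        for _ in range(1000):
            a = rng.random(3)
            b = OneShotStrategy(*rng.random(3))
            p12, p21 = rng.random(2) * 0.5
            orig = OneShotStrategy(*a)
            better = OneShotStrategy(a[0], a[1], s3_target)
            assert (one_shot_expected_payoff(better, b, p12, p21, payoff)
                    >= one_shot_expected_payoff(orig, b, p12, p21, payoff) - 1e-12)


class TestPdEquilibria:
    def test_defection_bound_values(self):
        assert pd_ne_defection_bound(IPD, 0.5).bound == pytest.approx(1 / 3)
        assert pd_ne_defection_bound(IPD, 0.25).bound == pytest.approx(1.0)
        zero = pd_ne_defection_bound(IPD, 0.0)
        assert zero.bound == 1.0 and zero.s2_irrelevant

    def test_defector_pairs_are_equilibria(self):
        # best-response search confirms no profitable deviation against
        # (0; x; 0) for x within the bound, and a profitable one beyond it
        p = 0.5
        bound = pd_ne_defection_bound(IPD, p).bound
        for x in (0.0, bound / 2, bound):
            opp = OneShotStrategy(0, x, 0)
            best = _grid_best_response(opp, p, p, IPD)
            ne_payoff = one_shot_expected_payoff(OneShotStrategy(0, 0, 0),
                                                 opp, p, p, IPD)
            assert best <= ne_payoff + 1e-9
        beyond = OneShotStrategy(0, min(1.0, bound + 0.2), 0)
        assert _grid_best_response(beyond, p, p, IPD) > 1.0 + 1e-9

    @pytest.mark.parametrize("p_see, x, expected", [
        (0.1, 0.2, Relation.FIRST_DOMINATES),
        (0.45, 0.9, Relation.SECOND_DOMINATES),
    ])
    def test_cooperator_defector_examples(self, p_see, x, expected):
        assert pd_cooperator_defector_relation(IPD, p_see, x) is expected

    def test_cooperator_defector_agrees_with_payoff_classification(self):
        coop = OneShotStrategy(1, 0, 0)
        for p in (0.05, 0.15, 0.25, 0.35, 0.45):
            for x in (0.05, 0.25, 0.45, 0.65, 0.85):
                dfct = OneShotStrategy(0, x, 0)
                E11 = one_shot_expected_payoff(dfct, dfct, p, p, IPD)
                E12 = one_shot_expected_payoff(dfct, coop, p, p, IPD)
                E21 = one_shot_expected_payoff(coop, dfct, p, p, IPD)
                E22 = one_shot_expected_payoff(coop, coop, p, p, IPD)
                assert (pd_cooperator_defector_relation(IPD, p, x)
                        is classify_pair(E11, E12, E21, E22))


class TestUnequalReactionTimes:
    def test_payoff_matrix_matches_general_formula(self):
        p11, p12 = 0.3, 0.6
        E11, E12, E21, E22 = pd_unequal_rt_payoffs(IPD, p11, p12)
        c, d = OneShotStrategy(1, 0, 0), OneShotStrategy(0, 0, 0)
        assert E11 == pytest.approx(one_shot_expected_payoff(c, c, p11, p11, IPD))
        assert E12 == pytest.approx(one_shot_expected_payoff(c, d, p12, 0.2, IPD))
        assert E21 == pytest.approx(one_shot_expected_payoff(d, c, 0.2, p12, IPD))
        assert E22 == pytest.approx(one_shot_expected_payoff(d, d, 0.1, 0.1, IPD))

    def test_bistability_threshold_is_five_eighths(self):
        assert pd_unequal_rt_bistability_threshold(IPD, 0.5) == pytest.approx(5 / 8)

    @pytest.mark.parametrize("p11, p12, expected", [
        (0.5, 1.0, Relation.FIRST_DOMINATES),
        (0.5, 0.7, Relation.BISTABLE),
        (0.2, 0.5, Relation.SECOND_DOMINATES),
    ])
    def test_classification(self, p11, p12, expected):
        assert pd_unequal_rt_classification(IPD, p11, p12) is expected


class TestAnticoordination:
    def test_simultaneous_limit_recovers_classic_mixed(self):
        eqs = anticoordination_equilibria(ACG, 0.0, 0.0)
        assert len(eqs) == 3
        mixed = [e for e in eqs if e.kind == "mixed"][0]
        assert mixed.player1.s1 == pytest.approx(3 / 4)
        assert mixed.player2.s1 == pytest.approx(3 / 4)

    def test_equal_visibility_mixed_entry(self):
        eqs = anticoordination_equilibria(ACG, 0.2, 0.2)
        mixed = [e for e in eqs if e.kind == "mixed"][0]
        assert mixed.player1.s1 == pytest.approx(5 / 6)

    def test_high_visibility_single_insisting_equilibrium(self):
        eqs = anticoordination_equilibria(ACG, 0.4, 0.4)
        assert len(eqs) == 1
        assert eqs[0].player1.as_tuple() == (1.0, 0.0, 1.0)
        assert eqs[0].player2.as_tuple() == (1.0, 0.0, 1.0)

    def test_rejects_non_anticoordination_payoffs(self):
        with pytest.raises(ValueError):
            anticoordination_equilibria(IPD, 0.1, 0.1)

    @pytest.mark.parametrize("payoff", [
        ACG, get_preset("hawkdove").payoff, get_preset("leader").payoff])
    @pytest.mark.parametrize("p12, p21", [
        (0.0, 0.0), (0.1, 0.1), (0.1, 0.2), (0.25, 0.25), (0.45, 0.45),
        (0.3, 0.1)])
    def test_equilibria_pass_best_response_oracle(self, payoff, p12, p21):
        for eq in anticoordination_equilibria(payoff, p12, p21):
            own1 = one_shot_expected_payoff(eq.player1, eq.player2, p12, p21, payoff)
            own2 = one_shot_expected_payoff(eq.player2, eq.player1, p21, p12, payoff)
            assert _grid_best_response(eq.player2, p12, p21, payoff) <= own1 + 1e-9
            assert _grid_best_response(eq.player1, p21, p12, payoff) <= own2 + 1e-9

    def test_mixed_equilibrium_indifference(self):
        for p12, p21 in ((0.0, 0.0), (0.1, 0.2), (0.15, 0.15)):
            eqs = anticoordination_equilibria(ACG, p12, p21)
            mixed = [e for e in eqs if e.kind == "mixed"][0]
            insist = OneShotStrategy(1, 0, 1)
            accomm = OneShotStrategy(0, 0, 1)
            e_ins = one_shot_expected_payoff(insist, mixed.player1, p21, p12, ACG)
            e_acc = one_shot_expected_payoff(accomm, mixed.player1, p21, p12, ACG)
            assert abs(e_ins - e_acc) < 1e-12


class TestLeaderFollowerRisk:
    @pytest.mark.parametrize("n, expected", [
        (1, Fraction(1, 2)), (2, Fraction(1, 4)), (6, Fraction(7, 64))])
    def test_printed_fractions(self, n, expected):
        assert lf_vs_alld_risk(n, IPD) == float(expected)

    def test_matches_exhaustive_role_enumeration(self):
        # independent oracle: enumerate every Leader/Follower role sequence;
        # the pure strategy earns T as Leader, S = 0 as Follower, and falls
        # short of the all-defection baseline n*P when its total is below it
        T, P = IPD.T, IPD.P
        for n in range(1, 13):
            if (n * P / T) == int(n * P / T):
                continue  # boundary convention differs at integer n*P/T
            hits = 0
            for roles in itertools.product((0, 1), repeat=n):
                total = sum(roles) * T
                if total < n * P:
                    hits += 1
            assert lf_vs_alld_risk(n, IPD) == pytest.approx(hits / 2 ** n)

    def test_large_n_uses_closed_form(self):
        value = lf_vs_alld_risk(40, IPD)
        expected = sum(math.comb(40, j) for j in range(0, 9)) / 2 ** 40
        assert value == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lf_vs_alld_risk(0, IPD)
        with pytest.raises(ValueError):
            lf_vs_alld_risk(3, ACG)
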