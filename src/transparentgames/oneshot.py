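"""Closed-form theory for one-shot transparent games.

In a one-shot transparent game each player i has a probability
:math:`p_{see}^{ij}` of seeing the partner's current choice before acting,
with :math:`p_{see}^{12} + p_{see}^{21} \\le 1`.  The expected payoff of
Player 1 with strategy :math:`(s_1; s_2; s_3)` against Player 2 is the sum of
three mutually exclusive branches — neither player sees, Player 2 sees
Player 1, Player 1 sees Player 2:

.. math::

   E(s^1, s^2) = (1 - p^1 - p^2)\\,[s_1^1 s_1^2 R + s_1^1(1-s_1^2) S
                + (1-s_1^1) s_1^2 T + (1-s_1^1)(1-s_1^2) P] \\\\
   + p^2\\,[s_1^1 (s_2^2 R + (1-s_2^2) S) + (1-s_1^1)(s_3^2 T + (1-s_3^2) P)] \\\\
   + p^1\\,[s_1^2 (s_2^1 R + (1-s_2^1) T) + (1-s_1^2)(s_3^1 S + (1-s_3^1) P)].

This module implements the analytical equilibrium results built on that
payoff: the defecting Nash equilibria of the transparent Prisoner's Dilemma,
the dominance/bistability relations between conditional cooperators and
defectors, the equilibria of transparent anti-coordination games (including
Hawk-Dove and Leader), and the finite-horizon risk of playing
Leader-Follower instead of unconditional defection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from .games import GameClass, PayoffMatrix, classify_game
from .pairwise import Relation, classify_pair
from .strategies import OneShotStrategy

__all__ = [
    "one_shot_expected_payoff",
    "DefectionBound",
    "pd_ne_defection_bound",
    "pd_cooperator_defector_relation",
    "pd_unequal_rt_payoffs",
    "pd_unequal_rt_bistability_threshold",
    "pd_unequal_rt_classification",
    "NashEquilibrium",
    "anticoordination_equilibria",
    "lf_vs_alld_risk",
]


def _check_psee(p12: float, p21: float) -> None:
    if p12 < 0 or p21 < 0:
        raise ValueError(f"visibility probabilities must be >= 0, got {p12}, {p21}")
    if p12 + p21 > 1.0 + 1e-12:
        raise ValueError(f"p12 + p21 = {p12 + p21} exceeds 1")


def one_shot_expected_payoff(
    s_i: OneShotStrategy,
    s_j: OneShotStrategy,
    p12: float,
    p21: float,
    payoff: PayoffMatrix,
) -> float:
    """Expected payoff of the focal player i against partner j.

    ``p12`` is the probability that i sees j's current choice, ``p21`` the
    probability that j sees i's.  With ``p12 = p21 = 0`` this reduces to the
    bilinear simultaneous-game payoff in the unseen entries ``s1``.
    """
    _check_psee(p12, p21)
    R, S, T, P = payoff.R, payoff.S, payoff.T, payoff.P
    a1, a2, a3 = s_i.as_tuple()
    b1, b2, b3 = s_j.as_tuple()
    blind = (a1 * b1 * R + a1 * (1 - b1) * S
             + (1 - a1) * b1 * T + (1 - a1) * (1 - b1) * P)
    # j sees i: i commits blindly with a1, j responds with b2 / b3
    j_sees = (a1 * (b2 * R + (1 - b2) * S)
              + (1 - a1) * (b3 * T + (1 - b3) * P))
    # i sees j: j commits blindly with b1, i responds with a2 / a3
    i_sees = (b1 * (a2 * R + (1 - a2) * T)
              + (1 - b1) * (a3 * S + (1 - a3) * P))
    return (1 - p12 - p21) * blind + p21 * j_sees + p12 * i_sees


# ---------------------------------------------------------------------------
# Transparent Prisoner's Dilemma, equal reaction times
# ---------------------------------------------------------------------------

class DefectionBound(NamedTuple):
    """Upper bound on the seen-cooperation entry x of an equilibrium defector.

    ``s2_irrelevant`` is set when ``p_see = 0``: the conditional entry is then
    never used and every (0; x; 0) pair is the classic defection equilibrium.
    """

    bound: float
    s2_irrelevant: bool


def pd_ne_defection_bound(payoff: PayoffMatrix, p_see: float) -> DefectionBound:
    """Largest x such that the defector pairs ((0; x; 0), (0; y; 0)) are NE.

    In the transparent Prisoner's Dilemma every Nash equilibrium consists of
    strategies (0; x; 0) — defect unless seeing the partner cooperate, in
    which case cooperate with probability at most

    .. math:: x \\le \\frac{1 - p_{see}}{p_{see}} \\cdot \\frac{P - S}{R - S}.

    The returned bound is capped at 1.
    """
    if classify_game(payoff) != GameClass.PD:
        raise ValueError("payoff matrix is not a Prisoner's Dilemma")
    if not 0.0 <= p_see <= 0.5:
        raise ValueError(f"p_see={p_see} outside [0, 0.5]")
    if p_see == 0.0:
        return DefectionBound(bound=1.0, s2_irrelevant=True)
    R, S, P = payoff.R, payoff.S, payoff.P
    raw = (1.0 - p_see) / p_see * (P - S) / (R - S)
    return DefectionBound(bound=min(1.0, raw), s2_irrelevant=False)


def pd_cooperator_defector_relation(
    payoff: PayoffMatrix, p_see: float, x: float
) -> Relation:
    """Relation of the equilibrium defector (0; x; 0) to the conditional
    cooperator (1; 0; 0) in the transparent Prisoner's Dilemma.

    Two inequalities decide the relation: the equilibrium condition

    .. math:: x \\le \\frac{1-p_{see}}{p_{see}} \\frac{P-S}{R-S} \\qquad (i)

    and the payoff-comparison condition

    .. math:: x \\le \\frac{1}{p_{see}} - 2 + \\frac{P-S}{T-R}. \\qquad (ii)

    Both hold: the defector dominates; neither: the cooperator dominates.
    Condition (i) alone means each strategy resists invasion by the other
    (bistability); condition (ii) alone means each invades the other
    (coexistence).  This follows from the payoff comparisons behind the two
    conditions: (i) is "the defector pair is an equilibrium", i.e.
    :math:`E_{11} \\ge E_{21}`, and (ii) is "defectors outscore cooperators
    in a cooperator population", i.e. :math:`E_{12} \\ge E_{22}`.  Boundary
    equalities count as satisfied.
    """
    if classify_game(payoff) != GameClass.PD:
        raise ValueError("payoff matrix is not a Prisoner's Dilemma")
    if not 0.0 < p_see < 1.0:
        raise ValueError(f"p_see={p_see} outside (0, 1)")
    R, S, T, P = payoff.R, payoff.S, payoff.T, payoff.P
    cond_eq = x <= (1.0 - p_see) / p_see * (P - S) / (R - S)
    cond_cmp = x <= 1.0 / p_see - 2.0 + (P - S) / (T - R)
    if cond_eq and cond_cmp:
        return Relation.FIRST_DOMINATES
    if not cond_eq and not cond_cmp:
        return Relation.SECOND_DOMINATES
    if cond_eq:
        return Relation.BISTABLE
    return Relation.COEXIST


# ---------------------------------------------------------------------------
# Transparent Prisoner's Dilemma, unequal reaction times
# ---------------------------------------------------------------------------

def pd_unequal_rt_payoffs(
    payoff: PayoffMatrix, p11: float, p12: float
) -> tuple[float, float, float, float]:
    """2x2 expected-payoff matrix for slow cooperators (1;0;0) vs fast
    defectors (0;0;0) with unequal visibility.

    ``p11`` is the mutual-visibility probability within the cooperator type
    (≤ 0.5); ``p12`` the probability that a cooperator sees a defector's
    choice.  Returns ``(E11, E12, E21, E22)``.
    """
    R, S, T, P = payoff.R, payoff.S, payoff.T, payoff.P
    E11 = R - p11 * (2 * R - S - T)
    E12 = p12 * P + (1 - p12) * S
    E21 = T - p12 * (T - P)
    E22 = P
    return (E11, E12, E21, E22)


def pd_unequal_rt_bistability_threshold(payoff: PayoffMatrix, p11: float) -> float:
    """The visibility level above which cooperators and defectors are bistable:

    .. math:: p_{see}^{12} > \\frac{T-R}{T-P} + \\frac{2R-S-T}{T-P}\\,p_{see}^{11}.

    For the standard Prisoner's Dilemma payoffs and ``p11 = 0.5`` this is 5/8.
    """
    R, S, T, P = payoff.R, payoff.S, payoff.T, payoff.P
    return (T - R) / (T - P) + (2 * R - S - T) / (T - P) * p11


def pd_unequal_rt_classification(
    payoff: PayoffMatrix, p11: float, p12: float
) -> Relation:
    """Classify (1; 0; 0) vs (0; 0; 0) under unequal reaction times.

    The cooperative strategy strictly dominates only in the limit
    ``p12 = 1`` (the cooperator always sees the defector's move); it is
    bistable with the defector above the threshold of
    :func:`pd_unequal_rt_bistability_threshold`, and dominated below it.
    """
    if classify_game(payoff) != GameClass.PD:
        raise ValueError("payoff matrix is not a Prisoner's Dilemma")
    if not 0.0 < p11 <= 0.5:
        raise ValueError(f"p11={p11} outside (0, 0.5]")
    if not 0.0 < p12 <= 1.0:
        raise ValueError(f"p12={p12} outside (0, 1]")
    if p12 == 1.0:
        return Relation.FIRST_DOMINATES
    if p12 > pd_unequal_rt_bistability_threshold(payoff, p11):
        return Relation.BISTABLE
    return Relation.SECOND_DOMINATES


# ---------------------------------------------------------------------------
# Transparent (anti-)coordination games
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NashEquilibrium:
    """A Nash equilibrium of a one-shot transparent game."""

    player1: OneShotStrategy
    player2: OneShotStrategy
    kind: str  # "pure" or "mixed"


def anticoordination_equilibria(
    payoff: PayoffMatrix, p12: float, p21: float
) -> list[NashEquilibrium]:
    """Nash equilibria of a one-shot transparent anti-coordination game.

    Applies to every payoff matrix with ``S > T > R`` and ``S > P`` — the
    Bach-or-Stravinsky preset as well as Hawk-Dove and Leader.  Writing
    :math:`p_{lo} \\le p_{hi}` for the ordered visibility probabilities, when

    .. math:: \\frac{p_{hi}}{1 - p_{lo}} \\le \\frac{T - R}{S - R}

    there are three equilibria: the two pure asymmetric ones — one player
    insists with (1; 0; 1), the other accommodates with (0; 0; 1) — and a
    mixed one where player i insists blindly with probability

    .. math::

       s_1^i = \\frac{(1 - p^{ji})(S - P) - p^{ij}(T - P)}
                    {(1 - p^{ij} - p^{ji})(T + S - P - R)}.

    When only the weaker condition :math:`p_{lo}/(1-p_{hi}) \\le (T-R)/(S-R)`
    holds, the less-seeing player insists and the other accommodates; when
    even that fails, mutual insisting (1; 0; 1) is the unique equilibrium.
    """
    _check_psee(p12, p21)
    R, S, T, P = payoff.R, payoff.S, payoff.T, payoff.P
    if not (S > T > R and S > P):
        raise ValueError(
            "payoff matrix outside the anti-coordination class (requires "
            "S > T > R and S > P)"
        )
    swapped = p12 > p21
    lo, hi = (p21, p12) if swapped else (p12, p21)

    insist = OneShotStrategy(1.0, 0.0, 1.0)
    accommodate = OneShotStrategy(0.0, 0.0, 1.0)
    ratio = (T - R) / (S - R)

    def _oriented(a: OneShotStrategy, b: OneShotStrategy, kind: str) -> NashEquilibrium:
        # a is the low-visibility player's strategy, b the high-visibility one's
        if swapped:
            return NashEquilibrium(player1=b, player2=a, kind=kind)
        return NashEquilibrium(player1=a, player2=b, kind=kind)

    if hi / (1.0 - lo) <= ratio:
        denom = (1.0 - lo - hi) * (T + S - P - R)
        x_lo = ((1.0 - hi) * (S - P) - lo * (T - P)) / denom
        x_hi = ((1.0 - lo) * (S - P) - hi * (T - P)) / denom
        mixed_lo = OneShotStrategy(x_lo, 0.0, 1.0)
        mixed_hi = OneShotStrategy(x_hi, 0.0, 1.0)
        return [
            _oriented(accommodate, insist, "pure"),
            _oriented(insist, accommodate, "pure"),
            _oriented(mixed_lo, mixed_hi, "mixed"),
        ]
    if lo / (1.0 - hi) <= ratio:
        # only the low-visibility player can credibly insist
        return [_oriented(insist, accommodate, "pure")]
    return [NashEquilibrium(player1=insist, player2=insist, kind="pure")]


# ---------------------------------------------------------------------------
# Finite-horizon risk of Leader-Follower play
# ---------------------------------------------------------------------------

def lf_vs_alld_risk(n: int, payoff: PayoffMatrix) -> float:
    """Probability that n rounds of Leader-Follower play against a pure
    Leader-Follower partner fall short of the all-defection baseline.

    At :math:`p_{see} = 0.5` the Leader/Follower roles are fair coin flips
    each round; a pure Leader-Follower earns T in Leader rounds and S = 0 in
    Follower rounds.  The player's total stays below the mutual-defection
    baseline :math:`nP` exactly when the number of Leader rounds j satisfies
    :math:`jT < nP`, giving

    .. math:: 2^{-n} \\sum_{j=0}^{\\lfloor nP/T \\rfloor} \\binom{n}{j}

    (the boundary term with :math:`jT = nP`, possible only when ``nP/T`` is
    an integer, is included, matching the closed form).
    """
    if classify_game(payoff) != GameClass.PD:
        raise ValueError("payoff matrix is not a Prisoner's Dilemma")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    kmax = math.floor(n * payoff.P / payoff.T)
    total = sum(math.comb(n, j) for j in range(kmax + 1))
    return total / 2.0 ** n
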