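"""Two-strategy competition: dominance, bistability, coexistence, invasion.

Writing :math:`E_{ij}` for the expected payoff of strategy i against
strategy j, a pair of strategies falls into one of four generic classes:

* the first *dominates* when :math:`E_{11} \\ge E_{21}` and
  :math:`E_{12} \\ge E_{22}` (at least one strict),
* *bistable* when :math:`E_{11} > E_{21}` but :math:`E_{12} < E_{22}` —
  whichever strategy is common enough wins,
* *coexistence* when :math:`E_{11} < E_{21}` but :math:`E_{12} > E_{22}` —
  the replicator dynamics settles at an interior equilibrium,
* NEUTRAL when all payoff differences vanish (identical strategies).

For bistable and coexisting pairs the invasion threshold

.. math:: h_1 = \\frac{E_{22} - E_{12}}{E_{11} - E_{12} - E_{21} + E_{22}}

is the frequency at which the dynamics flips direction (unstable equilibrium
when bistable) or settles (stable equilibrium under coexistence).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .engine import expected_payoff_pair
from .games import PayoffMatrix
from .strategies import MemoryOneStrategy

__all__ = [
    "Relation",
    "PairwiseAssessment",
    "classify_pair",
    "invasion_threshold",
    "assess_pair",
    "two_type_trajectory",
    "transparency_sweep",
    "DEFAULT_TOLERANCE",
]

DEFAULT_TOLERANCE = 1e-9


class Relation(enum.Enum):
    FIRST_DOMINATES = "first_dominates"
    SECOND_DOMINATES = "second_dominates"
    BISTABLE = "bistable"
    COEXIST = "coexist"
    NEUTRAL = "neutral"


def classify_pair(
    E11: float, E12: float, E21: float, E22: float,
    tolerance: float = DEFAULT_TOLERANCE,
) -> Relation:
    """Classify the competition between two strategies from their payoffs.

    Differences within ``tolerance`` count as equalities; a pair whose
    payoff differences both vanish is NEUTRAL.
    """
    d1 = E11 - E21  # edge where the first strategy is common
    d2 = E12 - E22  # edge where the first strategy is rare
    z1 = abs(d1) <= tolerance
    z2 = abs(d2) <= tolerance
    if z1 and z2:
        return Relation.NEUTRAL
    if d1 >= -tolerance and d2 >= -tolerance:
        return Relation.FIRST_DOMINATES
    if d1 <= tolerance and d2 <= tolerance:
        return Relation.SECOND_DOMINATES
    if d1 > 0 and d2 < 0:
        return Relation.BISTABLE
    return Relation.COEXIST


def invasion_threshold(E11: float, E12: float, E21: float, E22: float) -> float:
    """Interior equilibrium frequency of the first strategy (bistable or
    coexisting pairs only)."""
    denom = E11 - E12 - E21 + E22
    if abs(denom) < 1e-15:
        raise ValueError("degenerate pair: E11 - E12 - E21 + E22 = 0")
    h = (E22 - E12) / denom
    return h


@dataclass(frozen=True)
class PairwiseAssessment:
    """Payoffs, relation class and invasion threshold of a strategy pair."""

    E11: float
    E12: float
    E21: float
    E22: float
    relation: Relation
    threshold: float | None
    threshold_kind: str  # "unstable", "stable" or "none"

    def __post_init__(self) -> None:
        has_thr = self.relation in (Relation.BISTABLE, Relation.COEXIST)
        if has_thr != (self.threshold is not None):
            raise ValueError("threshold must be present iff bistable/coexist")


def assess_pair(
    s1: MemoryOneStrategy,
    s2: MemoryOneStrategy,
    p_see: float,
    payoff: PayoffMatrix,
    tolerance: float = DEFAULT_TOLERANCE,
) -> PairwiseAssessment:
    """Full pairwise assessment of two memory-one strategies at equal
    visibility ``p_see`` for both players."""
    E11, _ = expected_payoff_pair(s1, s1, p_see, p_see, payoff)
    E12, E21 = expected_payoff_pair(s1, s2, p_see, p_see, payoff)
    E22, _ = expected_payoff_pair(s2, s2, p_see, p_see, payoff)
    relation = classify_pair(E11, E12, E21, E22, tolerance)
    if relation in (Relation.BISTABLE, Relation.COEXIST):
        thr = invasion_threshold(E11, E12, E21, E22)
        kind = "unstable" if relation == Relation.BISTABLE else "stable"
    else:
        thr, kind = None, "none"
    return PairwiseAssessment(E11=E11, E12=E12, E21=E21, E22=E22,
                              relation=relation, threshold=thr,
                              threshold_kind=kind)


def two_type_trajectory(
    s1: MemoryOneStrategy,
    s2: MemoryOneStrategy,
    x0: float,
    p_see: float,
    payoff: PayoffMatrix,
    generations: int,
) -> np.ndarray:
    """Replicator trajectory x1(t), t = 1..generations, of a two-type
    population.

    Fitnesses are the population-weighted payoffs
    :math:`f_1 = x_1 E_{11} + x_2 E_{12}`,
    :math:`f_2 = x_1 E_{21} + x_2 E_{22}`, and frequencies update
    multiplicatively by relative fitness,
    :math:`x_1(t+1) = x_1(t)\\, f_1(t)/\\bar f(t)`.
    """
    if not 0.0 <= x0 <= 1.0:
        raise ValueError(f"x0={x0} outside [0, 1]")
    a = assess_pair(s1, s2, p_see, payoff)
    E = np.array([[a.E11, a.E12], [a.E21, a.E22]])
    if E.max() <= 0:
        raise ValueError("all payoffs <= 0: mean fitness must be positive")
    x = x0
    out = np.empty(generations)
    for t in range(generations):
        f1 = x * E[0, 0] + (1 - x) * E[0, 1]
        f2 = x * E[1, 0] + (1 - x) * E[1, 1]
        fbar = x * f1 + (1 - x) * f2
        if fbar <= 0:
            raise ValueError("mean fitness is non-positive; replicator map undefined")
        x = x * f1 / fbar
        out[t] = x
    return out


def transparency_sweep(
    s1: MemoryOneStrategy,
    s2: MemoryOneStrategy,
    payoff: PayoffMatrix,
    p_grid: Sequence[float],
) -> list[tuple[float, PairwiseAssessment]]:
    """Pairwise assessment at every visibility level of a grid in [0, 0.5].

    The output supports reconstructing invasion-map style summaries: for each
    ``p_see`` the relation class and (where defined) the invasion threshold.
    """
    for p in p_grid:
        if not 0.0 <= p <= 0.5:
            raise ValueError(f"grid value {p} outside [0, 0.5]")
    return [(float(p), assess_pair(s1, s2, float(p), payoff)) for p in p_grid]
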