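"""Payoff matrices, game classes and shared conventions.

Both games studied here are symmetric two-player, two-action games.  A payoff
matrix is written in the standard (R, S, T, P) notation: the focal player
receives

* ``R`` when both players choose action :math:`A_1` (mutual cooperation in the
  Prisoner's Dilemma, mutual insisting in the anti-coordination games),
* ``S`` when the focal player chooses :math:`A_1` and the partner :math:`A_2`,
* ``T`` when the focal player chooses :math:`A_2` and the partner :math:`A_1`,
* ``P`` when both choose :math:`A_2`.

All modules share one state-order convention: the four joint outcomes are
ordered ``(A1A1, A1A2, A2A1, A2A2)`` from the focal player's perspective,
mapping to the payoffs ``(R, S, T, P)`` in that order.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass

__all__ = [
    "GameClass",
    "PayoffMatrix",
    "GameSpec",
    "classify_game",
    "get_preset",
    "payoff_from_json",
    "STATE_ORDER",
    "PRESETS",
]

#: Joint-outcome order used by every matrix and stationary vector in the
#: package, from the focal player's perspective.
STATE_ORDER = ("A1A1", "A1A2", "A2A1", "A2A2")


class GameClass(enum.Enum):
    """Strict-ordering game classes.

    ``PD``        T > R > P > S (Prisoner's Dilemma)
    ``ACG``       S > T > R > P (anti-coordination, Bach-or-Stravinsky)
    ``HAWK_DOVE`` S > P > T > R
    ``LEADER``    S > T > P > R
    ``OTHER``     anything else, including ties.
    """

    PD = "PD"
    ACG = "ACG"
    HAWK_DOVE = "HAWK_DOVE"
    LEADER = "LEADER"
    OTHER = "OTHER"


@dataclass(frozen=True)
class PayoffMatrix:
    """The four payoffs of a symmetric 2x2 game, in reward units."""

    R: float
    S: float
    T: float
    P: float

    def __post_init__(self) -> None:
        for name in ("R", "S", "T", "P"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"payoff {name} must be finite, got {v!r}")

    def as_vector(self) -> tuple[float, float, float, float]:
        """Payoffs in the shared state order (R, S, T, P)."""
        return (self.R, self.S, self.T, self.P)

    def replace_R(self, R: float) -> "PayoffMatrix":
        return PayoffMatrix(R=R, S=self.S, T=self.T, P=self.P)


def classify_game(payoff: PayoffMatrix) -> GameClass:
    """Classify a payoff matrix by the strict ordering of its entries.

    Ties (non-strict orderings) classify as ``OTHER``: the analytical results
    for all four named classes assume strict inequalities.
    """
    R, S, T, P = payoff.R, payoff.S, payoff.T, payoff.P
    if T > R > P > S:
        return GameClass.PD
    if S > T > R > P:
        return GameClass.ACG
    if S > P > T > R:
        return GameClass.HAWK_DOVE
    if S > T > P > R:
        return GameClass.LEADER
    return GameClass.OTHER


@dataclass(frozen=True)
class GameSpec:
    """A payoff matrix together with its class and bookkeeping metadata.

    ``max_mean_payoff`` is the ceiling used by the cooperation metrics: the
    highest per-round payoff a homogeneous population can average.  For the
    Prisoner's Dilemma preset this is ``R`` (mutual cooperation); for the
    anti-coordination preset it is ``(S+T)/2`` (alternating or role-split
    coordination).
    """

    payoff: PayoffMatrix
    game_class: GameClass
    action_labels: tuple[str, str]
    max_mean_payoff: float

    def __post_init__(self) -> None:
        if self.game_class != classify_game(self.payoff):
            raise ValueError(
                f"game_class {self.game_class} inconsistent with payoffs "
                f"{self.payoff} -> {classify_game(self.payoff)}"
            )


def _make_spec(payoff: PayoffMatrix, labels: tuple[str, str]) -> GameSpec:
    cls = classify_game(payoff)
    if cls == GameClass.PD:
        ceiling = payoff.R
    else:
        ceiling = (payoff.S + payoff.T) / 2.0
    return GameSpec(payoff=payoff, game_class=cls, action_labels=labels,
                    max_mean_payoff=ceiling)


PRESETS: dict[str, GameSpec] = {
    "ipd": _make_spec(PayoffMatrix(R=3, S=0, T=5, P=1), ("C", "D")),
    "iacg": _make_spec(PayoffMatrix(R=2, S=4, T=3, P=1), ("I", "A")),
    "hawkdove": _make_spec(PayoffMatrix(R=1, S=4, T=2, P=3), ("Hawk", "Dove")),
    "leader": _make_spec(PayoffMatrix(R=1, S=4, T=3, P=2), ("I", "A")),
}


def get_preset(name: str) -> GameSpec:
    """Look up a bundled game preset by name (``ipd``, ``iacg``, ``hawkdove``, ``leader``)."""
    try:
        return PRESETS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown game preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def payoff_from_json(text: str) -> PayoffMatrix:
    """Parse an explicit ``{"R":..,"S":..,"T":..,"P":..}`` JSON payoff object."""
    obj = json.loads(text)
    missing = {"R", "S", "T", "P"} - set(obj)
    if missing:
        raise ValueError(f"payoff JSON missing keys: {sorted(missing)}")
    return PayoffMatrix(R=float(obj["R"]), S=float(obj["S"]),
                        T=float(obj["T"]), P=float(obj["P"]))
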