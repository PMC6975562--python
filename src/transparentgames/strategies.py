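"""One-shot and memory-one strategies, random sampling and classification.

A one-shot strategy in a transparent game is a vector ``(s1; s2; s3)``:

* ``s1`` — probability of choosing action :math:`A_1` without seeing the
  partner's current choice,
* ``s2`` — probability of choosing :math:`A_1` while seeing the partner
  choose :math:`A_1`,
* ``s3`` — probability of choosing :math:`A_1` while seeing the partner
  choose :math:`A_2`.

A memory-one strategy extends this by conditioning on the previous round's
joint outcome, giving 12 entries ``s1..s12``: entries 1–4 are the unseen
probabilities after previous outcomes ``A1A1, A1A2, A2A1, A2A2`` (own action
first), entries 5–8 apply when the partner is seen choosing :math:`A_1`, and
entries 9–12 when the partner is seen choosing :math:`A_2`.

Evolved strategies are reported with a coarse-grained 12-token notation:
``0`` for an entry ≤ 0.1, ``1`` for ≥ 0.9, ``*`` for an arbitrary value,
and named interval bounds (``a``, ``b``, ``c``, ``d``) for specific classes.
The bundled pattern library (``data/patterns.json``) encodes the named
strategy classes for the iterated Prisoner's Dilemma and anti-coordination
game in this notation, in the precedence order used for classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence, Union

import numpy as np

from .games import GameClass

__all__ = [
    "OneShotStrategy",
    "MemoryOneStrategy",
    "PatternToken",
    "StrategyPattern",
    "pattern_library",
    "sample_random_strategy",
    "match_pattern",
    "classify_strategy",
    "DEFAULT_EPSILON",
]

DEFAULT_EPSILON = 0.001

#: ZERO / ONE coarse-graining thresholds (inclusive).
ZERO_MAX = 0.1
ONE_MIN = 0.9


@dataclass(frozen=True)
class OneShotStrategy:
    """Memoryless strategy ``(s1; s2; s3)`` for a one-shot transparent game."""

    s1: float
    s2: float
    s3: float

    def __post_init__(self) -> None:
        for name in ("s1", "s2", "s3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.s1, self.s2, self.s3)


@dataclass(frozen=True)
class MemoryOneStrategy:
    """A 12-entry conditional-probability vector with an error floor ``epsilon``.

    Entries are conditional probabilities of choosing :math:`A_1`, confined to
    ``[epsilon, 1 - epsilon]`` to model execution errors ("trembling hand").
    ``epsilon = 0`` (pure strategies) is permitted but must be requested
    explicitly; the iterated-game engine then checks ergodicity itself.
    """

    s: tuple[float, ...]
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if len(self.s) != 12:
            raise ValueError(f"memory-one strategy needs 12 entries, got {len(self.s)}")
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError(f"epsilon={self.epsilon} outside [0, 0.5)")
        lo, hi = self.epsilon, 1.0 - self.epsilon
        for k, v in enumerate(self.s, start=1):
            if not lo - 1e-12 <= v <= hi + 1e-12:
                raise ValueError(f"s{k}={v} outside [{lo}, {hi}]")
        object.__setattr__(self, "s", tuple(float(v) for v in self.s))

    @classmethod
    def from_pure(cls, values: Iterable[float],
                  epsilon: float = DEFAULT_EPSILON) -> "MemoryOneStrategy":
        """Build from 0/1 (or fractional) entries with epsilon substitution.

        Entries equal to 0 become ``epsilon`` and entries equal to 1 become
        ``1 - epsilon``; interior entries pass through unchanged.
        """
        subs = tuple(
            epsilon if v == 0 else (1.0 - epsilon if v == 1 else float(v))
            for v in values
        )
        return cls(s=subs, epsilon=epsilon)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.s, dtype=float)

    def to_json(self) -> str:
        return json.dumps(list(self.s))

    @classmethod
    def from_json(cls, text: str,
                  epsilon: float = DEFAULT_EPSILON) -> "MemoryOneStrategy":
        return cls(s=tuple(json.loads(text)), epsilon=epsilon)


# ---------------------------------------------------------------------------
# Random strategies
# ---------------------------------------------------------------------------

def sample_random_strategy(
    rng: Union[int, np.random.Generator, None],
    epsilon: float = DEFAULT_EPSILON,
) -> MemoryOneStrategy:
    """Draw a random memory-one strategy from the arcsine density.

    Each of the 12 entries is an independent draw from the U-shaped arcsine
    density :math:`\\rho(y) = \\frac{1}{\\pi}(y(1-y))^{-1/2}` on (0, 1)
    (a Beta(1/2, 1/2) distribution, favouring values near 0 and 1), clipped
    into ``[epsilon, 1 - epsilon]``.
    """
    if not 0.0 < epsilon < 0.5:
        raise ValueError(f"epsilon={epsilon} outside (0, 0.5)")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    draws = gen.beta(0.5, 0.5, size=12)
    clipped = np.clip(draws, epsilon, 1.0 - epsilon)
    return MemoryOneStrategy(s=tuple(clipped), epsilon=epsilon)


# ---------------------------------------------------------------------------
# Patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternToken:
    """One position of a coarse-grained pattern.

    ``kind`` is ``"zero"`` (entry ≤ 0.1), ``"one"`` (entry ≥ 0.9), ``"wild"``
    (any entry) or ``"range"`` with explicit bounds and open/closed flags.
    """

    kind: str
    lo: float = 0.0
    hi: float = 1.0
    lo_open: bool = False
    hi_open: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("zero", "one", "wild", "range"):
            raise ValueError(f"unknown token kind {self.kind!r}")
        if self.kind == "range" and not 0.0 <= self.lo < self.hi <= 1.0:
            raise ValueError(f"range bounds [{self.lo}, {self.hi}] invalid")

    def matches(self, value: float) -> bool:
        if self.kind == "wild":
            return True
        if self.kind == "zero":
            return value <= ZERO_MAX
        if self.kind == "one":
            return value >= ONE_MIN
        lo_ok = value > self.lo if self.lo_open else value >= self.lo
        hi_ok = value < self.hi if self.hi_open else value <= self.hi
        return lo_ok and hi_ok


def _parse_token(raw) -> PatternToken:
    if raw == "0":
        return PatternToken(kind="zero")
    if raw == "1":
        return PatternToken(kind="one")
    if raw == "*":
        return PatternToken(kind="wild")
    return PatternToken(kind="range", lo=float(raw["lo"]), hi=float(raw["hi"]),
                        lo_open=bool(raw.get("lo_open", False)),
                        hi_open=bool(raw.get("hi_open", False)))


@dataclass(frozen=True)
class StrategyPattern:
    """A named 12-token coarse-grained pattern for one game class.

    ``any_gt`` is an optional disjunctive side condition: a list of
    ``(index, threshold)`` pairs of which at least one must satisfy
    ``s[index] > threshold`` (used by the generous win-stay-lose-shift class,
    whose interior entries must not both be coarse zeros).
    """

    name: str
    game_class: GameClass
    tokens: tuple[PatternToken, ...]
    descriptor: str = ""
    any_gt: tuple[tuple[int, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.tokens) != 12:
            raise ValueError(f"pattern {self.name!r} needs 12 tokens")


def match_pattern(strategy: MemoryOneStrategy, pattern: StrategyPattern) -> bool:
    """True iff every strategy entry satisfies the corresponding token
    and any disjunctive side condition holds."""
    if not all(tok.matches(v) for tok, v in zip(pattern.tokens, strategy.s)):
        return False
    if pattern.any_gt:
        return any(strategy.s[i] > thr for i, thr in pattern.any_gt)
    return True


def _load_library() -> dict[GameClass, tuple[StrategyPattern, ...]]:
    text = resources.files("transparentgames.data").joinpath("patterns.json").read_text()
    raw = json.loads(text)
    lib: dict[GameClass, tuple[StrategyPattern, ...]] = {}
    for key, entries in raw.items():
        gc = GameClass[key]
        pats = tuple(
            StrategyPattern(
                name=e["name"],
                game_class=gc,
                tokens=tuple(_parse_token(t) for t in e["tokens"]),
                descriptor=e.get("descriptor", ""),
                any_gt=tuple((int(i), float(t)) for i, t in e.get("any_gt", [])),
            )
            for e in entries
        )
        lib[gc] = pats
    return lib


_LIBRARY: dict[GameClass, tuple[StrategyPattern, ...]] | None = None


def pattern_library(game_class: GameClass) -> tuple[StrategyPattern, ...]:
    """The ordered pattern list for a game class (most specific first)."""
    global _LIBRARY
    if _LIBRARY is None:
        _LIBRARY = _load_library()
    try:
        return _LIBRARY[game_class]
    except KeyError:
        raise ValueError(
            f"no pattern library for game class {game_class}; "
            f"supported: PD, ACG"
        ) from None


def classify_strategy(
    strategy: MemoryOneStrategy, game_class: GameClass
) -> str:
    """Name the coarse-grained class of a memory-one strategy.

    Patterns are tested in the library's order and the first match wins; a
    strategy matching no pattern is labelled ``"other"`` (rare transient
    strategies in the evolutionary runs).
    """
    for pattern in pattern_library(game_class):
        if match_pattern(strategy, pattern):
            return pattern.name
    return "other"


def classify_strategies(
    strategies: Sequence[MemoryOneStrategy], game_class: GameClass
) -> list[str]:
    return [classify_strategy(s, game_class) for s in strategies]
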