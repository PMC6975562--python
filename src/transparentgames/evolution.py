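"""Infinite-population replicator-dynamics evolution of memory-one strategies.

The population holds :math:`n(t)` strategy types with frequencies
:math:`x_i(t)` summing to one.  Each generation:

1. **Selection.**  Every type's fitness is its mean payoff against the
   current population, :math:`f_i = \\sum_j x_j E_{ij}` (self-play included:
   the population is infinite), and frequencies update by the discrete
   replicator equation :math:`x_i(t+1) = x_i(t) f_i(t) / \\bar f(t)`.
2. **Extinction.**  Types whose frequency drops below the threshold
   :math:`\\chi` (default 0.001) are removed, their share redistributed
   proportionally among the survivors.
3. **Innovation.**  With probability ``1/intro_rate`` per generation
   (default: once per 100 generations on average, desynchronised), a fresh
   random strategy drawn from the arcsine density enters at frequency
   :math:`1.1\\chi`.

Pairwise payoffs :math:`E_{ij}` come from the stationary distribution of the
transparent-game Markov chain and are computed lazily when a type first
appears, then cached.

Runs are summarised the way long evolutionary experiments are reported:
each type that survives more than 1000 generations contributes its summed
frequency mass to its coarse-grained strategy class; shorter-lived types
count as rare transient strategies ("other").  Cooperation is tracked at
logarithmically spaced checkpoints as the population mean payoff relative to
the game's ceiling (0.9 of the mutual-cooperation payoff in the Prisoner's
Dilemma, 0.95 of the coordination payoff (S+T)/2 in the anti-coordination
game), together with the forfeit payoff (ceiling minus actual mean).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import _component_matrices, expected_payoff_pair
from .games import GameClass, GameSpec, PayoffMatrix, classify_game
from .strategies import (DEFAULT_EPSILON, MemoryOneStrategy, classify_strategy,
                         sample_random_strategy)

__all__ = [
    "EvolutionConfig",
    "PopulationState",
    "PayoffCache",
    "TypeRecord",
    "RunSummary",
    "replicator_step",
    "apply_extinction",
    "introduce_type",
    "run_evolution",
    "cooperation_metrics",
    "aggregate_runs",
    "default_checkpoints",
    "SURVIVAL_GENERATIONS",
]

#: Minimum lifetime (in generations) for a type to count towards the named
#: strategy-class shares rather than the transient pool.
SURVIVAL_GENERATIONS = 1000

_COOP_FACTOR = {GameClass.PD: 0.9, GameClass.ACG: 0.95}

logger = logging.getLogger("transparentgames.evolution")

_EYE4 = np.eye(4)
_RHS = np.array([0.0, 0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# Configuration and state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvolutionConfig:
    """Simulation parameters.  Defaults are the study conditions: error floor
    and extinction threshold 0.001, five random founder types at frequency
    0.2 each, one random introduction per 100 generations on average at
    frequency 1.1 chi."""

    game: GameSpec
    p_see: float
    generations: int
    seed: int | None = None
    epsilon: float = DEFAULT_EPSILON
    chi: float = 0.001
    init_types: int = 5
    init_freq: float = 0.2
    intro_rate: float = 100.0
    intro_freq: float = 1.1 * 0.001
    R_override: float | None = None
    init_strategies: tuple[MemoryOneStrategy, ...] | None = None
    checkpoints: tuple[int, ...] | None = None
    track_frequencies: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_see <= 0.5:
            raise ValueError(f"p_see={self.p_see} outside [0, 0.5]")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not 0.0 < self.chi < 1.0:
            raise ValueError(f"chi={self.chi} outside (0, 1)")

    @property
    def payoff(self) -> PayoffMatrix:
        if self.R_override is None:
            return self.game.payoff
        return self.game.payoff.replace_R(self.R_override)

    @property
    def max_mean_payoff(self) -> float:
        if self.R_override is None:
            return self.game.max_mean_payoff
        p = self.payoff
        if self.game.game_class == GameClass.PD:
            return p.R
        return (p.S + p.T) / 2.0


@dataclass
class PopulationState:
    """Named strategy types with frequencies and birth generations."""

    strategies: list[MemoryOneStrategy]
    frequencies: np.ndarray
    birth_generations: list[int]
    generation: int = 0

    @property
    def n(self) -> int:
        return len(self.strategies)

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("population needs at least one type")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {self.frequencies.sum()}, not 1")


class PayoffCache:
    """Lazy cache of pairwise expected payoffs for one game and visibility.

    Keyed by the 12-entry strategy tuples; one stationary-distribution solve
    fills both directions of a pair.
    """

    def __init__(self, payoff: PayoffMatrix, p12: float, p21: float | None = None):
        self.payoff = payoff
        self.p12 = p12
        self.p21 = p12 if p21 is None else p21
        self._store: dict[tuple, float] = {}

    def get(self, s_i: MemoryOneStrategy, s_j: MemoryOneStrategy) -> float:
        key = (s_i.s, s_j.s)
        if key not in self._store:
            e_ij, e_ji = expected_payoff_pair(s_i, s_j, self.p12, self.p21, self.payoff)
            self._store[key] = e_ij
            self._store[(s_j.s, s_i.s)] = e_ji
        return self._store[key]

    def matrix(self, strategies: Sequence[MemoryOneStrategy]) -> np.ndarray:
        n = len(strategies)
        E = np.empty((n, n))
        for i, si in enumerate(strategies):
            for j, sj in enumerate(strategies):
                E[i, j] = self.get(si, sj)
        return E


# ---------------------------------------------------------------------------
# Elementary generation operations (also used standalone in tests/CLI)
# ---------------------------------------------------------------------------

def replicator_step(pop: PopulationState, cache: PayoffCache) -> PopulationState:
    """One discrete replicator update of the type frequencies."""
    pop.validate()
    E = cache.matrix(pop.strategies)
    x = pop.frequencies
    f = E @ x
    fbar = float(x @ f)
    if fbar <= 0:
        raise ValueError("mean fitness is non-positive; replicator map undefined")
    x_new = x * f / fbar
    return PopulationState(strategies=list(pop.strategies),
                           frequencies=x_new,
                           birth_generations=list(pop.birth_generations),
                           generation=pop.generation + 1)


def apply_extinction(pop: PopulationState, chi: float) -> PopulationState:
    """Remove types below the extinction threshold, redistributing their
    share proportionally; the largest type always survives."""
    x = pop.frequencies
    keep = x >= chi
    if not keep.any():
        keep = x == x.max()
        # ties: keep only the first maximal type
        first = int(np.flatnonzero(keep)[0])
        keep = np.zeros_like(keep)
        keep[first] = True
    if keep.all():
        return pop
    x_kept = x[keep]
    x_kept = x_kept / x_kept.sum()
    return PopulationState(
        strategies=[s for s, k in zip(pop.strategies, keep) if k],
        frequencies=x_kept,
        birth_generations=[b for b, k in zip(pop.birth_generations, keep) if k],
        generation=pop.generation,
    )


def introduce_type(
    pop: PopulationState,
    rng: np.random.Generator,
    epsilon: float = DEFAULT_EPSILON,
    intro_rate: float = 100.0,
    intro_freq: float = 1.1 * 0.001,
) -> PopulationState:
    """With probability ``1/intro_rate``, add one random arcsine-drawn type
    at frequency ``intro_freq``, scaling existing frequencies down."""
    if rng.random() >= 1.0 / intro_rate:
        return pop
    newcomer = sample_random_strategy(rng, epsilon)
    x = pop.frequencies * (1.0 - intro_freq)
    return PopulationState(
        strategies=list(pop.strategies) + [newcomer],
        frequencies=np.append(x, intro_freq),
        birth_generations=list(pop.birth_generations) + [pop.generation],
        generation=pop.generation,
    )


def cooperation_metrics(
    pop: "PopulationState | float",
    game: GameSpec,
    cache: PayoffCache | None = None,
    max_mean_payoff: float | None = None,
) -> tuple[bool, float]:
    """Cooperation flag and forfeit payoff of a population.

    ``pop`` may be a PopulationState (whose mean payoff is then computed
    through the cache) or the mean payoff itself.  A population counts as
    cooperative when its mean payoff exceeds 0.9 of the ceiling in the
    Prisoner's Dilemma or 0.95 of the ceiling in the anti-coordination game;
    the forfeit is ceiling minus actual mean payoff.
    """
    factor = _COOP_FACTOR.get(game.game_class)
    if factor is None:
        raise ValueError(f"cooperation metrics undefined for {game.game_class}")
    ceiling = game.max_mean_payoff if max_mean_payoff is None else max_mean_payoff
    if isinstance(pop, PopulationState):
        if cache is None:
            raise ValueError("a PayoffCache is required to evaluate a population")
        E = cache.matrix(pop.strategies)
        x = pop.frequencies
        fbar = float(x @ (E @ x))
    else:
        fbar = float(pop)
    return fbar > factor * ceiling, ceiling - fbar


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------

def default_checkpoints(generations: int) -> tuple[int, ...]:
    """Logarithmic checkpoints: 1, 3, 10, 30, ... up to the final generation."""
    cps: list[int] = []
    k = 0
    while True:
        for base in (10 ** k, 3 * 10 ** k):
            if base <= generations:
                cps.append(base)
        if 10 ** (k + 1) > generations:
            break
        k += 1
    if generations >= 1 and (not cps or cps[-1] != generations):
        cps.append(generations)
    return tuple(sorted(set(cps)))


@dataclass(frozen=True)
class TypeRecord:
    """Per-type bookkeeping of a finished run."""

    strategy: tuple[float, ...]
    birth: int
    death: int  # generation of removal, or final generation if still alive
    mass: float  # summed frequency over its lifetime
    label: str


@dataclass
class RunSummary:
    """Aggregated outcome of one evolutionary run."""

    config: EvolutionConfig
    class_shares: dict[str, float]
    checkpoints: tuple[int, ...]
    cooperation_series: list[bool]
    forfeit_series: list[float]
    mean_payoff_series: list[float]
    first_cooperative_generation: int | None
    survivor_records: list[TypeRecord]
    n_introductions: int
    total_mass: float
    frequency_history: list[np.ndarray] | None = None


def _fast_pair(a: np.ndarray, b: np.ndarray, p12: float, p21: float,
               vec_f: np.ndarray, vec_p: np.ndarray) -> tuple[float, float]:
    """Both-direction expected payoffs without validation overhead."""
    M0, M1, M2 = _component_matrices(a, b)
    M = (1.0 - p12 - p21) * M0 + p12 * M1 + p21 * M2
    A = M.T - _EYE4
    A[3, :] = 1.0
    y = np.linalg.solve(A, _RHS)
    return float(y @ vec_f), float(y @ vec_p)


def run_evolution(config: EvolutionConfig) -> RunSummary:
    """Run one full evolutionary simulation and summarise it."""
    game = config.game
    payoff = config.payoff
    if classify_game(game.payoff) not in (GameClass.PD, GameClass.ACG):
        raise ValueError("evolution runs support the PD and ACG presets")
    R, S, T, P = payoff.as_vector()
    vec_f = np.array((R, S, T, P))
    vec_p = np.array((R, T, S, P))
    p = config.p_see
    chi = config.chi
    G = config.generations
    rng = np.random.default_rng(config.seed)
    ceiling = config.max_mean_payoff
    coop_factor = _COOP_FACTOR[game.game_class]
    cps = config.checkpoints if config.checkpoints is not None else default_checkpoints(G)
    cps = tuple(sorted(set(cps)))

    # --- founders -----------------------------------------------------------
    if config.init_strategies is not None:
        founders = [s.as_array() for s in config.init_strategies]
        x = np.full(len(founders), 1.0 / len(founders))
    else:
        founders = [sample_random_strategy(rng, config.epsilon).as_array()
                    for _ in range(config.init_types)]
        x = np.full(config.init_types, config.init_freq)
        x = x / x.sum()
    strategies = founders
    birth = [0] * len(strategies)
    mass = np.zeros(len(strategies))
    n = len(strategies)
    E = np.empty((n, n))
    for i in range(n):
        E[i, i], _ = _fast_pair(strategies[i], strategies[i], p, p, vec_f, vec_p)
        for j in range(i + 1, n):
            E[i, j], E[j, i] = _fast_pair(strategies[i], strategies[j], p, p, vec_f, vec_p)

    records: list[TypeRecord] = []
    coop_series: list[bool] = []
    forfeit_series: list[float] = []
    payoff_series: list[float] = []
    first_coop: int | None = None
    history = [] if config.track_frequencies else None

    intro_p = 1.0 / config.intro_rate if math.isfinite(config.intro_rate) else 0.0
    u_intro = rng.random(G) if intro_p > 0 and G > 0 else None
    n_intro = 0
    cp_idx = 0
    game_class = game.game_class

    def _finalize(idx: int, gen: int) -> None:
        records.append(TypeRecord(
            strategy=tuple(strategies[idx]), birth=birth[idx], death=gen,
            mass=float(mass[idx]), label=""))

    for t in range(1, G + 1):
        # selection
        f = E @ x
        fbar = float(x @ f)
        if fbar <= 0:
            raise ValueError("mean fitness is non-positive; replicator map undefined")
        x = x * (f / fbar)
        # extinction
        if x.min() < chi:
            keep = x >= chi
            if not keep.any():
                keep = np.zeros_like(keep)
                keep[int(np.argmax(x))] = True
            for idx in np.flatnonzero(~keep):
                _finalize(int(idx), t)
                if logger.isEnabledFor(logging.DEBUG):
                    logger.debug("generation %d: extinction of type born at %d",
                                 t, birth[int(idx)])
            kl = keep.tolist()
            strategies = [s for s, k in zip(strategies, kl) if k]
            birth = [b for b, k in zip(birth, kl) if k]
            mass = mass[keep]
            x = x[keep]
            x = x / x.sum()
            E = E[np.ix_(keep, keep)]
        # introduction
        if u_intro is not None and u_intro[t - 1] < intro_p:
            n_intro += 1
            newcomer = sample_random_strategy(rng, config.epsilon).as_array()
            if logger.isEnabledFor(logging.DEBUG):
                logger.debug(
                    "generation %d: introduced %s (%s)", t,
                    np.array2string(newcomer, precision=3),
                    classify_strategy(MemoryOneStrategy(
                        s=tuple(newcomer), epsilon=config.epsilon), game_class))
            m = len(strategies)
            E_new = np.empty((m + 1, m + 1))
            E_new[:m, :m] = E
            for j in range(m):
                E_new[m, j], E_new[j, m] = _fast_pair(newcomer, strategies[j],
                                                      p, p, vec_f, vec_p)
            E_new[m, m], _ = _fast_pair(newcomer, newcomer, p, p, vec_f, vec_p)
            E = E_new
            strategies.append(newcomer)
            birth.append(t)
            mass = np.append(mass, 0.0)
            x = np.append(x * (1.0 - config.intro_freq), config.intro_freq)
        # bookkeeping
        mass += x
        if history is not None:
            history.append(x.copy())
        fbar_now = float(x @ (E @ x))
        if first_coop is None and fbar_now > coop_factor * ceiling:
            first_coop = t
        if cp_idx < len(cps) and t == cps[cp_idx]:
            payoff_series.append(fbar_now)
            coop_series.append(fbar_now > coop_factor * ceiling)
            forfeit_series.append(ceiling - fbar_now)
            cp_idx += 1

    for idx in range(len(strategies)):
        _finalize(idx, G)

    # --- class shares -------------------------------------------------------
    class_names = [pat.name for pat in _class_order(game_class)]
    shares = {name: 0.0 for name in class_names}
    shares["other"] = 0.0
    total_mass = float(G)
    survivors: list[TypeRecord] = []
    for rec in records:
        lifetime = rec.death - rec.birth
        if lifetime > SURVIVAL_GENERATIONS:
            strat = MemoryOneStrategy(s=rec.strategy, epsilon=config.epsilon)
            label = classify_strategy(strat, game_class)
            survivors.append(replace(rec, label=label))
            shares[label] = shares.get(label, 0.0) + rec.mass
        else:
            shares["other"] += rec.mass
    if total_mass > 0:
        shares = {k: 100.0 * v / total_mass for k, v in shares.items()}
    return RunSummary(
        config=config,
        class_shares=shares,
        checkpoints=cps,
        cooperation_series=coop_series,
        forfeit_series=forfeit_series,
        mean_payoff_series=payoff_series,
        first_cooperative_generation=first_coop,
        survivor_records=survivors,
        n_introductions=n_intro,
        total_mass=total_mass,
        frequency_history=history if history else None,
    )


def _class_order(game_class: GameClass):
    from .strategies import pattern_library
    return pattern_library(game_class)


def aggregate_runs(summaries: Iterable[RunSummary]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate run summaries into a class-share table and cooperation curves.

    Returns ``(class_table, cooperation_table)``: mean percent share per
    strategy class and visibility level, and the fraction of runs that are
    cooperative at each checkpoint generation.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("need at least one run summary")
    share_rows = []
    coop_rows = []
    for s in summaries:
        p = s.config.p_see
        for cls, share in s.class_shares.items():
            share_rows.append({"class": cls, "p_see": p, "share_percent": share})
        for cp, coop in zip(s.checkpoints, s.cooperation_series):
            coop_rows.append({"p_see": p, "generation": cp,
                              "cooperative": float(coop)})
    class_table = (pd.DataFrame(share_rows)
                   .groupby(["class", "p_see"], as_index=False)["share_percent"]
                   .mean())
    coop_table = (pd.DataFrame(coop_rows)
                  .groupby(["p_see", "generation"], as_index=False)["cooperative"]
                  .mean()
                  .rename(columns={"cooperative": "fraction_cooperative"}))
    return class_table, coop_table
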