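"""Markov-chain engine for iterated transparent games.

An infinitely repeated transparent game between two memory-one strategies is
a Markov chain on the four joint outcomes ``(A1A1, A1A2, A2A1, A2A2)``
(focal player's action first).  The transition matrix mixes three component
matrices by the visibility probabilities:

.. math:: M = (1 - p^{ij} - p^{ji})\\,M_0 + p^{ij}\\,M_1 + p^{ji}\\,M_2,

where :math:`M_0` covers rounds in which neither player sees the other's
choice (both act on their blind entries ``s1..s4``), :math:`M_1` rounds in
which the focal player i sees partner j act first (i responds with ``s5..s8``
or ``s9..s12``), and :math:`M_2` the reverse.  The expected per-round payoff
is the stationary distribution dotted with the payoffs in state order:

.. math:: E_{ij} = y_R R + y_S S + y_T T + y_P P.

The same stationary vector also yields the partner's payoff via the
transposed payoff order ``(R, T, S, P)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .games import PayoffMatrix, STATE_ORDER
from .strategies import MemoryOneStrategy

__all__ = [
    "TransitionModel",
    "build_transition_matrix",
    "stationary_distribution",
    "expected_payoff",
    "expected_payoff_pair",
    "MatchResult",
    "simulate_match",
]

# Previous joint outcome as seen by the partner: A1A2 and A2A1 swap.
_PARTNER_VIEW = (0, 2, 1, 3)

_STATIONARY_TOL = 1e-10


def _component_matrices(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """M0, M1, M2 for focal entries ``a`` and partner entries ``b`` (0-based)."""
    M0 = np.empty((4, 4))
    M1 = np.empty((4, 4))
    M2 = np.empty((4, 4))
    for k in range(4):
        m = _PARTNER_VIEW[k]
        ak, bm = a[k], b[m]
        # neither sees: both act blindly
        M0[k] = (ak * bm, ak * (1 - bm), (1 - ak) * bm, (1 - ak) * (1 - bm))
        # focal sees: partner commits blindly, focal responds
        a_seen1, a_seen2 = a[4 + k], a[8 + k]
        M1[k] = (a_seen1 * bm, a_seen2 * (1 - bm),
                 (1 - a_seen1) * bm, (1 - a_seen2) * (1 - bm))
        # partner sees: focal commits blindly, partner responds
        b_seen1, b_seen2 = b[4 + m], b[8 + m]
        M2[k] = (ak * b_seen1, ak * (1 - b_seen1),
                 (1 - ak) * b_seen2, (1 - ak) * (1 - b_seen2))
    return M0, M1, M2


@dataclass(frozen=True)
class TransitionModel:
    """The assembled 4x4 chain and its visibility components."""

    M: np.ndarray
    M0: np.ndarray
    M1: np.ndarray
    M2: np.ndarray
    p12: float
    p21: float
    state_order: tuple[str, ...] = STATE_ORDER


def build_transition_matrix(
    s_i: MemoryOneStrategy,
    s_j: MemoryOneStrategy,
    p12: float,
    p21: float,
) -> TransitionModel:
    """Assemble the transparent-game transition matrix for a strategy pair.

    ``p12`` is the probability that the focal player i sees j's current
    choice, ``p21`` the reverse; their sum may not exceed 1.
    """
    if p12 < 0 or p21 < 0 or p12 + p21 > 1.0 + 1e-12:
        raise ValueError(f"invalid visibility probabilities p12={p12}, p21={p21}")
    a = s_i.as_array()
    b = s_j.as_array()
    M0, M1, M2 = _component_matrices(a, b)
    M = (1.0 - p12 - p21) * M0 + p12 * M1 + p21 * M2
    return TransitionModel(M=M, M0=M0, M1=M1, M2=M2, p12=p12, p21=p21)


def _recurrent_classes(M: np.ndarray, tol: float = 1e-15) -> list[list[int]]:
    """Recurrent classes of a 4-state chain via boolean reachability."""
    adj = M > tol
    reach = adj | np.eye(4, dtype=bool)
    for _ in range(4):
        reach = reach | (reach @ reach)
    classes: list[list[int]] = []
    seen: set[int] = set()
    for s in range(4):
        if s in seen:
            continue
        # s is recurrent iff every state reachable from s reaches s back
        targets = np.flatnonzero(reach[s])
        if all(reach[t, s] for t in targets):
            cls = [t for t in targets if reach[t, s]]
            classes.append(sorted(cls))
            seen.update(cls)
    return classes


def stationary_distribution(model: TransitionModel) -> np.ndarray:
    """Stationary distribution ``(y_R, y_S, y_T, y_P)`` of the chain.

    Solved directly as the null space of :math:`M^\\top - I` with the
    normalisation row appended; falls back to power iteration if the linear
    solve degrades.  For chains built from pure (epsilon = 0) strategies the
    stationary vector is well defined only when there is a single recurrent
    class; otherwise an error naming the classes is raised.
    """
    M = model.M
    classes = _recurrent_classes(M)
    if len(classes) > 1:
        names = [" + ".join(STATE_ORDER[s] for s in cls) for cls in classes]
        raise ValueError(
            f"chain has {len(classes)} recurrent classes ({'; '.join(names)}); "
            "the stationary distribution is not unique"
        )
    A = M.T - np.eye(4)
    A[3, :] = 1.0
    rhs = np.array([0.0, 0.0, 0.0, 1.0])
    try:
        y = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        y = None
    if y is None or np.linalg.norm(y @ M - y, ord=np.inf) > _STATIONARY_TOL or y.min() < -1e-9:
        y = np.full(4, 0.25)
        for _ in range(100000):
            y_next = y @ M
            if np.linalg.norm(y_next - y, ord=np.inf) < 1e-14:
                y = y_next
                break
            y = y_next
    y = np.clip(y, 0.0, None)
    return y / y.sum()


def expected_payoff(
    s_i: MemoryOneStrategy,
    s_j: MemoryOneStrategy,
    p12: float,
    p21: float,
    payoff: PayoffMatrix,
) -> float:
    """Expected per-round payoff of the focal player i against partner j."""
    model = build_transition_matrix(s_i, s_j, p12, p21)
    y = stationary_distribution(model)
    return float(y @ np.asarray(payoff.as_vector()))


def expected_payoff_pair(
    s_i: MemoryOneStrategy,
    s_j: MemoryOneStrategy,
    p12: float,
    p21: float,
    payoff: PayoffMatrix,
) -> tuple[float, float]:
    """Both players' expected payoffs ``(E_ij, E_ji)`` from one chain.

    The partner's payoff reuses the focal-perspective stationary vector with
    the S and T entries swapped (state ``A1A2`` pays the focal player S and
    the partner T, and vice versa).
    """
    model = build_transition_matrix(s_i, s_j, p12, p21)
    y = stationary_distribution(model)
    R, S, T, P = payoff.as_vector()
    e_ij = float(y @ np.array((R, S, T, P)))
    e_ji = float(y @ np.array((R, T, S, P)))
    return e_ij, e_ji


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchResult:
    """Empirical outcome of a simulated match."""

    state_frequencies: np.ndarray
    mean_payoff_i: float
    mean_payoff_j: float
    n_rounds: int


def simulate_match(
    s_i: MemoryOneStrategy,
    s_j: MemoryOneStrategy,
    p12: float,
    p21: float,
    n_rounds: int,
    rng: int | np.random.Generator | None = None,
    payoff: PayoffMatrix | None = None,
    initial_state: int = 0,
) -> MatchResult:
    """Round-by-round Monte-Carlo simulation of a transparent-game match.

    Deliberately independent of the transition-matrix construction: each
    round first samples who (if anyone) sees the partner's choice, then the
    players' choices directly from the strategy entries.  Intended as an
    oracle for :func:`expected_payoff`; payoffs default to zero when no
    matrix is given.
    """
    if p12 < 0 or p21 < 0 or p12 + p21 > 1.0 + 1e-12:
        raise ValueError(f"invalid visibility probabilities p12={p12}, p21={p21}")
    counts = np.zeros(4)
    if n_rounds == 0:
        return MatchResult(state_frequencies=counts, mean_payoff_i=0.0,
                           mean_payoff_j=0.0, n_rounds=0)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    a = list(s_i.s)
    b = list(s_j.s)
    u_see = gen.random(n_rounds)
    u_first = gen.random(n_rounds)
    u_second = gen.random(n_rounds)
    cnt = [0, 0, 0, 0]
    state = initial_state
    pv = _PARTNER_VIEW
    for t in range(n_rounds):
        m = pv[state]
        w = u_see[t]
        if w < p12:  # focal sees partner
            j_a1 = u_first[t] < b[m]
            if j_a1:
                i_a1 = u_second[t] < a[4 + state]
            else:
                i_a1 = u_second[t] < a[8 + state]
        elif w < p12 + p21:  # partner sees focal
            i_a1 = u_first[t] < a[state]
            if i_a1:
                j_a1 = u_second[t] < b[4 + m]
            else:
                j_a1 = u_second[t] < b[8 + m]
        else:  # neither sees
            i_a1 = u_first[t] < a[state]
            j_a1 = u_second[t] < b[m]
        state = (0 if i_a1 else 2) + (0 if j_a1 else 1)
        cnt[state] += 1
    counts = np.array(cnt, dtype=float)
    freqs = counts / n_rounds
    if payoff is None:
        pay_i = pay_j = 0.0
    else:
        R, S, T, P = payoff.as_vector()
        pay_i = float(freqs @ np.array((R, S, T, P)))
        pay_j = float(freqs @ np.array((R, T, S, P)))
    return MatchResult(state_frequencies=freqs, mean_payoff_i=pay_i,
                       mean_payoff_j=pay_j, n_rounds=n_rounds)
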