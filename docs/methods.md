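# Methods

## The model

A transparent game is an iterated two-player, two-action game in which, each
round, exactly one of three things happens: player 1 sees player 2's current
choice before acting (probability `p12`), player 2 sees player 1's
(probability `p21`), or neither sees the other.  The two probabilities
satisfy `p12 + p21 <= 1`; the remainder is the chance the players act too close in
time for either to react.  Throughout the evolutionary analyses both players
are assumed to have equal mean reaction times, so `p12 = p21 = p_see <= 0.5`.
This assumption is not cosmetic: in the Prisoner's Dilemma it pays to act
late (see the defector first) and in the anti-coordination game it pays to
act early (commit to insisting), so unequal mean reaction times are
evolutionarily unstable in either direction and the symmetric case is the
relevant one.

Strategies are memory-one: 12 conditional probabilities of choosing action
A1, indexed by the previous round's joint outcome (A1A1, A1A2, A2A1, A2A2,
own action first) crossed with the current visibility condition (unseen /
partner seen choosing A1 / partner seen choosing A2).  All entries are
confined to `[eps, 1-eps]` with `eps = 0.001`, modelling execution errors
("trembling hand") and guaranteeing ergodicity of the pair chain.  Pure
(`eps = 0`) strategies are allowed only through an explicit flag; the engine
then detects recurrent classes itself.

## Numerics of the pair chain

For a strategy pair the iterated game is a 4-state Markov chain
`M = (1-p12-p21) M0 + p12 M1 + p21 M2`, where the three component matrices
cover the visibility cases; the row for a unilateral previous outcome uses
the partner's entries with the A1A2/A2A1 indices swapped, since the partner
saw the mirrored outcome.  The stationary vector is obtained by a direct
linear solve of `(M^T - I) y = 0` with the normalisation row appended, with
two safeguards: a residual check (`||yM - y||_inf <= 1e-10`) falling back to
power iteration, and, before solving, a reachability-based recurrent-class
analysis so that pure-strategy chains with several absorbing sets raise an
error naming the classes instead of returning an arbitrary eigenvector.
One solve yields both players' payoffs: the focal player's payoff is
`y . (R,S,T,P)` and the partner's is `y . (R,T,S,P)` (the unilateral states
swap S and T).

The Monte-Carlo cross-check (`simulate_match`) deliberately does not touch
the transition matrices: it samples who-sees-whom and then both choices
directly from the strategy entries, round by round.  Agreement tests use
standard errors from the Markov-chain central limit theorem (autocovariance
sum over the chain), not the i.i.d. formula, because round-level payoffs are
autocorrelated.

## One-shot theory

Closed-form results cover: the defector equilibria of the transparent
Prisoner's Dilemma and the bound on their "cooperate if seen cooperating"
entry; the relation between the equilibrium defector `(0; x; 0)` and the
conditional cooperator `(1; 0; 0)`; cooperation under unequal reaction
times (bistability above `p12 = (T-R)/(T-P) + p11 (2R-S-T)/(T-P)`, which is
5/8 for the standard payoffs at `p11 = 0.5`); and the equilibria of the
anti-coordination class `S > T > R, S > P`, which includes Bach-or-Stravinsky,
Hawk-Dove and Leader.  Two resolution choices deserve note:

* **Bistable vs coexist labelling.**  The two conditions entering the
  defector/cooperator relation are exactly the payoff comparisons
  `E11 >= E21` (the defector pair is an equilibrium) and `E12 >= E22`
  (defectors outscore cooperators inside a cooperator population).  The
  relation labels follow the payoff-level definitions — one condition alone
  gives bistability when it is the equilibrium condition and coexistence
  when it is the other — which keeps this function consistent with
  `classify_pair` applied to the same four payoffs.  Tests enforce that
  cross-module agreement on a grid of `(p_see, x)`.
* **Finite-horizon Leader-Follower risk.**  In `n` rounds against a pure
  Leader-Follower partner at `p_see = 0.5`, a pure Leader-Follower earns
  `T` per Leader round and `S = 0` per Follower round.  The implemented
  risk is the probability that the number of Leader rounds `j` satisfies
  `j <= floor(nP/T)`, i.e. the player's total falls to the all-defection
  baseline `nP` or below; for `nP/T` not an integer this is exactly the
  strict event "total < nP".  An alternative reading — AllD is *round-wise*
  weakly better, probability `1 - 2^{-n}` — is arithmetically defensible
  but does not produce the 1/2, 1/4, 7/64 sequence this quantity is meant
  to measure, so the baseline reading is used and flagged here.

Equilibria are verified by a best-response search over a 21^3 strategy grid
(no profitable deviation beyond 1e-9) and mixed equilibria by exact
indifference (1e-12).

## Evolutionary simulation

Infinite population, discrete replicator dynamics
`x_i(t+1) = x_i f_i / fbar` with `f_i = sum_j x_j E_ij` (self-play included).
Each generation: selection, then extinction (types with `x_i < chi = 0.001`
removed, share redistributed proportionally, the largest type always kept),
then with probability 1/100 the introduction of one random type at frequency
`1.1 chi` (i.i.d. Bernoulli per generation — the simplest desynchronised
reading of "every 100 generations on average").  Runs start from five random
types at frequency 0.2.  Random strategy entries are drawn from the
normalised arcsine density `(1/pi) (y(1-y))^{-1/2}` — Beta(1/2, 1/2),
favouring near-deterministic entries — clipped to `[eps, 1-eps]`.  Pairwise
payoffs are computed lazily when a type first appears and cached.

These defaults *are* the study conditions; none of them is a tuning knob.
The only scale parameter is the horizon: defaults target desk-scale runs of
1e6 generations and 10 seeds per condition (about 7 s per run on one CPU),
where the published experiments trace 1e9 generations in 80 runs.

**Aggregation.**  A type whose lifetime exceeds 1000 generations contributes
its entire summed frequency mass to its coarse-grained class; shorter-lived
types count as rare transients under "other".  Class patterns use the
12-token notation (`0` ≤ 0.1, `1` ≥ 0.9, `*` wildcard, named interval
bounds), shipped as `data/patterns.json` and matched in a fixed
most-specific-first order; thresholds are inclusive as printed, and the
generous-tit-for-tat/firm-but-fair interior bounds use the open interval
(0.1, 0.9) so interior tokens are disjoint from the 0/1 tokens.  The two
challenger variants share a descriptor and are separated by their prose
`b`-ranges (≤ 0.1 vs (0.1, 1/3]).

**Cooperation metrics.**  A population is "cooperative" when its mean payoff
exceeds 0.9 of the ceiling in the iPD (0.9 × 3) and 0.95 of the ceiling in
the i(A)CG (0.95 × 3.5 = 3.325, the stricter factor reflecting the less
competitive game).  The forfeit payoff is ceiling minus actual mean.
Cooperation is recorded both as a boolean series at logarithmically spaced
checkpoints (1, 3, 10, 30, …) and as the first-passage generation, since
either convention is defensible.

## What desk scale does and does not show

The deterministic layers (payoffs, thresholds, equilibria, trajectories)
reproduce the published worked-example values to their printed precision,
so passing tests there are direct checks of the machinery.  The stochastic
evolutionary layer is different: at 1e6 generations the establishment and
refinement transient — which occupies a negligible fraction of a
1e9-generation run — dominates the mass average.  Concretely, populations in
the transparent i(A)CG at `p_see = 0.5` typically reach Leader-Follower
*behaviour* within ~1e4 generations, but individual strategy entries under
weak selection (e.g. the seen-response entry after a unilateral outcome)
can sit just outside the coarse-grained 0.1/0.9 cutoffs for 1e5–1e6
generations, so a behaviourally Leader-Follower winner may be tallied under
a neighbouring class.  In the iPD at `p_see = 0.2`, escape from
defection-dominated epochs into win-stay-lose-shift cooperation is an
intermittent process whose typical waiting time is of order 1e5–1e7
generations; a 1e6-generation run therefore often averages substantial
pre-cooperative mass.  Desk-scale class shares consequently show the right
*ordering* (Leader-Follower largest at high transparency in the i(A)CG;
win-stay-lose-shift the largest named class at moderate transparency in the
iPD; cooperation increasing with transparency in the i(A)CG and decreasing
in the iPD) with absolute shares systematically below the full-scale
values.  The two-type dynamics tests, which are transient-free, pin down
the same machinery exactly.

## Reaction times

Reaction times are ex-Gaussian (Normal(mu, sigma) + Exponential(tau)).
Visibility is parameterised by a perception delay `delta >= 0`: player i
sees player j when `T_j + delta < T_i`.  This is one admissible reading of
how visibility arises from response timing (alternatives include soft
detection probabilities or decision-window truncation); it reproduces the
two structural constraints that matter — equal distributions give
`p12 = p21 <= 0.5` with equality only at `delta = 0`, and
`p12 + p21 + Pr(|T_i - T_j| <= delta) = 1`.  The deterministic method
evaluates `Pr(T_j + delta < T_i)` by adaptive quadrature of the ex-Gaussian
density–CDF product, with a Monte-Carlo fallback and cross-check.

## Known limitations

* Memory-one strategies only; longer memories and N-player extensions are
  out of scope.
* Infinite-population deterministic dynamics: no genetic drift, so a
  resident type can only be displaced by a selectively favoured entrant;
  finite-population effects are not modelled.
* Desk-scale evolutionary shares under-weight fully refined strategies, as
  discussed above.
* Payoff matrices are symmetric between the two players.
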