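# transparentgames

Evolutionary game theory for **transparent games**: iterated two-player games
in which each player has a probability `p_see` of observing the partner's
*current-round* choice before acting.  `p_see = 0` recovers the classic
simultaneous game; `p_see = 0.5` (players with equal mean reaction times)
recovers a sequential game with random move order.  Action visibility of this
kind is ubiquitous in real dyadic interactions — human economic games played
face to face, primates foraging side by side — yet sits between the two
classical settings game theory usually offers.

The package is aimed at researchers in behavioural modelling, social
neuroscience and evolutionary biology who want to ask: *which strategies are
long-term successful when actions are partially visible?*  It covers both a
competitive game (the iterated Prisoner's Dilemma, payoffs
`T > R > P > S` = 5, 3, 1, 0) and a coordination-with-conflict game (the
iterated (Anti-)Coordination Game / Bach-or-Stravinsky, `S > T > R > P` =
4, 3, 2, 1), plus the Hawk-Dove and Leader one-shot variants.

## What it computes

**One-shot theory** (`transparentgames.oneshot`).  The expected payoff of
strategy $(s_1; s_2; s_3)$ — act unseen / seeing the partner pick $A_1$ /
seeing $A_2$ — is a three-branch sum over who (if anyone) sees whom.  From it
the module derives closed-form Nash equilibria: in the transparent one-shot
PD all equilibria are defector pairs $(0; x; 0)$ with
$x \le \frac{1-p_{see}}{p_{see}}\frac{P-S}{R-S}$; in the anti-coordination
class there are either two pure "insist/accommodate" equilibria plus a mixed
one, or (for high visibility) the single "insist unless you see the partner
insist" equilibrium $(1; 0; 1)$.

**Markov-chain engine** (`transparentgames.engine`).  A pair of *memory-one*
strategies (12 conditional probabilities: 4 previous outcomes × 3 visibility
conditions) induces a Markov chain on the four joint outcomes with

$$M = (1 - p^{12} - p^{21}) M_0 + p^{12} M_1 + p^{21} M_2,$$

and the expected per-round payoff is the stationary distribution dotted with
$(R, S, T, P)$.  A round-by-round Monte-Carlo simulator serves as an
independent cross-check.

**Pairwise dynamics and evolution** (`pairwise`, `evolution`).  Two-strategy
competitions are classified as dominance / bistability / coexistence with the
invasion threshold $h_1 = \frac{E_{22}-E_{12}}{E_{11}-E_{12}-E_{21}+E_{22}}$,
and an infinite-population replicator simulator —
$x_i(t+1) = x_i f_i/\bar f$ with extinction below $\chi = 0.001$ and random
strategy introduction (arcsine-distributed entries, error floor
$\varepsilon = 0.001$) — tracks which coarse-grained strategy classes
(win-stay-lose-shift, tit-for-tat variants, turn-takers, challengers,
leader-followers, …) dominate at each transparency level.

**Reaction times** (`reaction_times`) converts two ex-Gaussian reaction-time
distributions into the visibility probabilities `(p12, p21)`.

## Worked example

Win-stay-lose-shift (WSLS) against unconditional defection (AllD) in the
transparent iPD at `p_see = 0.4`, with the error-floor substitution
$0 \to 0.001$, $1 \to 0.999$:

```
$ transparentgames match '[1,0,0,1,1,0,0,1,0,0,0,0]' '[0,0,0,0,0,0,0,0,0,0,0,0]' \
      --game ipd --p-see 0.4
{
  "p_see": 0.4,
  "stationary": {
    "y_R": 0.0006245937894439613,
    "y_S": 0.37478111739270237,
    "y_T": 0.00037540621055605204,
    "y_P": 0.6242188826072976
  },
  "E12": 0.6279696950284098,
  "E21": 2.499998250939141
}
```

The chain spends 62% of rounds in mutual defection and 37% in unilateral
cooperation (WSLS cooperating into defection), so WSLS earns 0.628 per round
against AllD while AllD earns 2.500.  Together with the self-play payoffs
(WSLS: 2.995, AllD: 1.003) the pair is *bistable*: WSLS takes over whenever
its initial share exceeds the invasion threshold
$h_1 = (1.003-0.628)/(2.995-0.628-2.500+1.003) \approx 0.431$.  At
`p_see = 0` the same pair has payoffs (2.995, 0.504, 2.999, 1.003) and AllD
simply dominates — visibility is what lets conditional cooperators punish
defectors before being exploited.

The same machinery at population scale (`transparentgames evolve --game iacg
--p-see 0.5 --generations 1000000 --runs 10 --seed 1 --out scratch/acg`)
shows the Leader-Follower class — defect/insist when acting first, yield
when seeing the partner's move — taking over the anti-coordination game at
high transparency, while in the Prisoner's Dilemma high visibility erodes
cooperation.

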