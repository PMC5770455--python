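# Methods

This note documents the models and procedures implemented in `coopgames`,
the design choices made where the design was genuinely open, and what the
package's tests do and do not establish.

## Repeated stochastic games

A two-player repeated stochastic game (RSG) is played in rounds.  Each
round starts in a designated start stage; in every stage both players
simultaneously pick actions, receive stage rewards, and the game moves to
a next stage according to a (possibly stochastic) transition kernel.  The
round ends when a goal stage is entered.  A normal-form game is the
single-stage special case: one simultaneous move per round.

Game validation checks, at load time, that every transition row is a
probability distribution (sum within 1e-12 of one) and that rounds end
almost surely under *every* joint policy.  The latter reduces to the
absence of a policy-closed subset of non-goal stages (a greatest-fixed-
point computation over the reachable stage graph); if such a subset
exists, some policy could cycle forever and the game is rejected.  As a
second line of defense the match engine caps each round at a configurable
number of stages (default 50); hitting the cap is flagged on the round
record and ends the round with the payoffs accumulated so far.

Randomness: every match takes one root seed, split into three independent
streams (environment, player 0, player 1), so histories are bit-exactly
reproducible and no agent's behavior depends on how much randomness its
partner consumes.

## The ordinal benchmark

The benchmark is the family of 2×2 games with strict ordinal preferences:
each player ranks the four outcomes strictly, giving payoffs that permute
{1, 2, 3, 4}.  There are 24 × 24 = 576 labeled games; relabeling either
player's two actions (a 4-element group) identifies them into equivalence
classes.  The group acts freely — strictness forbids a payoff matrix equal
to its own row- or column-swap — so there are exactly 576 / 4 = 144
classes.  The canonical representative is the lexicographically smallest
flattened payoff encoding over the four relabelings.  Ordinal ranks are
used directly as cardinal payoffs, which the planning layer needs.  The
family tagger shipped with the enumeration (win-win, prisoner's-dilemma,
cyclic, battle, coordination, unique-equilibrium) is a coarse default
taxonomy, configurable by passing a different tagging callable; it makes
no claim to match any external table's family labels.

## Security levels and punishment

A player's maximin (security) value is what it can guarantee with a mixed
strategy against an adversarial partner.  For a single stage this is the
value of the zero-sum matrix game on the player's own payoffs, solved as a
linear program (HiGHS via `scipy.optimize.linprog`).  For multi-stage
games it is the value of the zero-sum stochastic game, computed by value
iteration with one matrix-game solve per stage (tolerance 1e-10, at most
10,000 sweeps; termination is guaranteed because rounds end almost
surely).  The minimax *attack* — the strategy that minimizes the partner's
best achievable payoff — is the LP dual of the same computation and holds
the victim to exactly its maximin value; it is the punishment phase of
trigger strategies.

## Compromise (target) solutions

Candidate compromises come from planning in the joint-action MDP with the
blended reward y_w(s, a) = w·r0(s, a) + (1−w)·r1(s, a), w ∈ [0, 1], with
goal stages worth zero.  The MDP is solved by value iteration (tolerance
1e-10; equal-value joint actions break ties by enumeration order, for
determinism).  Under the optimal joint policy each player's *own*
expected per-round payoff is obtained by a linear policy-evaluation solve;
that pair is the solution's payoff profile.  Sweeping w over an
11-point grid {0, 0.1, …, 1} and deduplicating by payoff profile yields
the "pure solutions"; every unordered pair of distinct pure solutions
additionally defines an "alternating solution" that cycles between the
two with the averaged profile.  Cycles are capped at length two — longer
cycles are hard for a partner to model, and the pair construction already
spans the line segments between pure profiles.

Five compromises are then selected: (1) the most egalitarian candidate,
operationalized as maximizing the smaller of the two maximin gains (the
equivalence of this stand-in with other egalitarian definitions is not
claimed); (2)–(3) each player's best candidate subject to the partner
clearing its security level; (4)–(5) candidates chosen greedily to
maximize the minimum Euclidean distance between selected payoff profiles.
Duplicates are skipped, so degenerate games yield fewer than five.

The Nash bargaining solution (NBS) — the operational definition of mutual
cooperation throughout — is the candidate maximizing the product of
payoff gains over the maximin point, with candidates from the target-
solution set plus (for normal-form games) all pure joint actions.
Candidates where both players clear their security level are preferred
whenever any exists, since a product of two shortfalls is not a
bargaining gain; ties break by payoff sum, then candidate order.  The
mutual-cooperation proportion of a match counts rounds matching the NBS
pattern, choosing the phase offset of an alternating pattern to maximize
the match count.

## The expert set

For each side of a game the package builds up to thirteen experts:

* **Expectant followers** (five): play a selected compromise
  unconditionally.
* **Trigger strategies** (five): play the compromise (the *offer*) but
  punish profitable deviations with the minimax attack.  The forgiveness
  ledger accumulates, from the deviation round on, the partner's actual
  payoffs against the counterfactual payoffs compliance would have paid;
  punishment starts when a deviation strictly beats the counterfactual
  and ends (with expectations reset) once the partner's running total
  falls below it.  With the worked numbers of the 0-1-3-5 prisoner's
  dilemma — deviation pays 5 against a counterfactual of 3, punishment
  holds the partner to 1 — punishment lasts exactly two further rounds.
* **Preventative**: maximin play with one round of retaliation whenever
  the realized payoff falls below the security level.  This is a
  documented stand-in for a strategy whose published description is not
  available in detail; it is config-switchable.
* **Maximin**: the security-level mixed strategy.
* **MBRL**: a model-based reinforcement learner.  In normal-form games
  its state is the previous round's joint action (plus an initial state);
  the partner's next action per state is modeled with Dirichlet-smoothed
  counts, and the induced MDP (discount 0.95) is re-solved after every
  round by exact policy iteration, warm behavior being irrelevant since
  the solve is exact and cheap.  In multi-stage games the partner model
  is per-stage and the round value recurses through the start stage with
  the same discount; this stage-conditioned model is a deliberate
  simplification that keeps planning desk-scale.

### Potentials

Each expert reports a *potential*: its estimated best attainable
per-round payoff under current beliefs.

* Followers: offer's own payoff × a recency-weighted compliance estimate
  (exponential smoothing, retention 0.7 per observed round, optimistic
  start at 1), updated **only while the expert is selected** and its offer
  is actually on the table.  Optimism makes untried offers look as good
  as their promise — this is what drives the algorithm's early attempts
  to get the better end of a bargain — and recency weighting lets a
  collapsed estimate recover against a partner that has since changed.
  Count-based (Beta) smoothing was rejected: against an adapting partner
  it can never recover, which produces an absorbing mutual-defection
  state in self-play.
* Triggers: when the offer pays the partner strictly more than its
  security level, punishment makes compliance the partner's optimal
  strategy, so the trigger reports the offer's own payoff outright.
  Offers at or below the partner's security level are not enforceable —
  minimax play cannot push the partner below what the offer pays, so the
  forgiveness ledger would never clear — and such triggers report the
  compliance-discounted value like followers.  (Strictness matters: at
  equality, punishment holds the partner to exactly the counterfactual
  and would last forever.)
* Preventative and maximin: the security value.
* MBRL: its value estimate at the current state on a per-round scale,
  (1 − γ)·V.

The exact potential formulas of the original systems are not published in
detail; the choices above are this package's documented operationalization
of "highest expected utility", selected so that the published qualitative
dynamics (bully first, settle on enforceable compromises, exploit the
exploitable, accept being bullied when nothing better exists) emerge.

## The S++ selector

S++ plays in epochs of m rounds.  At each epoch boundary it recomputes
potentials, prunes the expert set to E(t) = {e : ρ_e(t) ≥ α(t)}, applies
satisficing selection, and after the epoch relaxes its aspiration toward
the realized mean payoff R: α(t+m) = λ^m α(t) + (1−λ^m) R.  The
aspiration starts at the maximum potential (optimism).  When the pruned
set is empty — the aspiration has outrun every potential — the experts
tying for the best potential are used instead (followers and triggers can
tie exactly, so this is a set, drawn from uniformly).

Satisficing selection keeps the incumbent expert when it both survives
the pruning and *delivered* an epoch payoff meeting the aspiration;
otherwise a new expert is drawn uniformly from E(t).  The
payoff-satisfaction condition matters: judging the incumbent only by its
advertised potential lets an expert be held forever on stale optimism.
Keeping the incumbent while R ≥ α is also what produces loyalty — once
mutual cooperation pays 3 against an aspiration below 3, the selector
never deviates.

Defaults: λ = 0.95 per round, m = 3 rounds.  Both are config-exposed
stand-ins (the original epoch schedule is not published in detail),
chosen so that self-play converges within a few hundred rounds while
100-round games still allow ~30 reselection opportunities.  Algorithm S
(the same selector without pruning) is available as a registry entry.

## S#: cheap talk

S# is S++ plus signaling; with talk disabled it is bit-identical to S++
under the same seed (it consumes no extra randomness).

Each expert carries a Mealy machine over the event alphabet {conformed,
deviated, benefited-from-deviation, punishing, punishment-complete}.  The
trigger machine has nine states: an expectation chain s0–s6 (initial
transition voices the plan, act #15, plus a threat, act #0; conformity
earns praise, acts #5–6; deviations draw displeasure, acts #11–12), a
punishment state s7 (entered on a beneficial deviation with a punishment
notice, act #13, and gloating, act #14, while it lasts) and a forgiveness
state s8 (act #4) that renews expectations.  Followers use the same
machine without the punishment states; experts without an offer voice an
expectation once and then stay quiet.  Catalog ids not used by these
machines are placeholders so the numbering stays aligned; their templates
are editable.

Plans attached to act #15 are joint-action cycles in normal-form games
and high-level fairness descriptors in multi-stage games: a solution
whose payoff profile is within 10% of the payoff range of the NBS profile
is "fair"/cooperative, otherwise it is described by who gets the higher
payoff.  The 10% threshold is a package choice, config-exposed.

On hearing a proposal, congruence filtering prefers experts whose offers
match it — exact cyclic equality of joint-action cycles for normal form,
descriptor equality (with the I/you perspective flipped) for multi-stage
games — intersected with the aspiration test; if nothing congruent clears
the aspiration, plain pruning takes over.  Listening is gated by a
Bernoulli draw with probability equal to a smoothed estimate (retention
0.8) of how often the partner keeps its own proposals; speaking stops
after three consecutive epochs in which the agent's own proposals were
ignored and resumes after any followed proposal.  The smoothing constants
and patience are documented stand-ins for unpublished details.

## Baselines

Twelve reference strategies share the match-engine agent contract:
random, generous tit-for-tat (payoff-derived generosity with a 0.1
fallback), win-stay-lose-shift (aspiration = own mutual-cooperation
payoff), Bully (Stackelberg demand plus minimax punishment with the same
forgiveness accounting as triggers), memory-one and memory-two stochastic
strategies (default vectors are generous-ZD-flavored and
two-round-forgiveness stand-ins respectively; both config-exposed),
fictitious play, MBRL-1 (the MBRL expert standalone), MBRL-2 (state =
last two joint actions), tabular Q-learning, and two traditional
expert-selection baselines over the *same* expert set as S++: EEE
(epsilon-greedy over empirical expert means with optimistic
initialization) and Exp3 (exponential weights with importance-weighted
payoff estimates normalized by the payoff range).  Strategies that need a
notion of "cooperating" in an arbitrary 2×2 game cooperate with their
component of the NBS joint action.  All defaults live in constructor
signatures and the registry validates parameters.

## Tournament metrics

The round-robin runs every pairing (including self-play) in every game
for a list of seeds, playing each unordered pairing once per (game, seed)
and recording both perspectives.  Derived metrics: round-robin average;
best score (share of partners against which an algorithm's mean payoff is
highest, exact ties splitting credit); worst-case score (minimum over
games and partners of the per-game z-scored mean payoff; constant games
map to zero); final usage rates of the discrete-time replicator dynamic
over 10,000 generations (payoffs shifted positive by global-min + 1e-6);
and two elimination tournaments that iteratively remove the survivor with
the lowest round-robin average (variant 1) or lowest worst-case score
(variant 2) among survivors, ties broken by prior overall average then
name.  The elimination protocols are documented reconstructions, not
claimed to match any external protocol exactly.  Time-to-cooperation is
the first round t such that rounds t and t+1 both match the NBS pattern
at a common phase offset; loyalty is the share of pairings reaching such
a t that never play a non-matching round after t+1.

## Problem sizes used in the shipped checks

The test suite reproduces the headline results at desk scale, a package
choice balancing statistical resolution against turnaround: the scaled
round-robin uses the full 15-entry registry over an evenly spaced
40-game subset of the 144-game benchmark (100 rounds, 10 seeds); the
self-play dynamic uses 50 seeds × 1,000 rounds; the cheap-talk comparison
uses 50 seeds × 300 rounds per condition with censored times placed past
the horizon.  Full-benchmark, 25-algorithm, 50,000-round evaluations are
outside the scope of this package's checks.

## What the synthetic games do and do not show

All inputs are synthetic: canonical named games, the strict-ordinal
benchmark, random ordinal games, and a configurable block-drafting RSG.
The named prisoner's dilemma carries its standard 0-1-3-5 payoffs; the
chicken and alternator cardinalizations and the block game's values and
validity rule are illustrative stand-ins and are not calibrated to any
external source.  Tests passing on these games show that the algorithms
have the intended game-theoretic behavior (planning, enforcement,
satisficing, signaling); they do not show anything about play against
humans, about natural-language communication, or about games with
imperfect information, more than two players, or per-round payoff
changes, all of which are out of scope.

## Known limitations

* Expert potentials, the preventative strategy, the epoch schedule, the
  speak/listen constants, and several baseline parameter vectors are
  documented operationalizations of systems whose exact published
  details are unavailable; all are config-exposed.
* The MBRL expert's multi-stage partner model conditions on the stage
  only, not on the preceding joint action.
* The congruence filter for multi-stage games works at the descriptor
  level; two distinct solutions with similar profiles are
  indistinguishable to it.
* Game files require YAML-scalar stage identifiers; programmatically
  built games with richer stage objects are stringified on save.
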