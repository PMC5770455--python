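"""The expert set: pre-computed full-game strategies that a meta-learner
selects among.

For a given game the set contains (at most) thirteen experts:

* five *expectant followers*, one per selected compromise solution, which
  play the solution unconditionally;
* five *trigger strategies* over the same solutions, which play the
  solution (the "offer") but punish beneficial partner deviations with
  minimax play until the deviation gain is nullified, then forgive;
* a *preventative* strategy (maximin play with one round of retaliation
  when the realized payoff drops below the security level);
* the *maximin* strategy; and
* a model-based reinforcement learner (MBRL) that models the partner's
  next action and best-responds by solving the induced MDP.

Each expert exposes a *potential*: its estimated highest attainable
per-round payoff under current beliefs.  Followers and triggers scale their
offer's own-payoff by a smoothed estimate of how often the partner follows
the offer, with an optimistic prior (compliance pseudo-count 1), so untried
offers look as good as their promise; the estimate only updates while the
offer is actually on the table (the expert is selected and not punishing).
"""

from __future__ import annotations

import numpy as np

from .games import RepeatedStochasticGame
from .planning import (TargetSolution, _phase_payoffs, enumerate_target_solutions,
                       select_five_solutions)
from .solve import maximin_strategy, maximin_value, minimax_attack_strategy


def _policy_iteration(P: np.ndarray, r: np.ndarray, gamma: float,
                      max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Exact solve of a small discounted MDP.

    ``P[s, a, s']`` transition probabilities, ``r[s, a]`` expected rewards.
    Returns (V, Q).
    """
    S, A = r.shape
    idx = np.arange(S)
    policy = r.argmax(axis=1)
    eye = np.eye(S)
    for _ in range(max_iter):
        V = np.linalg.solve(eye - gamma * P[idx, policy], r[idx, policy])
        Q = r + gamma * (P.reshape(S * A, S) @ V).reshape(S, A)
        new = Q.argmax(axis=1)
        if np.array_equal(new, policy):
            return V, Q
        policy = new
    return V, Q  # pragma: no cover - policy iteration terminates finitely


def _sample(rng: np.random.Generator, probs: np.ndarray) -> int:
    """Sample an index from a small probability vector."""
    if probs.size == 1 or probs.max() > 1 - 1e-12:
        return int(np.argmax(probs))
    return int(rng.choice(probs.size, p=probs / probs.sum()))


class Expert:
    """Base class: a full-game strategy with its own update rule."""

    kind = "expert"

    def __init__(self, expert_id: str):
        self.id = expert_id
        self.offer: TargetSolution | None = None

    def reset(self, game: RepeatedStochasticGame, player: int,
              rng: np.random.Generator) -> None:
        self.game = game
        self.player = player
        self.rng = rng
        self.last_event = None

    def on_selected(self) -> None:
        """Called when the meta-learner (re)selects this expert."""

    def act(self, stage, t: int) -> int:
        raise NotImplementedError

    def end_round(self, record, selected: bool) -> None:
        """Update internal models from the completed round."""

    def potential(self) -> float:
        raise NotImplementedError


class FollowerExpert(Expert):
    """Plays a target solution unconditionally, expecting the partner to follow."""

    kind = "follower"

    #: per-round retention of the compliance estimate (recency weighting)
    compliance_retention = 0.7

    def __init__(self, expert_id: str, solution: TargetSolution):
        super().__init__(expert_id)
        self.offer = solution

    def reset(self, game, player, rng):
        super().reset(game, player, rng)
        self.phase_payoffs = tuple(
            _phase_payoffs(game, pol) for pol in self.offer.policies)
        self._compliance = 1.0  # optimistic: untried offers look kept

    def _partner_complied(self, record) -> bool:
        policy = self.offer.phase(record.t)
        partner = 1 - self.player
        return all(policy.get(stage) is not None
                   and joint[partner] == policy[stage][partner]
                   for stage, joint in zip(record.stages, record.joint_actions))

    def compliance(self) -> float:
        """Recency-weighted follow rate of the offer, optimistic start."""
        return self._compliance

    def act(self, stage, t):
        return self.offer.phase(t)[stage][self.player]

    def end_round(self, record, selected):
        self.last_event = None
        if not selected:
            return
        complied = self._partner_complied(record)
        w = self.compliance_retention
        self._compliance = w * self._compliance + (1 - w) * float(complied)
        self.last_event = "s" if complied else "d"

    def potential(self):
        return self.offer.payoffs[self.player] * self.compliance()


class TriggerExpert(FollowerExpert):
    """Offer + punishment automaton.

    On a partner deviation that beat the offer's counterfactual payoff, the
    expert switches to the minimax attack and keeps a forgiveness ledger:
    punishment continues while the partner's cumulative payoff since the
    deviation is still at least what compliance would have paid, and ends
    (with expectations reset) once the partner has fallen below it.

    When the offer grants the partner strictly more than its security
    level, punishment makes following the offer the partner's optimal
    strategy, so the trigger's potential is the offer's own payoff itself:
    the automaton can in principle teach any payoff-maximizing partner to
    comply.  Offers at or below the partner's security level are not
    enforceable (minimax play cannot drive the partner below what the
    offer pays, so deviation never costs it anything), and those triggers
    report the compliance-discounted value, like followers.
    """

    kind = "trigger"

    def potential(self):
        if self.enforceable:
            return self.offer.payoffs[self.player]
        return super().potential()

    def reset(self, game, player, rng):
        super().reset(game, player, rng)
        self.enforceable = (
            self.offer.payoffs[1 - player]
            > maximin_value(game, 1 - player) + 1e-9)
        self.attack, self.attack_value = minimax_attack_strategy(game, 1 - player)
        self.punishing = False
        self.ledger_actual = 0.0
        self.ledger_counterfactual = 0.0

    def on_selected(self):
        # a stale punishment from an earlier selection is dropped
        self.punishing = False
        self.ledger_actual = 0.0
        self.ledger_counterfactual = 0.0

    def act(self, stage, t):
        if self.punishing:
            return _sample(self.rng, self.attack[stage])
        return super().act(stage, t)

    def end_round(self, record, selected):
        self.last_event = None
        if not selected:
            return
        partner = 1 - self.player
        partner_payoff = record.payoffs[partner]
        counterfactual = self.phase_payoffs[(record.t - 1) % len(self.phase_payoffs)][partner]
        if not self.punishing:
            complied = self._partner_complied(record)
            w = self.compliance_retention
            self._compliance = w * self._compliance + (1 - w) * float(complied)
            if complied:
                self.last_event = "s"
            elif partner_payoff > counterfactual + 1e-9:
                # beneficial deviation: open the ledger and start punishing
                self.punishing = True
                self.ledger_actual = partner_payoff
                self.ledger_counterfactual = counterfactual
                self.last_event = "g"
            else:
                self.last_event = "d"
        else:
            self.ledger_actual += partner_payoff
            self.ledger_counterfactual += counterfactual
            if self.ledger_actual < self.ledger_counterfactual - 1e-9:
                self.punishing = False
                self.ledger_actual = 0.0
                self.ledger_counterfactual = 0.0
                self.last_event = "f"
            else:
                self.last_event = "p"


class MaximinExpert(Expert):
    """Plays the security-level mixed strategy."""

    kind = "maximin"

    def reset(self, game, player, rng):
        super().reset(game, player, rng)
        self.strategy = maximin_strategy(game, player)
        self.value = maximin_value(game, player)

    def act(self, stage, t):
        return _sample(self.rng, self.strategy[stage])

    def potential(self):
        return self.value


class PreventativeExpert(MaximinExpert):
    """Maximin play plus one round of minimax retaliation after any partner
    move that drags the realized payoff below the security level."""

    kind = "preventative"

    def reset(self, game, player, rng):
        super().reset(game, player, rng)
        self.attack, _ = minimax_attack_strategy(game, 1 - player)
        self.retaliating = False

    def on_selected(self):
        self.retaliating = False

    def act(self, stage, t):
        if self.retaliating:
            return _sample(self.rng, self.attack[stage])
        return super().act(stage, t)

    def end_round(self, record, selected):
        self.last_event = None
        if not selected:
            return
        if self.retaliating:
            self.retaliating = False
            self.last_event = "f"
        elif record.payoffs[self.player] < self.value - 1e-9:
            self.retaliating = True
            self.last_event = "d"
        else:
            self.last_event = "s"


class MBRLExpert(Expert):
    """Model-based reinforcement learner.

    Normal-form games: the state is the previous round's joint action (plus
    a distinguished initial state); the partner's next action is modeled by
    Dirichlet-smoothed empirical counts per state, and the induced MDP is
    solved by value iteration (discount ``gamma``) after every round, warm
    starting from the previous solution.  Multi-stage games use per-stage
    partner models with the round value recursing through the start stage.
    The potential is the value estimate at the current state on a per-round
    scale, ``(1 - gamma) * V``.
    """

    kind = "mbrl"

    def __init__(self, expert_id: str, gamma: float = 0.95, tol: float = 1e-6):
        super().__init__(expert_id)
        self.gamma = gamma
        self.tol = tol

    def reset(self, game, player, rng):
        super().reset(game, player, rng)
        self.partner = 1 - self.player
        if game.is_normal_form:
            self._reset_normal_form(game)
        else:
            self._reset_rsg(game)
        self._plan(max_sweeps=2000)

    # -- normal-form machinery -------------------------------------------
    def _reset_normal_form(self, game):
        s = game.start_stage
        self.n_own = game.n_actions(s, self.player)
        self.n_partner = game.n_actions(s, self.partner)
        self.joints = game.joint_actions(s)
        # states: one per previous joint action, plus initial state -1 (last)
        self.n_states = len(self.joints) + 1
        self.counts = np.ones((self.n_states, self.n_partner))
        own = game.payoff_matrix(self.player)
        if self.player == 1:
            own = own.T  # rows = own action, cols = partner action
        self.r_own = own
        # next-state index for (own action, partner action)
        self.next_state = np.empty((self.n_own, self.n_partner), dtype=int)
        for k, (a0, a1) in enumerate(self.joints):
            a_own, a_partner = (a0, a1) if self.player == 0 else (a1, a0)
            self.next_state[a_own, a_partner] = k
        self.V = np.zeros(self.n_states)
        self.Q = np.zeros((self.n_states, self.n_own))
        self.state = self.n_states - 1

    def _plan_normal_form(self, max_sweeps):
        probs = self.counts / self.counts.sum(axis=1, keepdims=True)
        S, A, Pn = self.n_states, self.n_own, self.n_partner
        P = np.zeros((S, A, S))
        for a in range(A):
            for p in range(Pn):
                P[:, a, self.next_state[a, p]] += probs[:, p]
        r = probs @ self.r_own.T  # (S, A)
        self.V, self.Q = _policy_iteration(P, r, self.gamma)

    # -- multi-stage machinery -------------------------------------------
    def _reset_rsg(self, game):
        self.stages = game.decision_stages
        self.counts_rsg = {
            s: np.ones(game.n_actions(s, self.partner)) for s in self.stages}
        self.V_rsg = {s: 0.0 for s in self.stages}
        self.state = None

    def _plan_rsg(self, max_sweeps):
        game, g = self.game, self.gamma
        start = game.start_stage
        for _ in range(max_sweeps):
            delta = 0.0
            for s in self.stages:
                probs = self.counts_rsg[s] / self.counts_rsg[s].sum()
                best = -np.inf
                for a_own in range(game.n_actions(s, self.player)):
                    q = 0.0
                    for a_p, p_a in enumerate(probs):
                        joint = (a_own, a_p) if self.player == 0 else (a_p, a_own)
                        val = game.rewards[(s, joint)][self.player]
                        for s2, p in game.transitions[(s, joint)].items():
                            val += p * (g * self.V_rsg[start]
                                        if s2 in game.goal_stages else self.V_rsg[s2])
                        q += p_a * val
                    best = max(best, q)
                delta = max(delta, abs(best - self.V_rsg[s]))
                self.V_rsg[s] = best
            if delta < self.tol:
                break

    def _plan(self, max_sweeps=60):
        if self.game.is_normal_form:
            self._plan_normal_form(max_sweeps)
        else:
            self._plan_rsg(max_sweeps)

    # -- expert interface -------------------------------------------------
    def act(self, stage, t):
        if self.game.is_normal_form:
            return int(np.argmax(self.Q[self.state]))
        game, g = self.game, self.gamma
        probs = self.counts_rsg[stage] / self.counts_rsg[stage].sum()
        best_a, best_q = 0, -np.inf
        for a_own in range(game.n_actions(stage, self.player)):
            q = 0.0
            for a_p, p_a in enumerate(probs):
                joint = (a_own, a_p) if self.player == 0 else (a_p, a_own)
                val = game.rewards[(stage, joint)][self.player]
                for s2, p in game.transitions[(stage, joint)].items():
                    val += p * (g * self.V_rsg[game.start_stage]
                                if s2 in game.goal_stages else self.V_rsg[s2])
                q += p_a * val
            if q > best_q:
                best_a, best_q = a_own, q
        return best_a

    def end_round(self, record, selected):
        self.last_event = None
        if self.game.is_normal_form:
            joint = record.joint_actions[0]
            a_partner = joint[self.partner]
            self.counts[self.state, a_partner] += 1
            self.state = self.next_state[joint[self.player], a_partner]
        else:
            for stage, joint in zip(record.stages, record.joint_actions):
                self.counts_rsg[stage][joint[self.partner]] += 1
        self._plan()

    def potential(self):
        if self.game.is_normal_form:
            v = self.V[self.state]
        else:
            v = self.V_rsg[self.game.start_stage]
        return (1 - self.gamma) * v


def build_expert_set(game: RepeatedStochasticGame, player: int,
                     omega_grid=None, mbrl_gamma: float = 0.95) -> list[Expert]:
    """The (up to) thirteen experts for one side of a game.

    Five followers and five triggers over the selected compromise solutions
    (fewer if fewer distinct solutions exist), the preventative and maximin
    strategies, and an MBRL expert.  Ids are stable: ``follower-k`` /
    ``trigger-k`` index the selected solutions in selection order.
    """
    solutions = select_five_solutions(enumerate_target_solutions(game, omega_grid), game)
    experts: list[Expert] = []
    for k, sol in enumerate(solutions):
        experts.append(FollowerExpert(f"follower-{k}", sol))
    for k, sol in enumerate(solutions):
        experts.append(TriggerExpert(f"trigger-{k}", sol))
    experts.append(PreventativeExpert("preventative"))
    experts.append(MaximinExpert("maximin"))
    experts.append(MBRLExpert("mbrl", gamma=mbrl_gamma))
    return experts
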