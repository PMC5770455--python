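"""Reference strategies for tournaments.

Implementations follow the canonical descriptions in the repeated-games
literature; parameter defaults are documented stand-ins, config-exposed on
each class.  Strategies that speak of "cooperating" in an arbitrary 2x2
game interpret cooperation as each player's component of the game's Nash
bargaining (mutual-cooperation) joint action.

A registry maps names to classes; further algorithms can be registered via
:func:`register`.
"""

from __future__ import annotations

import inspect

import numpy as np

from .experts import MBRLExpert, build_expert_set
from .games import RepeatedStochasticGame
from .match import Agent
from .planning import nash_bargaining_solution
from .selector import SAlgorithm, SPlusPlus
from .signaling import SSharp
from .solve import minimax_attack_strategy


class GameNotSupportedError(ValueError):
    """Raised when a strategy is applied to a game outside its domain."""


class NormalFormAgent(Agent):
    """Base for strategies defined only on normal-form (single-stage) games."""

    requires_binary = False

    def begin_match(self, game, player, rng):
        if not game.is_normal_form:
            raise GameNotSupportedError(
                f"{self.name} is defined only for normal-form games; "
                f"{game.name} has {len(game.decision_stages)} decision stages")
        if self.requires_binary and game.actions[game.start_stage] != (2, 2):
            raise GameNotSupportedError(
                f"{self.name} requires a 2x2 game; {game.name} is "
                f"{game.actions[game.start_stage]}")
        super().begin_match(game, player, rng)
        self.stage = game.start_stage
        self.partner = 1 - player
        own = game.payoff_matrix(player)
        self.own_payoffs = own if player == 0 else own.T  # rows = own action
        nbs = nash_bargaining_solution(game)
        coop_joint = nbs.policies[0][self.stage]
        self.coop_own = coop_joint[player]
        self.coop_partner = coop_joint[self.partner]
        self.last_joint = None

    def end_round(self, record):
        self.last_joint = record.joint_actions[0]


class RandomAgent(Agent):
    """Uniformly random action in every stage."""

    name = "random"

    def act(self, stage):
        return int(self.rng.integers(self.game.n_actions(stage, self.player)))


class GTFTAgent(NormalFormAgent):
    """Generous Tit-for-Tat (generalized).

    Cooperates after partner cooperation; after a partner defection it still
    cooperates with the generosity probability.  The default generosity is
    the classic payoff-based formula min(1 - (T-R)/(R-S), (R-P)/(T-P))
    evaluated on the player's own payoffs, clipped to [0, 1] and falling
    back to 0.1 when the formula is undefined for the game.
    """

    name = "gtft"
    requires_binary = True

    def __init__(self, generosity: float | None = None):
        self.generosity = generosity

    def begin_match(self, game, player, rng):
        super().begin_match(game, player, rng)
        if self.generosity is None:
            c, d = self.coop_own, 1 - self.coop_own
            cp, dp = self.coop_partner, 1 - self.coop_partner
            R = self.own_payoffs[c, cp]
            S = self.own_payoffs[c, dp]
            T = self.own_payoffs[d, cp]
            P = self.own_payoffs[d, dp]
            try:
                g = min(1 - (T - R) / (R - S), (R - P) / (T - P))
            except ZeroDivisionError:
                g = 0.1
            self.g = float(np.clip(g, 0.0, 1.0)) if np.isfinite(g) else 0.1
        else:
            self.g = self.generosity

    def act(self, stage):
        if self.last_joint is None:
            return self.coop_own
        if self.last_joint[self.partner] == self.coop_partner:
            return self.coop_own
        return self.coop_own if self.rng.random() < self.g else 1 - self.coop_own

class WSLSAgent(NormalFormAgent):
    """Win-stay, lose-shift.

    Starts by cooperating; repeats its previous action when the realized
    payoff reached the mutual-cooperation payoff, otherwise switches.
    """

    name = "wsls"
    requires_binary = True

    def begin_match(self, game, player, rng):
        super().begin_match(game, player, rng)
        self.aspiration = self.own_payoffs[self.coop_own, self.coop_partner]
        self.last_payoff = None

    def act(self, stage):
        if self.last_joint is None:
            return self.coop_own
        own_prev = self.last_joint[self.player]
        if self.last_payoff >= self.aspiration - 1e-9:
            return own_prev
        return 1 - own_prev

    def end_round(self, record):
        super().end_round(record)
        self.last_payoff = record.payoffs[self.player]


class BullyAgent(NormalFormAgent):
    """Demands its Stackelberg outcome; punishes beneficial resistance.

    The demand is the action whose partner best response maximizes the
    agent's own payoff.  A partner deviation from that best response that
    beats its best-response payoff triggers minimax punishment until the
    cumulative deviation gain is erased (same forgiveness accounting as
    trigger experts).
    """

    name = "bully"

    def begin_match(self, game, player, rng):
        super().begin_match(game, player, rng)
        n_own = game.n_actions(self.stage, player)
        n_partner = game.n_actions(self.stage, self.partner)
        partner_payoffs = game.payoff_matrix(self.partner)
        if player == 1:
            partner_payoffs = partner_payoffs.T  # rows = our action
        best_own, best_val, best_br = 0, -np.inf, 0
        for a in range(n_own):
            br = int(np.argmax(partner_payoffs[a]))
            val = self.own_payoffs[a, br]
            if val > best_val:
                best_own, best_val, best_br = a, val, br
        self.demand_own = best_own
        self.demand_partner = best_br
        self.partner_comply_payoff = float(partner_payoffs[best_own, best_br])
        self.attack, _ = minimax_attack_strategy(game, self.partner)
        self.punishing = False
        self.ledger_actual = 0.0
        self.ledger_cf = 0.0

    def act(self, stage):
        if self.punishing:
            probs = self.attack[stage]
            if probs.max() > 1 - 1e-12:
                return int(np.argmax(probs))
            return int(self.rng.choice(probs.size, p=probs / probs.sum()))
        return self.demand_own

    def end_round(self, record):
        super().end_round(record)
        partner_payoff = record.payoffs[self.partner]
        if self.punishing:
            self.ledger_actual += partner_payoff
            self.ledger_cf += self.partner_comply_payoff
            if self.ledger_actual < self.ledger_cf - 1e-9:
                self.punishing = False
        elif (self.last_joint[self.partner] != self.demand_partner
              and partner_payoff > self.partner_comply_payoff + 1e-9):
            self.punishing = True
            self.ledger_actual = partner_payoff
            self.ledger_cf = self.partner_comply_payoff


class Mem1Agent(NormalFormAgent):
    """Memory-one stochastic strategy.

    ``probs`` gives the cooperation probability conditioned on the previous
    round's (own, partner) moves in the order (CC, CD, DC, DD).  The default
    (1, 1/8, 1, 1/4) is a generous zero-determinant-flavored stand-in.
    """

    name = "mem1"
    requires_binary = True

    def __init__(self, probs=(1.0, 0.125, 1.0, 0.25), init_coop: float = 1.0):
        self.probs = tuple(probs)
        self.init_coop = init_coop

    def act(self, stage):
        if self.last_joint is None:
            p = self.init_coop
        else:
            own_c = self.last_joint[self.player] == self.coop_own
            partner_c = self.last_joint[self.partner] == self.coop_partner
            p = self.probs[{(True, True): 0, (True, False): 1,
                            (False, True): 2, (False, False): 3}[(own_c, partner_c)]]
        return self.coop_own if self.rng.random() < p else 1 - self.coop_own


class Mem2Agent(NormalFormAgent):
    """Memory-two stochastic strategy conditioned on the partner's last two
    moves; the default forgives a single defection slowly and a sustained
    one never (a stand-in vector, config-exposed)."""

    name = "mem2"
    requires_binary = True

    def __init__(self, probs=None, init_coop: float = 1.0):
        # keys: (partner cooperated two rounds ago, last round)
        self.probs = probs or {(True, True): 1.0, (False, True): 0.875,
                               (True, False): 0.125, (False, False): 0.0}
        self.init_coop = init_coop
        self.prev_joints = []

    def begin_match(self, game, player, rng):
        super().begin_match(game, player, rng)
        self.prev_joints = []

    def act(self, stage):
        if len(self.prev_joints) < 2:
            p = self.init_coop
        else:
            key = tuple(j[self.partner] == self.coop_partner
                        for j in self.prev_joints[-2:])
            p = self.probs[key]
        return self.coop_own if self.rng.random() < p else 1 - self.coop_own

    def end_round(self, record):
        super().end_round(record)
        self.prev_joints.append(record.joint_actions[0])


class FictitiousPlayAgent(NormalFormAgent):
    """Best response to the empirical mixture of partner actions
    (unit pseudo-counts; lowest-index tie-break)."""

    name = "fictitious"

    def begin_match(self, game, player, rng):
        super().begin_match(game, player, rng)
        self.counts = np.ones(game.n_actions(self.stage, self.partner))

    def act(self, stage):
        mix = self.counts / self.counts.sum()
        return int(np.argmax(self.own_payoffs @ mix))

    def end_round(self, record):
        super().end_round(record)
        self.counts[record.joint_actions[0][self.partner]] += 1


class MBRL1Agent(Agent):
    """Standalone model-based reinforcement learner (the MBRL expert)."""

    name = "mbrl1"

    def __init__(self, gamma: float = 0.95):
        self.gamma = gamma

    def begin_match(self, game, player, rng):
        super().begin_match(game, player, rng)
        self.expert = MBRLExpert("mbrl", gamma=self.gamma)
        self.expert.reset(game, player, rng)
        self.t = 1

    def act(self, stage):
        return self.expert.act(stage, self.t)

    def end_round(self, record):
        self.expert.end_round(record, selected=True)
        self.t = record.t + 1


class MBRL2Agent(NormalFormAgent):
    """Model-based learner whose state is the last *two* joint actions."""

    name = "mbrl2"

    def __init__(self, gamma: float = 0.95, tol: float = 1e-6):
        self.gamma = gamma
        self.tol = tol

    def begin_match(self, game, player, rng):
        super().begin_match(game, player, rng)
        s = self.stage
        self.n_own = game.n_actions(s, self.player)
        self.n_partner = game.n_actions(s, self.partner)
        joints = game.joint_actions(s)
        J = len(joints)
        self.J = J
        self.jidx = {j: k for k, j in enumerate(joints)}
        n = (J + 1) ** 2  # (two-back, one-back) with J = "none yet"
        self.counts = np.ones((n, self.n_partner))
        # map (own, partner) -> joint index
        self.joint_of = np.empty((self.n_own, self.n_partner), dtype=int)
        for j, k in self.jidx.items():
            a_own, a_p = (j[0], j[1]) if self.player == 0 else (j[1], j[0])
            self.joint_of[a_own, a_p] = k
        one_back = np.arange(n) % (J + 1)
        self.next_state = (one_back[:, None, None] * (J + 1)
                           + self.joint_of[None, :, :])  # (n, own, partner)
        self.V = np.zeros(n)
        self.state = J * (J + 1) + J
        self._plan(2000)

    def _plan(self, max_sweeps=60):
        from .experts import _policy_iteration
        probs = self.counts / self.counts.sum(axis=1, keepdims=True)
        S = self.counts.shape[0]
        A, Pn = self.n_own, self.n_partner
        P = np.zeros((S, A, S))
        for a in range(A):
            for p in range(Pn):
                np.add.at(P[:, a, :],
                          (np.arange(S), self.next_state[:, a, p]),
                          probs[:, p])
        r = probs @ self.own_payoffs.T  # (S, A)
        self.V, self.Q = _policy_iteration(P, r, self.gamma)

    def act(self, stage):
        return int(np.argmax(self.Q[self.state]))

    def end_round(self, record):
        super().end_round(record)
        joint = record.joint_actions[0]
        a_p = joint[self.partner]
        self.counts[self.state, a_p] += 1
        self.state = int(self.next_state[self.state, joint[self.player], a_p])
        self._plan()


class QLearningAgent(NormalFormAgent):
    """Tabular Q-learning over (previous joint action) states, epsilon-greedy."""

    name = "qlearning"

    def __init__(self, lr: float = 0.2, gamma: float = 0.95, epsilon: float = 0.1):
        self.lr = lr
        self.gamma = gamma
        self.epsilon = epsilon

    def begin_match(self, game, player, rng):
        super().begin_match(game, player, rng)
        joints = game.joint_actions(self.stage)
        self.jidx = {j: k for k, j in enumerate(joints)}
        self.n_own = game.n_actions(self.stage, self.player)
        self.Q = np.zeros((len(joints) + 1, self.n_own))
        self.state = len(joints)
        self.last_action = None

    def act(self, stage):
        if self.rng.random() < self.epsilon:
            a = int(self.rng.integers(self.n_own))
        else:
            a = int(np.argmax(self.Q[self.state]))
        self.last_action = a
        return a

    def end_round(self, record):
        super().end_round(record)
        nxt = self.jidx[record.joint_actions[0]]
        r = record.payoffs[self.player]
        a = self.last_action
        self.Q[self.state, a] += self.lr * (
            r + self.gamma * self.Q[nxt].max() - self.Q[self.state, a])
        self.state = nxt


class ExpertMetaAgent(Agent):
    """Shared epoch machinery for traditional expert-selection baselines
    (same expert set as S++, different selection rule)."""

    def __init__(self, m: int = 3, omega_grid=None):
        self.m = m
        self.omega_grid = omega_grid

    def begin_match(self, game, player, rng):
        super().begin_match(game, player, rng)
        self.experts = build_expert_set(game, player, self.omega_grid)
        for e in self.experts:
            e.reset(game, player, rng)
        self.t = 1
        self.epoch_rounds = 0
        self.epoch_total = 0.0
        self._setup()
        self.selected = self._choose()
        self.selected.on_selected()

    def _setup(self):
        pass

    def _choose(self):
        raise NotImplementedError

    def _record(self, mean_payoff: float):
        pass

    def act(self, stage):
        return self.selected.act(stage, self.t)

    def end_round(self, record):
        self.epoch_total += record.payoffs[self.player]
        self.epoch_rounds += 1
        for e in self.experts:
            e.end_round(record, selected=(e is self.selected))
        self.t = record.t + 1
        if self.epoch_rounds >= self.m:
            self._record(self.epoch_total / self.epoch_rounds)
            self.epoch_rounds = 0
            self.epoch_total = 0.0
            nxt = self._choose()
            if nxt is not self.selected:
                nxt.on_selected()
            self.selected = nxt

    def round_notes(self):
        return {"expert": self.selected.id}


class EEEAgent(ExpertMetaAgent):
    """Explore-exploit over experts: with probability ``explore`` pick a
    uniformly random expert for the epoch, otherwise the expert with the
    best empirical mean per-round payoff (optimistic initialization)."""

    name = "eee"

    def __init__(self, explore: float = 0.2, m: int = 3, omega_grid=None):
        super().__init__(m=m, omega_grid=omega_grid)
        self.explore = explore

    def _setup(self):
        self.stats = {e.id: [0.0, 0] for e in self.experts}
        self.optimistic = self.game.payoff_bounds()[1]

    def _estimate(self, eid):
        total, n = self.stats[eid]
        return self.optimistic if n == 0 else total / n

    def _choose(self):
        if self.rng.random() < self.explore:
            return self.experts[int(self.rng.integers(len(self.experts)))]
        return max(self.experts, key=lambda e: self._estimate(e.id))

    def _record(self, mean_payoff):
        st = self.stats[self.selected.id]
        st[0] += mean_payoff
        st[1] += 1


class Exp3Agent(ExpertMetaAgent):
    """Exp3 over experts: exponential weights with importance-weighted
    payoff estimates, payoffs normalized to [0, 1] by the game's range."""

    name = "exp3"

    def __init__(self, exploration: float = 0.1, m: int = 3, omega_grid=None):
        super().__init__(m=m, omega_grid=omega_grid)
        self.exploration = exploration

    def _setup(self):
        self.log_w = np.zeros(len(self.experts))
        lo, hi = self.game.payoff_bounds()
        self.lo, self.range = lo, max(hi - lo, 1e-12)
        self._last_prob = 1.0

    def _probs(self):
        g = self.exploration
        w = np.exp(self.log_w - self.log_w.max())
        return (1 - g) * w / w.sum() + g / len(self.experts)

    def _choose(self):
        p = self._probs()
        k = int(self.rng.choice(len(self.experts), p=p))
        self._last_prob = p[k]
        return self.experts[k]

    def _record(self, mean_payoff):
        x = (mean_payoff - self.lo) / self.range
        k = self.experts.index(self.selected)
        self.log_w[k] += self.exploration * (x / self._last_prob) / len(self.experts)


REGISTRY: dict[str, type] = {
    "random": RandomAgent,
    "gtft": GTFTAgent,
    "wsls": WSLSAgent,
    "bully": BullyAgent,
    "mem1": Mem1Agent,
    "mem2": Mem2Agent,
    "fictitious": FictitiousPlayAgent,
    "mbrl1": MBRL1Agent,
    "mbrl2": MBRL2Agent,
    "qlearning": QLearningAgent,
    "eee": EEEAgent,
    "exp3": Exp3Agent,
    "s": SAlgorithm,
    "s_plus_plus": SPlusPlus,
    "s_sharp": SSharp,
}

#: the registry subset used for scaled tournament evaluations
DEFAULT_TOURNAMENT = (
    "random", "gtft", "wsls", "bully", "mem1", "mem2", "fictitious",
    "mbrl1", "mbrl2", "qlearning", "eee", "exp3", "s_plus_plus",
)


def register(name: str, cls: type) -> None:
    """Add a strategy class to the registry (extension point)."""
    REGISTRY[name] = cls


def registry_lookup(name: str, **params) -> Agent:
    """Instantiate a registered strategy with validated parameters."""
    if name not in REGISTRY:
        raise KeyError(
            f"unknown strategy {name!r}; available: {', '.join(sorted(REGISTRY))}")
    cls = REGISTRY[name]
    sig = inspect.signature(cls.__init__)
    accepts_kwargs = any(p.kind is inspect.Parameter.VAR_KEYWORD
                         for p in sig.parameters.values())
    for key in params:
        if key not in sig.parameters and not accepts_kwargs:
            raise TypeError(
                f"{name} does not accept parameter {key!r}; "
                f"valid: {', '.join(k for k in sig.parameters if k != 'self')}")
    agent = cls(**params)
    agent.name = name
    return agent
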