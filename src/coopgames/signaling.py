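"""Cheap talk for S#: speech acts, per-expert Mealy machines, congruence
filtering, and trust-gated speaking/listening.

Each expert carries a finite-state machine with output (a Mealy machine)
whose states track behavioral expectations, punishment, and forgiveness;
algorithmic events (partner conformed / deviated / benefited from deviation
/ punishment complete) drive transitions whose outputs are speech-act ids.
A propose-plan act (#15) carries the expert's offer as an explicit
joint-action cycle in normal-form games, or as a high-level fairness
descriptor ("fair", "I/you get the higher payoff") in multi-stage games.

When the partner proposes a plan, S# prefers experts whose offers are
congruent with it: E(t) = {e in E_cong(t) : rho_e(t) >= alpha(t)}, falling
back to plain aspiration pruning when that set is empty.  Listening is
gated by the partner's track record of keeping its own proposals, and S#
goes silent after its proposals are repeatedly ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .experts import Expert
from .match import Message
from .planning import TargetSolution, enumerate_target_solutions, nash_bargaining_solution
from .selector import SPlusPlus, prune_experts

# ---------------------------------------------------------------------------
# speech-act catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeechAct:
    id: int
    category: str
    template: str
    has_payload: bool = False


#: Default catalog.  Ids #0, #5-6, #11-15 carry the categories used by the
#: trigger machine; the remaining ids are documented placeholders so that
#: indices stay aligned with the canonical numbering, and their semantics
#: can be edited via a custom catalog.
DEFAULT_CATALOG: dict[int, SpeechAct] = {a.id: a for a in [
    SpeechAct(0, "threat", "Do what I say, or I'll punish you."),
    SpeechAct(1, "placeholder", "(unassigned speech act #1)"),
    SpeechAct(2, "placeholder", "(unassigned speech act #2)"),
    SpeechAct(3, "placeholder", "(unassigned speech act #3)"),
    SpeechAct(4, "forgive", "I forgive you. Let's start over."),
    SpeechAct(5, "praise", "Nicely done."),
    SpeechAct(6, "praise", "We are getting rich together."),
    SpeechAct(7, "placeholder", "(unassigned speech act #7)"),
    SpeechAct(8, "placeholder", "(unassigned speech act #8)"),
    SpeechAct(9, "placeholder", "(unassigned speech act #9)"),
    SpeechAct(10, "placeholder", "(unassigned speech act #10)"),
    SpeechAct(11, "displeasure", "That was not what I expected."),
    SpeechAct(12, "displeasure", "You betrayed me."),
    SpeechAct(13, "punishment-notice", "You will pay for that."),
    SpeechAct(14, "gloat", "Serves you right."),
    SpeechAct(15, "expectation", "Here is my plan for us.", True),
]}

PROPOSE_ACT = 15

#: event symbols: partner conformed, deviated, benefited-from-deviation,
#: punishment ongoing, punishment complete (forgiveness)
EVENTS = ("s", "d", "g", "p", "f")


# ---------------------------------------------------------------------------
# Mealy machines
# ---------------------------------------------------------------------------

class SpeechFSM:
    """A deterministic Mealy machine over the event alphabet.

    ``transitions[(state, event)] = (next_state, output_act_ids)``; every
    (state, event) pair is defined (totality is property-tested).
    """

    def __init__(self, states, transitions, initial_output, start="s0",
                 after_start="s1"):
        self.states = tuple(states)
        self.transitions = dict(transitions)
        self.initial_output = frozenset(initial_output)
        self.start = start
        self.after_start = after_start
        self.reset()

    def reset(self):
        self.state = self.start

    def initial(self) -> frozenset:
        """The start transition (s0 -> s1): voice expectations upfront."""
        self.state = self.after_start
        return self.initial_output

    def step(self, event: str) -> frozenset:
        nxt, out = self.transitions[(self.state, event)]
        self.state = nxt
        return out


def _expectation_chain(n_last: int, punish: bool) -> dict:
    """Transitions for the expectation states s1..s{n_last}."""
    trans = {}
    propose = frozenset({PROPOSE_ACT, 0}) if punish else frozenset({PROPOSE_ACT})
    for k in range(1, n_last + 1):
        s = f"s{k}"
        nxt = f"s{min(k + 1, n_last)}"
        praise = frozenset({5}) if k < n_last else frozenset({6})
        trans[(s, "s")] = (nxt, praise)
        trans[(s, "d")] = ("s1", frozenset({11, 12}))
        if punish:
            trans[(s, "g")] = ("s7", frozenset({13}))
            trans[(s, "p")] = ("s7", frozenset({13}))
        else:
            trans[(s, "g")] = ("s1", frozenset({11, 12}))
            trans[(s, "p")] = ("s1", propose)
        trans[(s, "f")] = ("s1", propose)
    return trans


def build_fsm(expert: Expert) -> SpeechFSM:
    """The speech-generation machine for an expert.

    Triggers get the nine-state machine (expectation chain s0-s6,
    punishment state s7 announcing and relishing punishment, forgiveness
    state s8 that renews expectations).  Followers get the same machine
    without the punishment states.  Experts without an offer (maximin,
    preventative, MBRL) get a minimal machine that voices an expectation up
    front and then stays quiet.
    """
    propose_threat = frozenset({PROPOSE_ACT, 0})
    if expert.kind == "trigger":
        trans = _expectation_chain(6, punish=True)
        for ev in ("s", "d", "g", "p"):
            trans[("s7", ev)] = ("s7", frozenset({14}))
        trans[("s7", "f")] = ("s8", frozenset({4}))
        for ev in EVENTS:
            trans[("s8", ev)] = ("s1", propose_threat)
            trans[("s0", ev)] = ("s1", propose_threat)
        states = tuple(f"s{k}" for k in range(9))
        return SpeechFSM(states, trans, propose_threat)
    if expert.kind == "follower":
        trans = _expectation_chain(6, punish=False)
        for ev in EVENTS:
            trans[("s0", ev)] = ("s1", frozenset({PROPOSE_ACT}))
        states = tuple(f"s{k}" for k in range(7))
        return SpeechFSM(states, trans, frozenset({PROPOSE_ACT}))
    if expert.kind in ("maximin", "preventative", "mbrl"):
        trans = {}
        for ev in EVENTS:
            trans[("s0", ev)] = ("s1", frozenset({PROPOSE_ACT}))
            trans[("s1", ev)] = ("s1", frozenset())
        return SpeechFSM(("s0", "s1"), trans, frozenset({PROPOSE_ACT}))
    raise ValueError(f"no speech machine for expert kind {expert.kind!r}")


# ---------------------------------------------------------------------------
# plan payloads: joint-action cycles (normal form) or fairness descriptors
# ---------------------------------------------------------------------------

FAIR, I_HIGHER, YOU_HIGHER = "fair", "i_higher", "you_higher"
_FLIP = {FAIR: FAIR, I_HIGHER: YOU_HIGHER, YOU_HIGHER: I_HIGHER}


def solution_descriptor(game, solution: TargetSolution, speaker: int,
                        fair_tol: float = 0.1) -> str:
    """High-level descriptor of a solution, from the speaker's perspective.

    A payoff pair within ``fair_tol`` of the payoff range of the Nash
    bargaining profile counts as "fair"/cooperative; otherwise the solution
    is described by who gets the higher payoff.
    """
    nbs = nash_bargaining_solution(game)
    lo, hi = game.payoff_bounds()
    tol = fair_tol * (hi - lo)
    dv = max(abs(solution.payoffs[0] - nbs.payoffs[0]),
             abs(solution.payoffs[1] - nbs.payoffs[1]))
    if dv <= tol:
        return FAIR
    me, other = solution.payoffs[speaker], solution.payoffs[1 - speaker]
    return I_HIGHER if me > other else YOU_HIGHER


def plan_payload(game, solution: TargetSolution, speaker: int,
                 fair_tol: float = 0.1):
    """Wire payload for a propose-plan act."""
    if game.is_normal_form:
        return solution.cycle(game.start_stage)
    return solution_descriptor(game, solution, speaker, fair_tol)


def _cycles_equal(c1, c2) -> bool:
    """Cyclic equality of joint-action cycles (phase-shift invariant)."""
    c1, c2 = tuple(c1), tuple(c2)
    if len(c1) != len(c2):
        return False
    return any(c1 == c2[k:] + c2[:k] for k in range(len(c2)))


def payload_matches(game, offer: TargetSolution, payload, listener: int,
                    fair_tol: float = 0.1) -> bool:
    """Is an expert's offer congruent with a proposed payload?

    ``payload`` is in the proposer's (the listener's partner's) terms.
    """
    if offer is None or payload is None:
        return False
    if game.is_normal_form:
        try:
            return _cycles_equal(offer.cycle(game.start_stage), payload)
        except (TypeError, KeyError):
            return False
    if payload not in _FLIP:
        return False
    own_view = solution_descriptor(game, offer, listener, fair_tol)
    return own_view == _FLIP[payload]


def parse_proposal(messages, game, solutions, speaker: int,
                   fair_tol: float = 0.1) -> TargetSolution | None:
    """Map a propose-plan act to the matching candidate solution.

    Normal-form payloads must match a candidate's joint-action cycle
    exactly (up to phase); multi-stage descriptors pick the candidate whose
    payoff profile is nearest the Nash bargaining profile ("fair") or the
    candidate maximizing the speaker's / listener's payoff.  Returns None
    when no message is a proposal or the payload is malformed.
    """
    payload = None
    for msg in messages:
        if msg.act == PROPOSE_ACT and msg.payload is not None:
            payload = msg.payload
    if payload is None or not solutions:
        return None
    if game.is_normal_form:
        if not isinstance(payload, tuple):
            return None
        for sol in solutions:
            if _cycles_equal(sol.cycle(game.start_stage), payload):
                return sol
        return None
    if payload == FAIR:
        nbs = nash_bargaining_solution(game)
        return min(solutions, key=lambda s: (s.payoffs[0] - nbs.payoffs[0]) ** 2
                   + (s.payoffs[1] - nbs.payoffs[1]) ** 2)
    if payload == I_HIGHER:
        return max(solutions, key=lambda s: s.payoffs[speaker])
    if payload == YOU_HIGHER:
        return max(solutions, key=lambda s: s.payoffs[1 - speaker])
    return None


def congruent_experts(experts, payload, potentials: dict, alpha: float,
                      game, listener: int, fair_tol: float = 0.1) -> list:
    """Aspiration-pruned experts congruent with the partner's proposal.

    Falls back to plain aspiration pruning when no congruent expert clears
    the aspiration.
    """
    cong = [e.id for e in experts
            if payload_matches(game, e.offer, payload, listener, fair_tol)]
    kept = [eid for eid in cong if potentials[eid] >= alpha]
    if not kept:
        return prune_experts(potentials, alpha)
    return kept


# ---------------------------------------------------------------------------
# trust
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrustState:
    """Speak/listen gating state.

    ``follow_rate`` smooths whether the partner keeps its own proposals;
    the listen probability equals it.  Speaking shuts off after
    ``patience`` consecutive epochs in which the agent's own proposals were
    not followed, and resumes after any followed proposal.
    """

    follow_rate: float = 1.0
    consec_ignored: int = 0
    speak: bool = True
    retention: float = 0.8
    patience: int = 3

    @property
    def listen_prob(self) -> float:
        return self.follow_rate


def update_trust(trust: TrustState,
                 partner_kept_proposal: bool | None = None,
                 own_proposal_followed: bool | None = None) -> TrustState:
    """Epoch update; ``None`` means no proposal of that kind was on the table."""
    follow = trust.follow_rate
    if partner_kept_proposal is not None:
        follow = trust.retention * follow + (1 - trust.retention) * float(partner_kept_proposal)
    consec, speak = trust.consec_ignored, trust.speak
    if own_proposal_followed is not None:
        if own_proposal_followed:
            consec, speak = 0, True
        else:
            consec += 1
            if consec >= trust.patience:
                speak = False
    return replace(trust, follow_rate=follow, consec_ignored=consec, speak=speak)


# ---------------------------------------------------------------------------
# the S# agent
# ---------------------------------------------------------------------------

class SSharp(SPlusPlus):
    """S#: S++ plus cheap-talk generation and response.

    Without cheap talk (``talk`` disabled in the match) the agent never
    speaks, hears nothing, and draws no extra randomness, so its behavior
    is identical to S++ under the same seed.
    """

    name = "s_sharp"

    def __init__(self, lam: float = 0.95, m: int = 3, omega_grid=None,
                 mbrl_gamma: float = 0.95, fair_tol: float = 0.1,
                 listen_retention: float = 0.8, patience: int = 3):
        super().__init__(lam=lam, m=m, omega_grid=omega_grid,
                         prune=True, mbrl_gamma=mbrl_gamma)
        self.fair_tol = fair_tol
        self.listen_retention = listen_retention
        self.patience = patience

    def begin_match(self, game, player, rng):
        self._fsms: dict[str, SpeechFSM] = {}
        self.trust = TrustState(retention=self.listen_retention,
                                patience=self.patience)
        self.partner_payload = None  # latest proposal heard (raw payload)
        self.own_payload = None      # latest plan we proposed
        self._epoch_partner_actions = []
        self._need_initial = False
        self.sent_proposals = []  # (round, expert id, payload) fidelity log
        self._listened = False
        super().begin_match(game, player, rng)

    # -- selector hooks ---------------------------------------------------
    def _on_new_epoch(self):
        self._need_initial = True

    def _candidate_ids(self, potentials):
        if self.partner_payload is not None:
            self._listened = self.rng.random() < self.trust.listen_prob
            if self._listened:
                return congruent_experts(self.experts, self.partner_payload,
                                         potentials, self.alpha, self.game,
                                         self.player, self.fair_tol)
        return prune_experts(potentials, self.alpha)

    # -- cheap talk -------------------------------------------------------
    def _fsm(self, expert) -> SpeechFSM:
        if expert.id not in self._fsms:
            self._fsms[expert.id] = build_fsm(expert)
        return self._fsms[expert.id]

    def speak(self, t):
        expert = self.selected
        fsm = self._fsm(expert)
        if self._need_initial:
            fsm.reset()
            acts = fsm.initial()
            self._need_initial = False
        elif expert.last_event is not None:
            acts = fsm.step(expert.last_event)
        else:
            acts = frozenset()
        if not self.trust.speak:
            return ()
        out = []
        for act in sorted(acts):
            if act == PROPOSE_ACT and expert.offer is not None:
                payload = plan_payload(self.game, expert.offer, self.player,
                                       self.fair_tol)
                self.own_payload = payload
                self._own_offer = expert.offer
                self.sent_proposals.append((t, expert.id, payload))
                out.append(Message(act, payload))
            else:
                out.append(Message(act))
        return tuple(out)

    def hear(self, t, messages):
        for msg in messages:
            if msg.act == PROPOSE_ACT and msg.payload is not None:
                self.partner_payload = msg.payload

    # -- epoch bookkeeping ------------------------------------------------
    def _offer_kept(self, offer, actor: int) -> bool | None:
        """Did ``actor`` mostly play its side of ``offer`` this epoch?"""
        if offer is None or not self._epoch_partner_actions:
            return None
        hits = 0
        for t, pairs in self._epoch_partner_actions:
            policy = offer.phase(t)
            hits += all(policy.get(stage) is not None
                        and joint[actor] == policy[stage][actor]
                        for stage, joint in pairs)
        return hits * 2 >= len(self._epoch_partner_actions)

    def end_round(self, record):
        partner = 1 - self.player
        self._epoch_partner_actions.append(
            (record.t, tuple(zip(record.stages, record.joint_actions))))
        boundary = self.epoch_rounds + 1 >= self.m
        if boundary:
            partner_solution = parse_proposal(
                (Message(PROPOSE_ACT, self.partner_payload),)
                if self.partner_payload is not None else (),
                self.game, enumerate_target_solutions(self.game, self.omega_grid),
                speaker=partner, fair_tol=self.fair_tol)
            kept = self._offer_kept(partner_solution, partner)
            own = self._offer_kept(getattr(self, "_own_offer", None), partner) \
                if self.own_payload is not None else None
            self.trust = update_trust(self.trust, kept, own)
            self._epoch_partner_actions = []
        super().end_round(record)

    def round_notes(self):
        notes = super().round_notes()
        notes["fsm_state"] = self._fsm(self.selected).state
        notes["listen_prob"] = round(self.trust.listen_prob, 4)
        notes["speak"] = self.trust.speak
        return notes
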