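"""Match simulation: the round loop, cheap-talk exchange, and history records.

Per round, talk-enabled matches first collect both players' message sets
simultaneously (neither agent sees the partner's current messages before
committing its own), then play stages from the start stage until a goal
stage is reached.  A hard per-round stage cap guards against non-terminating
behavior in misbehaving agents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np


class Message(NamedTuple):
    """A cheap-talk utterance: a speech-act id plus optional plan payload."""

    act: int
    payload: object = None


class AgentError(RuntimeError):
    """Raised when an agent violates the agent contract mid-match."""


class Agent:
    """Contract for match participants.

    Lifecycle per match: :meth:`begin_match` once, then per round (in order)
    :meth:`speak` / :meth:`hear` (talk-enabled matches only), :meth:`act`
    for each stage, :meth:`observe_step` after each stage resolves, and
    :meth:`end_round` once the round terminates.
    """

    name = "agent"

    def begin_match(self, game, player: int, rng: np.random.Generator) -> None:
        self.game = game
        self.player = player
        self.rng = rng

    def speak(self, t: int) -> tuple[Message, ...]:
        """Messages to send before round ``t``; default silence."""
        return ()

    def hear(self, t: int, messages: tuple[Message, ...]) -> None:
        """Receive the partner's round-``t`` messages."""

    def act(self, stage) -> int:
        raise NotImplementedError

    def observe_step(self, stage, joint, rewards, next_stage) -> None:
        """Observe one resolved stage within the current round."""

    def end_round(self, record: "RoundRecord") -> None:
        """Observe the completed round (including the partner's messages)."""

    def round_notes(self) -> dict:
        """Diagnostics stored in the round record (expert id, machine state...)."""
        return {}


@dataclass(slots=True)
class RoundRecord:
    """One completed round of a match."""

    t: int
    stages: tuple
    joint_actions: tuple
    step_rewards: tuple
    payoffs: tuple  # per-player sums over the round's stages
    messages: tuple  # (messages sent by player 0, by player 1)
    notes: tuple  # (player-0 diagnostics, player-1 diagnostics)
    capped: bool = False


@dataclass
class MatchHistory:
    """Full trace of a match between two agents."""

    game_name: str
    agent_names: tuple
    seed: int
    talk: bool
    rounds: list = field(default_factory=list)
    cumulative: tuple = (0.0, 0.0)

    def __len__(self) -> int:
        return len(self.rounds)

    def append(self, record: RoundRecord) -> None:
        self.rounds.append(record)
        self.cumulative = (self.cumulative[0] + record.payoffs[0],
                           self.cumulative[1] + record.payoffs[1])

    def mean_payoffs(self) -> tuple[float, float]:
        n = max(len(self.rounds), 1)
        return (self.cumulative[0] / n, self.cumulative[1] / n)

    def joint_action_rounds(self):
        """Per-round tuples of (stage, joint action) pairs."""
        return [tuple(zip(r.stages, r.joint_actions)) for r in self.rounds]


def run_match(agent0: Agent, agent1: Agent, game, n_rounds: int, seed: int,
              talk: bool = False, stage_cap: int = 50) -> MatchHistory:
    """Simulate ``n_rounds`` rounds of ``game`` between two agents.

    The root seed is split into three independent streams (environment,
    agent 0, agent 1), so results do not depend on the order in which agent
    code consumes randomness.  Identical inputs reproduce the history
    bit-exactly.
    """
    ss = np.random.SeedSequence(seed)
    env_rng, rng0, rng1 = (np.random.default_rng(s) for s in ss.spawn(3))
    agent0.begin_match(game, 0, rng0)
    agent1.begin_match(game, 1, rng1)
    history = MatchHistory(game.name, (agent0.name, agent1.name), seed, talk)
    goal = game.goal_stages
    for t in range(1, n_rounds + 1):
        if talk:
            m0 = tuple(agent0.speak(t))
            m1 = tuple(agent1.speak(t))
            agent0.hear(t, m1)
            agent1.hear(t, m0)
        else:
            m0 = m1 = ()
        stages, joints, step_rewards = [], [], []
        p0 = p1 = 0.0
        stage = game.start_stage
        capped = False
        for _step in range(stage_cap):
            a0 = agent0.act(stage)
            a1 = agent1.act(stage)
            n0, n1 = game.actions[stage]
            if not (isinstance(a0, (int, np.integer)) and 0 <= a0 < n0):
                raise AgentError(
                    f"agent {agent0.name!r} (player 0) returned action {a0!r} "
                    f"outside A_0({stage!r}) in round {t}")
            if not (isinstance(a1, (int, np.integer)) and 0 <= a1 < n1):
                raise AgentError(
                    f"agent {agent1.name!r} (player 1) returned action {a1!r} "
                    f"outside A_1({stage!r}) in round {t}")
            joint = (int(a0), int(a1))
            r = game.rewards[(stage, joint)]
            dist = game.transitions[(stage, joint)]
            if len(dist) == 1:
                (nxt,) = dist
            else:
                targets = list(dist)
                probs = np.array([dist[s2] for s2 in targets])
                nxt = targets[env_rng.choice(len(targets), p=probs / probs.sum())]
            stages.append(stage)
            joints.append(joint)
            step_rewards.append(r)
            p0 += r[0]
            p1 += r[1]
            agent0.observe_step(stage, joint, r, nxt)
            agent1.observe_step(stage, joint, r, nxt)
            stage = nxt
            if stage in goal:
                break
        else:
            capped = True
        record = RoundRecord(
            t=t, stages=tuple(stages), joint_actions=tuple(joints),
            step_rewards=tuple(step_rewards), payoffs=(p0, p1),
            messages=(m0, m1), notes=({}, {}), capped=capped)
        agent0.end_round(record)
        agent1.end_round(record)
        record.notes = (agent0.round_notes(), agent1.round_notes())
        history.append(record)
    return history
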