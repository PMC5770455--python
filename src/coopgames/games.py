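"""Two-player repeated stochastic games (RSGs).

An RSG is played in rounds.  Each round starts in the start stage and the
players simultaneously pick actions stage after stage until a goal stage is
entered, at which point the round ends and a new round begins from the start
stage.  Rewards accrue per (stage, joint action); stage transitions may be
stochastic.  A two-player normal-form game is the special case with a single
decision stage whose every joint action leads straight to a goal stage, so
each round is a single simultaneous move.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

Joint = tuple[int, int]

#: tolerance for transition rows summing to one
_PROB_TOL = 1e-12


class GameValidationError(ValueError):
    """Raised when a game definition violates the RSG contract."""


@dataclass(eq=False)
class RepeatedStochasticGame:
    """A two-player repeated stochastic game.

    Parameters
    ----------
    name : str
        Identifier used in logs and game files.
    stages : tuple
        All stage identifiers, including goal stages.
    actions : dict
        ``stage -> (n_actions_player0, n_actions_player1)`` for every
        non-goal stage.
    rewards : dict
        ``(stage, (a0, a1)) -> (r0, r1)`` for every non-goal stage and joint
        action.
    transitions : dict
        ``(stage, (a0, a1)) -> {next_stage: probability}``.
    start_stage :
        Stage in which every round begins.
    goal_stages : frozenset
        Entering any of these ends the round.
    family : str
        Optional payoff-family tag (benchmark taxonomy).
    """

    name: str
    stages: tuple
    actions: dict
    rewards: dict
    transitions: dict
    start_stage: object
    goal_stages: frozenset
    family: str = ""
    #: per-instance scratch cache for derived quantities (planning results,
    #: security levels, the bargaining solution); keyed by the computing code.
    cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.goal_stages = frozenset(self.goal_stages)
        self.stages = tuple(self.stages)
        self._validate()

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def _validate(self) -> None:
        stage_set = set(self.stages)
        if self.start_stage not in stage_set:
            raise GameValidationError(
                f"{self.name}: start stage {self.start_stage!r} not in stages")
        if not self.goal_stages <= stage_set:
            raise GameValidationError(f"{self.name}: goal stages not in stages")
        if self.start_stage in self.goal_stages:
            raise GameValidationError(
                f"{self.name}: start stage may not be a goal stage")
        for s in self.decision_stages:
            if s not in self.actions:
                raise GameValidationError(f"{self.name}: no action sets for stage {s!r}")
            n0, n1 = self.actions[s]
            if n0 < 1 or n1 < 1:
                raise GameValidationError(f"{self.name}: empty action set in stage {s!r}")
            for a in self.joint_actions(s):
                if (s, a) not in self.rewards:
                    raise GameValidationError(
                        f"{self.name}: missing reward for stage {s!r}, action {a}")
                if (s, a) not in self.transitions:
                    raise GameValidationError(
                        f"{self.name}: missing transition for stage {s!r}, action {a}")
                dist = self.transitions[(s, a)]
                total = 0.0
                for s2, p in dist.items():
                    if s2 not in stage_set:
                        raise GameValidationError(
                            f"{self.name}: transition from {s!r}/{a} targets "
                            f"unknown stage {s2!r}")
                    if p < 0:
                        raise GameValidationError(
                            f"{self.name}: negative probability in row {s!r}/{a}")
                    total += p
                if abs(total - 1.0) > _PROB_TOL:
                    raise GameValidationError(
                        f"{self.name}: transition row for stage {s!r}, action {a} "
                        f"sums to {total!r}, not 1")
        self._check_termination()

    def _check_termination(self) -> None:
        """Rounds must end almost surely under *every* joint policy.

        A policy can avoid the goal stages forever iff there is a non-empty
        set C of non-goal stages such that every stage in C has some joint
        action whose transition support stays inside C.  We compute the
        greatest such C (a greatest fixed point) restricted to stages
        reachable from the start stage and require it to be empty.
        """
        reachable = {self.start_stage}
        frontier = [self.start_stage]
        while frontier:
            s = frontier.pop()
            if s in self.goal_stages:
                continue
            for a in self.joint_actions(s):
                for s2, p in self.transitions[(s, a)].items():
                    if p > 0 and s2 not in reachable:
                        reachable.add(s2)
                        frontier.append(s2)
        closed = {s for s in reachable if s not in self.goal_stages}
        changed = True
        while changed:
            changed = False
            for s in list(closed):
                ok = any(
                    all(s2 in closed for s2, p in self.transitions[(s, a)].items() if p > 0)
                    for a in self.joint_actions(s)
                )
                if not ok:
                    closed.discard(s)
                    changed = True
        if closed:
            raise GameValidationError(
                f"{self.name}: rounds may never terminate from stages {sorted(map(str, closed))} "
                "(a joint policy can avoid every goal stage forever)")

    # ------------------------------------------------------------------
    # structure accessors
    # ------------------------------------------------------------------
    @property
    def decision_stages(self) -> tuple:
        """Stages in which actions are taken (all non-goal stages)."""
        return tuple(s for s in self.stages if s not in self.goal_stages)

    def joint_actions(self, stage) -> list[Joint]:
        n0, n1 = self.actions[stage]
        return [(a0, a1) for a0 in range(n0) for a1 in range(n1)]

    def n_actions(self, stage, player: int) -> int:
        return self.actions[stage][player]

    @property
    def is_normal_form(self) -> bool:
        """True when every round is a single simultaneous move."""
        if len(self.decision_stages) != 1:
            return False
        (s,) = self.decision_stages
        if s != self.start_stage:
            return False
        return all(
            set(self.transitions[(s, a)]) <= self.goal_stages
            for a in self.joint_actions(s)
        )

    def payoff_matrix(self, player: int) -> np.ndarray:
        """The stage payoff matrix of ``player`` for a normal-form game.

        Rows index player 0's actions, columns player 1's.
        """
        if not self.is_normal_form:
            raise GameValidationError(f"{self.name} is not a normal-form game")
        s = self.start_stage
        n0, n1 = self.actions[s]
        m = np.empty((n0, n1))
        for a0 in range(n0):
            for a1 in range(n1):
                m[a0, a1] = self.rewards[(s, (a0, a1))][player]
        return m

    def payoff_bounds(self) -> tuple[float, float]:
        """(min, max) over all stage rewards of both players."""
        vals = [v for pair in self.rewards.values() for v in pair]
        return min(vals), max(vals)

    def __repr__(self) -> str:  # compact: games can have thousands of stages
        return (f"RepeatedStochasticGame({self.name!r}, "
                f"{len(self.stages)} stages, family={self.family!r})")


def normal_form(name: str, payoffs, family: str = "") -> RepeatedStochasticGame:
    """Build the single-stage RSG encoding a two-player normal-form game.

    ``payoffs[a0][a1]`` is the pair ``(r0, r1)``.
    """
    arr = np.asarray(payoffs, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise GameValidationError(
            f"{name}: payoffs must have shape (n0, n1, 2), got {arr.shape}")
    n0, n1 = arr.shape[:2]
    s, g = "play", "end"
    rewards = {}
    transitions = {}
    for a0 in range(n0):
        for a1 in range(n1):
            rewards[(s, (a0, a1))] = (float(arr[a0, a1, 0]), float(arr[a0, a1, 1]))
            transitions[(s, (a0, a1))] = {g: 1.0}
    return RepeatedStochasticGame(
        name=name,
        stages=(s, g),
        actions={s: (n0, n1)},
        rewards=rewards,
        transitions=transitions,
        start_stage=s,
        goal_stages=frozenset({g}),
        family=family,
    )
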