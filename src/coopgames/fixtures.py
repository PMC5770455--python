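"""Named study games, random ordinal games, and a configurable block game.

The 0-1-3-5 prisoner's dilemma carries its canonical cardinal payoffs
(mutual cooperation 3, mutual defection 1, temptation 5, sucker 0).  The
chicken and alternator payoffs are stand-in cardinalizations chosen so the
games have the intended structure (chicken: mutual daring is the disaster
outcome; alternator: the bargaining solution alternates between the two
asymmetric outcomes); they are not calibrated to any external source.

The block game is a turn-taking multi-stage game: two players draft blocks
from a shared pool, scoring their final sets (monochrome sets score their
summed values, mixed sets score negative).  Its defaults are illustrative,
configurable, and likewise not calibrated.
"""

from __future__ import annotations

import itertools

import numpy as np

from .games import RepeatedStochasticGame, normal_form

PD_0135 = [[(3, 3), (0, 5)], [(5, 0), (1, 1)]]
CHICKEN_0135 = [[(3, 3), (1, 5)], [(5, 1), (0, 0)]]
ALTERNATOR = [[(2, 2), (1, 4)], [(4, 1), (0, 0)]]
MATCHING_PENNIES = [[(1, -1), (-1, 1)], [(-1, 1), (1, -1)]]


def pd_0135() -> RepeatedStochasticGame:
    return normal_form("pd_0135", PD_0135, family="prisoners-dilemma")


def chicken_0135() -> RepeatedStochasticGame:
    return normal_form("chicken_0135", CHICKEN_0135, family="chicken")


def alternator_game() -> RepeatedStochasticGame:
    return normal_form("alternator", ALTERNATOR, family="battle")


def matching_pennies() -> RepeatedStochasticGame:
    return normal_form("matching_pennies", MATCHING_PENNIES, family="zero-sum")


def random_ordinal_game(seed: int, name: str | None = None) -> RepeatedStochasticGame:
    """A random strict-ordinal 2x2 game (each player's payoffs permute 1..4)."""
    rng = np.random.default_rng(seed)
    p0 = rng.permutation([1, 2, 3, 4])
    p1 = rng.permutation([1, 2, 3, 4])
    outcomes = [(0, 0), (0, 1), (1, 0), (1, 1)]
    payoffs = [[None, None], [None, None]]
    for k, (a0, a1) in enumerate(outcomes):
        payoffs[a0][a1] = (int(p0[k]), int(p1[k]))
    return normal_form(name or f"random_ordinal_{seed}", payoffs)


#: default block set: (value, shape); three blocks of each shape
DEFAULT_BLOCKS = (
    (9, "square"), (8, "square"), (7, "square"),
    (6, "circle"), (5, "circle"), (4, "circle"),
    (3, "triangle"), (2, "triangle"), (1, "triangle"),
)


def block_game(blocks=DEFAULT_BLOCKS, picks_per_player: int = 3,
               name: str = "block_game") -> RepeatedStochasticGame:
    """Turn-taking block drafting as a repeated stochastic game.

    Each round, players alternate (player 0 first) picking blocks from the
    shared pool until each holds ``picks_per_player``.  A monochrome set
    scores the sum of its block values; a mixed set scores the negated sum.
    Stages encode (player-0 holdings, player-1 holdings); only the player
    to move has a real choice (the other has a single pass action).
    """
    blocks = tuple(blocks)
    n = len(blocks)
    if 2 * picks_per_player > n:
        raise ValueError("not enough blocks for the requested picks")

    def score(holding) -> float:
        vals = [blocks[b][0] for b in holding]
        shapes = {blocks[b][1] for b in holding}
        total = float(sum(vals))
        return total if len(shapes) <= 1 else -total

    goal = "done"
    start = ((), ())
    stages = [start]
    actions, rewards, transitions = {}, {}, {}
    frontier = [start]
    seen = {start}
    while frontier:
        state = frontier.pop()
        t0, t1 = state
        mover = 0 if len(t0) == len(t1) else 1
        remaining = sorted(set(range(n)) - set(t0) - set(t1))
        acts = len(remaining)
        actions[state] = (acts, 1) if mover == 0 else (1, acts)
        for k, b in enumerate(remaining):
            joint = (k, 0) if mover == 0 else (0, k)
            n0, n1 = (tuple(sorted(t0 + (b,))), t1) if mover == 0 \
                else (t0, tuple(sorted(t1 + (b,))))
            finished = len(n0) == picks_per_player and len(n1) == picks_per_player
            if finished:
                rewards[(state, joint)] = (score(n0), score(n1))
                transitions[(state, joint)] = {goal: 1.0}
            else:
                rewards[(state, joint)] = (0.0, 0.0)
                nxt = (n0, n1)
                transitions[(state, joint)] = {nxt: 1.0}
                if nxt not in seen:
                    seen.add(nxt)
                    stages.append(nxt)
                    frontier.append(nxt)
    stages.append(goal)
    return RepeatedStochasticGame(
        name=name, stages=tuple(stages), actions=actions, rewards=rewards,
        transitions=transitions, start_stage=start,
        goal_stages=frozenset({goal}), family="block")


_NAMED = {
    "pd_0135": pd_0135,
    "chicken_0135": chicken_0135,
    "alternator": alternator_game,
    "matching_pennies": matching_pennies,
    "block_game": block_game,
}


def make_fixture(name: str, seed: int | None = None,
                 **config) -> RepeatedStochasticGame:
    """Build a named study game, a random ordinal game, or the block game."""
    if name == "random_ordinal":
        if seed is None:
            raise ValueError("random_ordinal requires a seed")
        return random_ordinal_game(seed, **config)
    if name in _NAMED:
        return _NAMED[name](**config)
    raise KeyError(
        f"unknown fixture {name!r}; available: "
        f"{', '.join(sorted(_NAMED))}, random_ordinal")
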