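import numpy as np
import pytest

import coopgames as cg


@pytest.fixture
def pd():
    return cg.make_fixture("pd_0135")


@pytest.fixture
def chicken():
    return cg.make_fixture("chicken_0135")


@pytest.fixture
def alternator():
    return cg.make_fixture("alternator")


@pytest.fixture
def pennies():
    return cg.make_fixture("matching_pennies")


class FixedActionAgent(cg.Agent):
    """Plays a fixed own action in every stage (clamped to the action set)."""

    def __init__(self, action: int, name: str = "fixed"):
        self.action = action
        self.name = name

    def act(self, stage):
        return min(self.action, self.game.n_actions(stage, self.player) - 1)


class ScriptedAgent(cg.Agent):
    """Plays a scripted sequence of own actions (one per round, normal form)."""

    name = "scripted"

    def __init__(self, actions):
        self.actions = list(actions)

    def begin_match(self, game, player, rng):
        super().begin_match(game, player, rng)
        self.k = 0

    def act(self, stage):
        a = self.actions[min(self.k, len(self.actions) - 1)]
        return a

    def end_round(self, record):
        self.k += 1


@pytest.fixture
def always_cooperate():
    return FixedActionAgent(0, "allc")


@pytest.fixture
def always_defect():
    return FixedActionAgent(1, "alld")


@pytest.fixture
def scripted():
    return ScriptedAgent
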