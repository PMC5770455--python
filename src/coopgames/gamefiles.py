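"""Game file format: one YAML document per game, with a 2x2 shorthand.

Shorthand (normal-form games)::

    schema: 1
    name: pd_0135
    payoffs: [[[3, 3], [0, 5]], [[5, 0], [1, 1]]]

Full format::

    schema: 1
    name: handoff
    stages: [s0, s1, end]
    start_stage: s0
    goal_stages: [end]
    actions: {s0: [2, 2], s1: [1, 2]}
    rewards:
      - {stage: s0, action: [0, 0], reward: [1.0, 0.5]}
      ...
    transitions:
      - {stage: s0, action: [0, 0], next: {s1: 0.25, end: 0.75}}
      ...

Stage identifiers must be YAML scalars (strings or ints); games built
programmatically with richer stage objects are stringified on save, which
preserves structure up to stage renaming.
"""

from __future__ import annotations

import yaml

from .games import GameValidationError, RepeatedStochasticGame, normal_form

SCHEMA_VERSION = 1
_TOP_KEYS = {"schema", "name", "family", "payoffs", "stages", "start_stage",
             "goal_stages", "actions", "rewards", "transitions"}


class GameFileError(ValueError):
    """Raised on malformed game files, with the offending field named."""


def load_game(path) -> RepeatedStochasticGame:
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise GameFileError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise GameFileError(f"{path}: expected a mapping at top level")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise GameFileError(f"{path}: unknown keys {sorted(unknown)}")
    if doc.get("schema") != SCHEMA_VERSION:
        raise GameFileError(
            f"{path}: schema must be {SCHEMA_VERSION}, got {doc.get('schema')!r}")
    name = doc.get("name")
    if not name:
        raise GameFileError(f"{path}: missing 'name'")
    family = doc.get("family", "")
    if "payoffs" in doc:
        try:
            return normal_form(name, doc["payoffs"], family=family)
        except (GameValidationError, ValueError) as exc:
            raise GameFileError(f"{path}: bad payoffs shorthand: {exc}") from exc
    for key in ("stages", "start_stage", "goal_stages", "actions", "rewards",
                "transitions"):
        if key not in doc:
            raise GameFileError(f"{path}: missing '{key}'")
    actions = {s: tuple(v) for s, v in doc["actions"].items()}
    rewards = {}
    for row in doc["rewards"]:
        try:
            rewards[(row["stage"], tuple(row["action"]))] = tuple(
                float(v) for v in row["reward"])
        except (KeyError, TypeError) as exc:
            raise GameFileError(f"{path}: malformed reward row {row!r}") from exc
    transitions = {}
    for row in doc["transitions"]:
        try:
            dist = {s2: float(p) for s2, p in row["next"].items()}
        except (KeyError, AttributeError) as exc:
            raise GameFileError(f"{path}: malformed transition row {row!r}") from exc
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-9:
            raise GameFileError(
                f"{path}: transition row for stage {row['stage']!r}, action "
                f"{row['action']!r} sums to {total!r}, not 1")
        transitions[(row["stage"], tuple(row["action"]))] = dist
    try:
        return RepeatedStochasticGame(
            name=name, stages=tuple(doc["stages"]), actions=actions,
            rewards=rewards, transitions=transitions,
            start_stage=doc["start_stage"],
            goal_stages=frozenset(doc["goal_stages"]), family=family)
    except GameValidationError as exc:
        raise GameFileError(f"{path}: {exc}") from exc


def _stage_key(stage):
    return stage if isinstance(stage, (str, int)) else str(stage)


def save_game(game: RepeatedStochasticGame, path) -> None:
    if game.is_normal_form:
        s = game.start_stage
        n0, n1 = game.actions[s]
        payoffs = [[list(game.rewards[(s, (a0, a1))]) for a1 in range(n1)]
                   for a0 in range(n0)]
        doc = {"schema": SCHEMA_VERSION, "name": game.name,
               "family": game.family, "payoffs": payoffs}
    else:
        doc = {
            "schema": SCHEMA_VERSION,
            "name": game.name,
            "family": game.family,
            "stages": [_stage_key(s) for s in game.stages],
            "start_stage": _stage_key(game.start_stage),
            "goal_stages": sorted(_stage_key(s) for s in game.goal_stages),
            "actions": {_stage_key(s): list(v) for s, v in game.actions.items()},
            "rewards": [
                {"stage": _stage_key(s), "action": list(a), "reward": list(r)}
                for (s, a), r in game.rewards.items()],
            "transitions": [
                {"stage": _stage_key(s), "action": list(a),
                 "next": {_stage_key(s2): p for s2, p in dist.items()}}
                for (s, a), dist in game.transitions.items()],
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
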