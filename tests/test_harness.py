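"""Fixtures, game files, logs, reporting, and the command-line interface."""

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

import coopgames as cg
from coopgames.cli import main
from coopgames.gamefiles import GameFileError
from coopgames.report import save_match_log, summarize_logs, summarize_pairings


def test_named_fixtures(pd):
    s = pd.start_stage
    assert pd.rewards[(s, (0, 0))] == (3.0, 3.0)
    assert pd.rewards[(s, (1, 1))] == (1.0, 1.0)
    with pytest.raises(KeyError, match="unknown fixture"):
        cg.make_fixture("nope")


def test_random_ordinal_fixture_reproducible():
    g1 = cg.make_fixture("random_ordinal", seed=5)
    g2 = cg.make_fixture("random_ordinal", seed=5)
    assert g1.rewards == g2.rewards
    with pytest.raises(ValueError):
        cg.make_fixture("random_ordinal")


def test_block_game_default_shape():
    g = cg.make_fixture("block_game")
    # nine blocks, three picks per player, strictly alternating turns
    s = g.start_stage
    assert s == ((), ())
    assert g.actions[s] == (9, 1)  # player 0 moves first
    nxt = next(iter(g.transitions[(s, (0, 0))]))
    assert g.actions[nxt][0] == 1 and g.actions[nxt][1] == 8
    terminal_rewards = [r for (st, a), r in g.rewards.items() if r != (0.0, 0.0)]
    assert terminal_rewards  # scoring happens on the final pick
    assert not g.is_normal_form


def test_game_file_round_trip(tmp_path, pd):
    path = tmp_path / "pd.yaml"
    cg.save_game(pd, path)
    g = cg.load_game(path)
    assert g.name == pd.name
    assert g.rewards == pd.rewards
    assert g.transitions == pd.transitions


def test_game_file_round_trip_multistage(tmp_path):
    g = cg.RepeatedStochasticGame(
        name="two-step", stages=("s0", "s1", "end"),
        actions={"s0": (2, 1), "s1": (1, 2)},
        rewards={("s0", (0, 0)): (1.0, 0.0), ("s0", (1, 0)): (0.0, 1.0),
                 ("s1", (0, 0)): (2.0, 2.0), ("s1", (0, 1)): (0.0, 3.0)},
        transitions={("s0", (0, 0)): {"s1": 1.0}, ("s0", (1, 0)): {"end": 1.0},
                     ("s1", (0, 0)): {"end": 1.0}, ("s1", (0, 1)): {"end": 1.0}},
        start_stage="s0", goal_stages=frozenset({"end"}))
    path = tmp_path / "g.yaml"
    cg.save_game(g, path)
    g2 = cg.load_game(path)
    assert g2.rewards == g.rewards
    assert g2.transitions == g.transitions
    assert g2.start_stage == "s0"


def test_game_file_shorthand_expands_to_single_stage(tmp_path):
    path = tmp_path / "short.yaml"
    path.write_text("schema: 1\nname: mini\n"
                    "payoffs: [[[3,3],[0,5]],[[5,0],[1,1]]]\n")
    g = cg.load_game(path)
    assert g.is_normal_form
    assert g.rewards[(g.start_stage, (0, 1))] == (0.0, 5.0)


def test_game_file_errors_name_the_problem(tmp_path):
    bad = tmp_path / "bad.yaml"
    bad.write_text(yaml.safe_dump({
        "schema": 1, "name": "bad", "stages": ["s", "end"],
        "start_stage": "s", "goal_stages": ["end"], "actions": {"s": [1, 1]},
        "rewards": [{"stage": "s", "action": [0, 0], "reward": [0, 0]}],
        "transitions": [{"stage": "s", "action": [0, 0],
                         "next": {"end": 0.9}}],
    }))
    with pytest.raises(GameFileError, match=r"stage 's'.*sums to 0.9"):
        cg.load_game(bad)
    unk = tmp_path / "unk.yaml"
    unk.write_text("schema: 1\nname: x\nbogus_key: 1\n")
    with pytest.raises(GameFileError, match="unknown keys"):
        cg.load_game(unk)


def test_report_aggregation(tmp_path, pd):
    with pytest.raises(FileNotFoundError):
        summarize_logs(tmp_path)
    for seed in (0, 1):
        h = cg.run_match(cg.registry_lookup("wsls"), cg.registry_lookup("gtft"),
                         pd, 20, seed=seed)
        save_match_log(h, tmp_path / f"m{seed}.csv")
    summary = summarize_logs(tmp_path)
    assert len(summary) == 2
    pairs = summarize_pairings(summary)
    assert len(pairs) == 1
    assert pairs.loc[0, "n"] == 2
    assert {"payoff0_mean", "payoff0_sem"} <= set(pairs.columns)


def test_cli_simulate_deterministic_logs(tmp_path):
    runner = CliRunner()
    out1, out2 = tmp_path / "a.csv", tmp_path / "b.csv"
    for out in (out1, out2):
        res = runner.invoke(main, ["simulate", "--game", "pd_0135",
                                   "--agents", "s_sharp,s_sharp",
                                   "--rounds", "30", "--seed", "7",
                                   "--talk", "on", "--out", str(out)])
        assert res.exit_code == 0, res.output
    assert out1.read_bytes() == out2.read_bytes()
    assert "mean payoff" in res.output


def test_cli_plan_and_enumerate_and_agents():
    runner = CliRunner()
    res = runner.invoke(main, ["plan", "--game", "pd_0135", "--omega", "0.5"])
    assert res.exit_code == 0 and "(3.0000, 3.0000)" in res.output
    res = runner.invoke(main, ["plan", "--game", "pd_0135", "--all"])
    assert res.exit_code == 0 and "alternating" in res.output
    res = runner.invoke(main, ["enumerate-games", "--families"])
    assert res.exit_code == 0 and "144 canonical game structures" in res.output
    res = runner.invoke(main, ["agents", "list"])
    assert res.exit_code == 0 and "s_plus_plus" in res.output


def test_cli_tournament_and_report(tmp_path):
    cfg = tmp_path / "t.yaml"
    cfg.write_text(yaml.safe_dump({
        "algorithms": ["wsls", "gtft", "random"],
        "games": ["pd_0135"], "rounds": 10, "seeds": 2}))
    runner = CliRunner()
    out = tmp_path / "results"
    res = runner.invoke(main, ["tournament", "--config", str(cfg),
                               "--out", str(out), "--seed", "1"])
    assert res.exit_code == 0, res.output
    assert (out / "records.csv").exists()
    assert (out / "ranks.csv").exists()
    assert (out / "manifest.yaml").exists()
    manifest = yaml.safe_load((out / "manifest.yaml").read_text())
    assert manifest["seeds"] == [1, 2]
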