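"""Tournament metrics: round robin, rankings, replicator, elimination,
cooperation dynamics."""

import numpy as np
import pandas as pd
import pytest

import coopgames as cg
from coopgames.match import MatchHistory, RoundRecord
from coopgames.tournament import (MetricTable, elimination_tournament,
                                  empirical_cdf, replicator_dynamics)


def _toy_table(rows):
    records = pd.DataFrame(rows, columns=["alg", "partner", "game", "seed",
                                          "payoff"])
    algs = sorted(records["alg"].unique())
    return MetricTable(records=records, algorithms=algs,
                       games=sorted(records["game"].unique()))


def test_round_robin_bookkeeping(pd, alternator):
    table = cg.round_robin(["random", "wsls", "gtft"], [pd, alternator],
                           n_rounds=20, seeds=2)
    # 6 unordered pairings x 2 games x 2 seeds x 2 perspectives
    assert len(table.records) == 6 * 2 * 2 * 2
    assert set(table.records["alg"]) == {"random", "wsls", "gtft"}
    again = cg.round_robin(["random", "wsls", "gtft"], [pd, alternator],
                           n_rounds=20, seeds=2)
    pd_testing = table.records.sort_values(list(table.records.columns))
    pd_testing2 = again.records.sort_values(list(again.records.columns))
    assert pd_testing.reset_index(drop=True).equals(pd_testing2.reset_index(drop=True))


def test_round_robin_requires_two_algorithms(pd):
    with pytest.raises(ValueError):
        cg.round_robin(["wsls"], [pd], 10, 1)


def test_best_score_dominant_and_ties():
    rows = []
    # a dominates against every partner; b and c tie against partner a
    for partner, (pa, pb, pc) in {"a": (5, 3, 3), "b": (5, 2, 1),
                                  "c": (5, 1, 2)}.items():
        rows += [("a", partner, "g", 0, pa), ("b", partner, "g", 0, pb),
                 ("c", partner, "g", 0, pc)]
    t = _toy_table(rows)
    bs = t.best_score()
    assert bs["a"] == pytest.approx(100.0)
    assert bs["b"] == pytest.approx(0.0)
    rows2 = [("a", "a", "g", 0, 4), ("b", "a", "g", 0, 4),
             ("a", "b", "g", 0, 1), ("b", "b", "g", 0, 0)]
    bs2 = _toy_table(rows2).best_score()
    assert bs2["a"] == pytest.approx(75.0)  # ties vs a split 50/50
    assert bs2["b"] == pytest.approx(25.0)


def test_standardization_and_worst_case():
    rows = [("a", "a", "g1", 0, 4.0), ("a", "b", "g1", 0, 2.0),
            ("b", "a", "g1", 0, 0.0), ("b", "b", "g1", 0, 2.0),
            ("a", "a", "g2", 0, 1.0), ("a", "b", "g2", 0, 1.0),
            ("b", "a", "g2", 0, 1.0), ("b", "b", "g2", 0, 1.0)]
    t = _toy_table(rows)
    z = t.standardized()
    for game, grp in z.groupby("game"):
        assert grp["z"].mean() == pytest.approx(0.0, abs=1e-12)
        sd = grp["z"].std(ddof=0)
        assert sd == pytest.approx(1.0) or sd == pytest.approx(0.0)  # constant game
    wc = t.worst_case_score()
    assert wc["b"] < wc["a"]
    assert wc["b"] == pytest.approx((0.0 - 2.0) / np.std([4, 2, 0, 2]))


def test_replicator_uniform_and_dominance():
    traj, final = replicator_dynamics(np.ones((3, 3)), generations=200)
    np.testing.assert_allclose(final, [1 / 3] * 3, atol=1e-12)
    np.testing.assert_allclose(traj.sum(axis=1), 1.0, atol=1e-12)
    A = np.array([[3.0, 3.0], [1.0, 1.0]])  # row 0 strictly dominant
    traj, final = replicator_dynamics(A, generations=2000)
    assert final[0] > 0.999
    # the dominated strategy's frequency never increases
    assert np.all(np.diff(traj[:, 1]) <= 1e-12)


def test_replicator_one_shot_pd_defection_fixates():
    # expected payoffs of AllC/AllD in the one-shot 0-1-3-5 PD
    A = np.array([[3.0, 0.0], [5.0, 1.0]])
    _, final = replicator_dynamics(A, generations=10_000)
    assert final[1] > 0.999


def test_replicator_rejects_bad_matrix():
    with pytest.raises(ValueError):
        replicator_dynamics(np.ones((2, 3)))


def test_elimination_orders_hand_checked():
    rows = []
    means = {("a", "a"): 3, ("a", "b"): 4, ("a", "c"): 5,
             ("b", "a"): 2, ("b", "b"): 3, ("b", "c"): 4,
             ("c", "a"): 1, ("c", "b"): 2, ("c", "c"): 3}
    for (alg, partner), v in means.items():
        rows.append((alg, partner, "g", 0, float(v)))
    t = _toy_table(rows)
    # c is weakest overall, then b; the dominant a survives both variants
    assert elimination_tournament(t, "group1") == ["c", "b", "a"]
    assert elimination_tournament(t, "group2")[-1] == "a"
    with pytest.raises(ValueError):
        elimination_tournament(t, "group3")


def test_elimination_ties_break_lexicographically():
    rows = [(a, p, "g", 0, 1.0) for a in "abc" for p in "abc"]
    t = _toy_table(rows)
    assert elimination_tournament(t, "group1") == ["a", "b", "c"]


def _history(game, joints):
    h = MatchHistory(game.name, ("x", "y"), 0, False)
    s = game.start_stage
    for t, j in enumerate(joints, start=1):
        r = game.rewards[(s, j)]
        h.append(RoundRecord(t=t, stages=(s,), joint_actions=(j,),
                             step_rewards=(r,), payoffs=r, messages=((), ()),
                             notes=({}, {})))
    return h


def test_time_to_cooperation_and_loyalty(pd):
    C, D = (0, 0), (1, 1)
    cooperative = _history(pd, [C] * 10)
    never = _history(pd, [D] * 10)
    lapsed = _history(pd, [D] * 4 + [C, C] + [D, D] + [C, C])
    times = cg.time_to_mutual_cooperation([cooperative, never, lapsed], pd)
    assert times[0] == 1
    assert np.isinf(times[1])
    assert times[2] == 5
    # of the two pairings that cooperated, only the first stayed loyal
    assert cg.loyalty([cooperative, never, lapsed], pd) == pytest.approx(50.0)
    xs, ps = empirical_cdf(times, 10)
    assert ps[0] == pytest.approx(1 / 3)
    assert ps[-1] == pytest.approx(2 / 3)


def test_ranks_table_structure(pd, alternator):
    table = cg.round_robin(["wsls", "gtft", "random"], [pd, alternator],
                           n_rounds=15, seeds=2)
    ranks = table.ranks(generations=500)
    assert set(ranks.columns) == {"round_robin", "best_score", "worst_case",
                                  "replicator", "elim_group1", "elim_group2"}
    assert ranks.shape == (3, 6)
    assert ranks.min().min() >= 1
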