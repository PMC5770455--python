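"""The expert set: followers, triggers, punishment accounting, MBRL,
and expert potentials."""

import numpy as np
import pytest

import coopgames as cg
from coopgames.experts import (FollowerExpert, MBRLExpert, MaximinExpert,
                               TriggerExpert, build_expert_set)
from coopgames.fixtures import random_ordinal_game
from coopgames.match import RoundRecord


def _record(game, t, joint):
    r = game.rewards[(game.start_stage, joint)]
    return RoundRecord(t=t, stages=(game.start_stage,), joint_actions=(joint,),
                       step_rewards=(r,), payoffs=r, messages=((), ()),
                       notes=({}, {}))


def _solution(game, payoffs):
    return next(s for s in cg.enumerate_target_solutions(game)
                if s.payoffs == payoffs)


def test_expert_census_thirteen(pd):
    experts = build_expert_set(pd, 0)
    assert len(experts) == 13
    kinds = [e.kind for e in experts]
    assert kinds.count("follower") == 5
    assert kinds.count("trigger") == 5
    assert {"preventative", "maximin", "mbrl"} <= set(kinds)
    assert [e.id for e in experts[:5]] == [f"follower-{k}" for k in range(5)]


def test_degenerate_game_collapses_expert_set():
    g = cg.normal_form("flat", [[(2, 2), (2, 2)], [(2, 2), (2, 2)]])
    experts = build_expert_set(g, 0)
    assert len(experts) < 13


def test_fair_follower_is_always_cooperate(pd):
    f = FollowerExpert("f", _solution(pd, (3.0, 3.0)))
    f.reset(pd, 0, np.random.default_rng(0))
    s = pd.start_stage
    for t, joint in enumerate([(0, 0), (0, 1), (1, 1), (0, 0)], start=1):
        assert f.act(s, t) == 0  # cooperates no matter the history
        f.end_round(_record(pd, t, joint), selected=True)


def test_trigger_punishment_ledger_worked_example(pd):
    """Partner gains 2 by deviating (5 vs 3); minimax holds it to 1 against a
    counterfactual of 3, so punishment lasts exactly 2 further rounds."""
    trig = TriggerExpert("t", _solution(pd, (3.0, 3.0)))
    trig.reset(pd, 0, np.random.default_rng(0))
    s = pd.start_stage
    trig.end_round(_record(pd, 1, (0, 0)), selected=True)
    assert not trig.punishing and trig.last_event == "s"
    trig.end_round(_record(pd, 2, (0, 1)), selected=True)  # beneficial deviation
    assert trig.punishing and trig.last_event == "g"
    assert trig.act(s, 3) == 1  # minimax: defect
    trig.end_round(_record(pd, 3, (1, 1)), selected=True)
    assert trig.punishing and trig.last_event == "p"  # 6 >= 6: still ahead
    trig.end_round(_record(pd, 4, (1, 1)), selected=True)
    assert not trig.punishing and trig.last_event == "f"  # 7 < 9: forgiven
    assert trig.act(s, 5) == 0  # back to the offer


def test_trigger_never_punishes_compliant_partner(pd):
    trig = TriggerExpert("t", _solution(pd, (3.0, 3.0)))
    trig.reset(pd, 0, np.random.default_rng(0))
    for t in range(1, 30):
        trig.end_round(_record(pd, t, (0, 0)), selected=True)
        assert not trig.punishing


def test_unprofitable_deviation_not_punished(pd):
    # offer (0, 5): partner expected to defect; cooperating pays it 3 <= 5
    trig = TriggerExpert("t", _solution(pd, (0.0, 5.0)))
    trig.reset(pd, 0, np.random.default_rng(0))
    trig.end_round(_record(pd, 1, (0, 0)), selected=True)
    assert not trig.punishing and trig.last_event == "d"


def test_follower_equals_trigger_twin_without_deviations(pd):
    sol = _solution(pd, (3.0, 3.0))
    f, t = FollowerExpert("f", sol), TriggerExpert("t", sol)
    rng = np.random.default_rng(0)
    f.reset(pd, 0, rng)
    t.reset(pd, 0, rng)
    s = pd.start_stage
    for k in range(1, 20):
        assert f.act(s, k) == t.act(s, k)
        f.end_round(_record(pd, k, (0, 0)), selected=True)
        t.end_round(_record(pd, k, (0, 0)), selected=True)


def test_mbrl_learns_always_defect_against_always_cooperate(pd, always_cooperate):
    h = cg.run_match(cg.registry_lookup("mbrl1"), always_cooperate, pd, 60, seed=0)
    assert all(r.joint_actions[0] == (1, 0) for r in h.rounds[-20:])


def test_mbrl_initial_action_is_uniform_model_best_response(pd):
    # best response to a uniform partner in the PD is defection
    e = MBRLExpert("m")
    e.reset(pd, 0, np.random.default_rng(0))
    assert e.act(pd.start_stage, 1) == 1


def test_potentials(pd):
    experts = {e.id: e for e in build_expert_set(pd, 0)}
    rng = np.random.default_rng(0)
    for e in experts.values():
        e.reset(pd, 0, rng)
    assert experts["trigger-0"].potential() == pytest.approx(3.0)  # fresh, fair
    assert experts["maximin"].potential() == pytest.approx(1.0)
    assert experts["preventative"].potential() == pytest.approx(1.0)
    lo, hi = pd.payoff_bounds()
    for e in experts.values():
        assert lo - 1e-9 <= e.potential() <= hi + 1e-9


def test_bully_follower_potential_decays_to_zero(pd):
    # the (5, 0) offer is never followed: its advertised value fades out
    f = FollowerExpert("f", _solution(pd, (5.0, 0.0)))
    f.reset(pd, 0, np.random.default_rng(0))
    for t in range(1, 40):
        f.end_round(_record(pd, t, (1, 1)), selected=True)
    assert f.potential() < 0.01


def test_potentials_bounded_after_live_play(pd):
    agent = cg.SPlusPlus()
    cg.run_match(agent, cg.registry_lookup("random"), pd, 120, seed=5)
    lo, hi = pd.payoff_bounds()
    for e in agent.experts:
        assert lo - 1e-9 <= e.potential() <= hi + 1e-9


# ---------------------------------------------------------------------------
# compliance optimality: following an enforceable offer is a best response
# ---------------------------------------------------------------------------

def _stationary_best_response_value(game, trig, gamma=0.99):
    """Exact best-response value against the trigger automaton.

    Value iteration over the partner's decision problem with states
    (offer phase) and (punishment with ledger surplus d).  Requires a pure
    offer and a pure minimax attack so the ledger evolves deterministically.
    """
    s = game.start_stage
    partner = 1 - trig.player
    offer_joint = trig.offer.policies[0][s]
    cf = game.rewards[(s, offer_joint)][partner]
    attack = trig.attack[s]
    assert attack.max() > 1 - 1e-9, "oracle needs a pure attack"
    a_att = int(np.argmax(attack))
    our_offer_action = offer_joint[trig.player]
    nb = game.n_actions(s, partner)

    def joint(ours, theirs):
        return (ours, theirs) if trig.player == 0 else (theirs, ours)

    r_off = [game.rewards[(s, joint(our_offer_action, b))][partner] for b in range(nb)]
    r_pun = [game.rewards[(s, joint(a_att, b))][partner] for b in range(nb)]

    # reachable ledger surpluses (strictly decreasing during punishment)
    states = {"offer"}
    frontier = ["offer"]
    while frontier:
        st = frontier.pop()
        if st == "offer":
            for b in range(nb):
                if b != offer_joint[partner] and r_off[b] > cf + 1e-9:
                    d = round(r_off[b] - cf, 9)
                    if d not in states:
                        states.add(d)
                        frontier.append(d)
        else:
            for b in range(nb):
                d2 = round(st + r_pun[b] - cf, 9)
                if d2 >= -1e-9 and d2 not in states:
                    states.add(d2)
                    frontier.append(d2)
    V = {st: 0.0 for st in states}
    for _ in range(6000):
        delta = 0.0
        for st in states:
            if st == "offer":
                best = -np.inf
                for b in range(nb):
                    if b != offer_joint[partner] and r_off[b] > cf + 1e-9:
                        nxt = round(r_off[b] - cf, 9)
                    else:
                        nxt = "offer"
                    best = max(best, r_off[b] + gamma * V[nxt])
            else:
                best = -np.inf
                for b in range(nb):
                    d2 = round(st + r_pun[b] - cf, 9)
                    nxt = "offer" if d2 < -1e-9 else d2
                    best = max(best, r_pun[b] + gamma * V[nxt])
            delta = max(delta, abs(best - V[st]))
            V[st] = best
        if delta < 1e-12:
            break
    return V["offer"], cf / (1 - gamma)


@pytest.mark.parametrize("seed", [None] + list(range(8)))
def test_compliance_is_best_response_to_enforceable_triggers(seed):
    game = cg.make_fixture("pd_0135") if seed is None \
        else random_ordinal_game(500 + seed)
    rng = np.random.default_rng(0)
    for e in build_expert_set(game, 0):
        if e.kind != "trigger":
            continue
        e.reset(game, 0, rng)
        if not e.enforceable or len(e.offer.policies) != 1:
            continue
        if e.attack[game.start_stage].max() <= 1 - 1e-9:
            continue
        br, comply = _stationary_best_response_value(game, e)
        assert br <= comply + 1e-6, (game.name, e.id)
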