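"""Cheap talk: speech catalog, Mealy machines, congruence, trust gating."""

import numpy as np
import pytest

import coopgames as cg
from coopgames.experts import build_expert_set
from coopgames.match import Message
from coopgames.signaling import (DEFAULT_CATALOG, EVENTS, FAIR, I_HIGHER,
                                 PROPOSE_ACT, YOU_HIGHER, payload_matches,
                                 plan_payload, solution_descriptor)


def _experts(game, player=0):
    experts = build_expert_set(game, player)
    rng = np.random.default_rng(0)
    for e in experts:
        e.reset(game, player, rng)
    return experts


def test_catalog_has_required_acts():
    expected = {0: "threat", 5: "praise", 6: "praise", 11: "displeasure",
                12: "displeasure", 13: "punishment-notice", 14: "gloat",
                15: "expectation"}
    for act_id, category in expected.items():
        assert DEFAULT_CATALOG[act_id].category == category


def test_trigger_fsm_transitions(pd):
    trig = next(e for e in _experts(pd) if e.kind == "trigger")
    fsm = cg.build_fsm(trig)
    # voicing expectations plus a threat up front (s0 -> s1)
    assert fsm.initial() == {15, 0}
    assert fsm.state == "s1"
    # conformity earns praise
    assert fsm.step("s") <= {5, 6}
    # a beneficial deviation announces punishment and enters s7
    out = fsm.step("g")
    assert out == {13} and fsm.state == "s7"
    # during punishment the machine gloats
    assert fsm.step("p") == {14} and fsm.state == "s7"
    # punishment completion forgives, then expectations are renewed
    assert fsm.step("f") == {4} and fsm.state == "s8"
    assert fsm.step("s") == {15, 0} and fsm.state == "s1"


def test_follower_fsm_has_no_punishment_states(pd):
    fol = next(e for e in _experts(pd) if e.kind == "follower")
    fsm = cg.build_fsm(fol)
    assert not any(s in fsm.states for s in ("s7", "s8"))
    fsm.initial()
    fsm.step("g")  # treated as plain deviation
    assert fsm.state == "s1"


@pytest.mark.parametrize("kind", ["trigger", "follower", "maximin", "mbrl",
                                  "preventative"])
def test_fsm_deterministic_and_total(pd, kind):
    expert = next(e for e in _experts(pd) if e.kind == kind)
    fsm = cg.build_fsm(expert)
    for state in fsm.states:
        for ev in EVENTS:
            assert (state, ev) in fsm.transitions
            nxt, out = fsm.transitions[(state, ev)]
            assert nxt in fsm.states
            assert all(a in DEFAULT_CATALOG for a in out)


def test_proposal_round_trip_normal_form(pd):
    solutions = cg.enumerate_target_solutions(pd)
    for sol in cg.select_five_solutions(solutions, pd):
        payload = plan_payload(pd, sol, speaker=0)
        msg = (Message(PROPOSE_ACT, payload),)
        parsed = cg.parse_proposal(msg, pd, solutions, speaker=0)
        assert parsed is not None and parsed.key() == sol.key()


def test_malformed_or_absent_proposal_is_none(pd):
    solutions = cg.enumerate_target_solutions(pd)
    assert cg.parse_proposal((), pd, solutions, speaker=0) is None
    assert cg.parse_proposal((Message(5),), pd, solutions, speaker=0) is None
    bad = (Message(PROPOSE_ACT, "gibberish"),)
    assert cg.parse_proposal(bad, pd, solutions, speaker=0) is None


def test_rsg_descriptors_and_congruence_flip():
    g = cg.make_fixture("block_game", picks_per_player=1,
                        blocks=((3, "a"), (2, "a"), (1, "b")))
    solutions = cg.enumerate_target_solutions(g)
    nbs = cg.nash_bargaining_solution(g)
    assert solution_descriptor(g, nbs, speaker=0) == FAIR
    best0 = max(solutions, key=lambda s: s.payoffs[0])
    if best0.payoffs[0] > best0.payoffs[1]:
        assert solution_descriptor(g, best0, speaker=0) in (I_HIGHER, FAIR)
        assert solution_descriptor(g, best0, speaker=1) in (YOU_HIGHER, FAIR)
    # a "fair" proposal parses to the candidate nearest the bargaining profile
    parsed = cg.parse_proposal((Message(PROPOSE_ACT, FAIR),), g, solutions,
                               speaker=1)
    d_parsed = max(abs(parsed.payoffs[0] - nbs.payoffs[0]),
                   abs(parsed.payoffs[1] - nbs.payoffs[1]))
    assert all(
        d_parsed <= max(abs(s.payoffs[0] - nbs.payoffs[0]),
                        abs(s.payoffs[1] - nbs.payoffs[1])) + 1e-9
        for s in solutions)


def test_congruence_filter(pd):
    experts = _experts(pd)
    fair = next(e for e in experts if e.kind == "trigger"
                and e.offer.payoffs == (3.0, 3.0))
    payload = plan_payload(pd, fair.offer, speaker=1)
    pots = {e.id: e.potential() for e in experts}
    # all fair experts clear a modest aspiration: only they survive
    kept = cg.congruent_experts(experts, payload, pots, 2.0, pd, listener=0)
    assert set(kept) <= {"follower-0", "trigger-0"}
    assert fair.id in kept
    # congruent experts all below aspiration: plain pruning takes over
    kept = cg.congruent_experts(experts, payload, pots, 4.5, pd, listener=0)
    assert kept == cg.prune_experts(pots, 4.5)


def test_trust_updates_and_silent_treatment():
    t = cg.TrustState()
    for _ in range(30):
        t = cg.update_trust(t, partner_kept_proposal=True)
    assert t.listen_prob > 0.99
    for k in range(30):
        t = cg.update_trust(t, partner_kept_proposal=False,
                            own_proposal_followed=False)
    assert t.listen_prob < 0.01
    assert not t.speak  # silent treatment after repeated ignoring
    t2 = cg.update_trust(t, own_proposal_followed=True)
    assert t2.speak
    assert cg.update_trust(t) == t  # no proposals: state unchanged


def test_speak_gate_suppresses_messages(pd):
    agent = cg.SSharp()
    cg.run_match(agent, cg.SSharp(), pd, 6, seed=0, talk=True)
    agent.trust = cg.TrustState(follow_rate=0.0, consec_ignored=3, speak=False)
    agent._need_initial = True
    assert agent.speak(7) == ()


def test_signal_fidelity_on_logged_epochs(pd):
    """Every emitted plan equals the proposing expert's actual offer."""
    a0, a1 = cg.SSharp(), cg.SSharp()
    cg.run_match(a0, a1, pd, 150, seed=3, talk=True)
    for agent in (a0, a1):
        assert agent.sent_proposals
        for t, expert_id, payload in agent.sent_proposals:
            offer = agent.by_id[expert_id].offer
            assert plan_payload(pd, offer, agent.player) == payload
            assert payload_matches(pd, offer, payload, listener=1 - agent.player)


def test_talk_off_s_sharp_identical_to_s_plus_plus(pd, chicken):
    for game in (pd, chicken):
        for seed in (0, 1, 2):
            h1 = cg.run_match(cg.SSharp(), cg.SSharp(), game, 80, seed=seed)
            h2 = cg.run_match(cg.SPlusPlus(), cg.SPlusPlus(), game, 80, seed=seed)
            assert [r.joint_actions for r in h1.rounds] == \
                   [r.joint_actions for r in h2.rounds]
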