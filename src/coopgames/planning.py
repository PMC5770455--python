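"""Joint planning: compromise (target) solutions of an RSG.

Candidate compromises are computed by planning in the joint-action MDP whose
reward blends the two players' payoffs,

    y_w(s, a) = w * r0(s, a) + (1 - w) * r1(s, a),       w in [0, 1],

and whose value function satisfies

    Q_w(s, a) = y_w(s, a) + sum_{s'} P(s, a, s') V_w(s'),
    V_w(s)    = max_a Q_w(s, a),

with goal stages worth 0 (the round ends there).  Sweeping w across a grid
yields a family of Pareto-optimal "pure solutions"; alternating between two
distinct pure solutions on even/odd rounds yields additional "alternating
solutions" whose payoff pair is the average of the two phases.  Cycles are
restricted to length two: longer cycles are hard for a partner to model.

Five compromises are then selected to span the bargaining frontier: the most
egalitarian one, the two that maximize each player's payoff subject to the
partner clearing its security level, and two more chosen greedily to spread
the selected payoff profiles apart.  The Nash bargaining solution — the
candidate maximizing the product of payoff gains over the maximin values —
serves as the operational definition of mutual cooperation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .games import RepeatedStochasticGame
from .solve import ConvergenceError, maximin_value

DEFAULT_OMEGA_GRID = tuple(np.round(np.linspace(0.0, 1.0, 11), 10))


@dataclass(frozen=True)
class JointPlanningProblem:
    """A solved joint-action MDP for one blend weight."""

    omega: float
    V: dict  # stage -> blended value
    Q: dict  # (stage, joint) -> blended action value
    policy: dict  # stage -> joint action (lowest-index argmax)


@dataclass(frozen=True)
class TargetSolution:
    """A pure or length-2 alternating joint strategy with its payoff pair.

    ``policies`` holds one joint policy per cycle phase (stage -> joint
    action); round ``t`` (1-indexed) uses phase ``(t - 1) % len(policies)``.
    """

    kind: str  # "pure" | "alternating"
    policies: tuple
    payoffs: tuple  # per-round expected payoff pair (v0, v1)
    omegas: tuple

    def phase(self, t: int) -> dict:
        return self.policies[(t - 1) % len(self.policies)]

    def cycle(self, start_stage) -> tuple:
        """Joint actions at the start stage, one per phase (normal form)."""
        return tuple(pol[start_stage] for pol in self.policies)

    def key(self) -> tuple:
        return tuple(round(v, 9) for v in self.payoffs)


def _phase_payoffs(game: RepeatedStochasticGame, policy: dict) -> tuple:
    """Each player's expected per-round payoff when both follow ``policy``.

    Solves the linear system V_i(s) = r_i(s, pi(s)) + sum P V_i(s') over the
    decision stages (the round terminates almost surely, so I - P is
    invertible).
    """
    stages = game.decision_stages
    idx = {s: k for k, s in enumerate(stages)}
    n = len(stages)
    P = np.zeros((n, n))
    R = np.zeros((n, 2))
    for s in stages:
        a = policy[s]
        R[idx[s]] = game.rewards[(s, a)]
        for s2, p in game.transitions[(s, a)].items():
            if s2 not in game.goal_stages:
                P[idx[s], idx[s2]] += p
    V = np.linalg.solve(np.eye(n) - P, R)
    v0, v1 = V[idx[game.start_stage]]
    return (float(v0), float(v1))


def solve_joint_mdp(game: RepeatedStochasticGame, omega: float,
                    tol: float = 1e-10, max_sweeps: int = 10_000,
                    ) -> tuple[JointPlanningProblem, TargetSolution]:
    """Solve the joint-action MDP for blend weight ``omega``.

    Returns the solved MDP and the pure target solution it induces, whose
    payoff pair is each player's *own* expected per-round payoff under the
    optimal joint policy (not the blended value).
    """
    if not 0.0 <= omega <= 1.0:
        raise ValueError(f"omega must be in [0, 1], got {omega}")
    key = ("joint_mdp", round(float(omega), 12), tol)
    if key in game.cache:
        return game.cache[key]
    stages = game.decision_stages
    y = {
        (s, a): omega * game.rewards[(s, a)][0] + (1 - omega) * game.rewards[(s, a)][1]
        for s in stages for a in game.joint_actions(s)
    }
    V = {s: 0.0 for s in stages}
    for _sweep in range(max_sweeps):
        delta = 0.0
        for s in stages:
            best = -np.inf
            for a in game.joint_actions(s):
                q = y[(s, a)]
                for s2, p in game.transitions[(s, a)].items():
                    if s2 not in game.goal_stages:
                        q += p * V[s2]
                if q > best:
                    best = q
            delta = max(delta, abs(best - V[s]))
            V[s] = best
        if delta <= tol:
            break
    else:
        raise ConvergenceError(
            f"joint MDP({omega}) on {game.name} did not converge "
            f"(residual {delta:.3e} after {max_sweeps} sweeps)")
    Q = {}
    policy = {}
    for s in stages:
        best_a, best_q = None, -np.inf
        for a in game.joint_actions(s):  # enumeration order is the tie-break
            q = y[(s, a)]
            for s2, p in game.transitions[(s, a)].items():
                if s2 not in game.goal_stages:
                    q += p * V[s2]
            Q[(s, a)] = q
            if q > best_q + tol:
                best_a, best_q = a, q
        policy[s] = best_a
    problem = JointPlanningProblem(omega=float(omega), V=dict(V), Q=Q, policy=policy)
    solution = TargetSolution(
        kind="pure", policies=(policy,),
        payoffs=_phase_payoffs(game, policy), omegas=(float(omega),))
    game.cache[key] = (problem, solution)
    return problem, solution


def enumerate_target_solutions(game: RepeatedStochasticGame,
                               omega_grid=None) -> list[TargetSolution]:
    """Pure solutions over the omega grid plus all length-2 alternations.

    Pure solutions with identical payoff pairs are deduplicated; every
    unordered pair of distinct pure solutions contributes one alternating
    solution whose payoff pair is the mean of the two phases.
    """
    if omega_grid is None:
        omega_grid = DEFAULT_OMEGA_GRID
    omega_grid = tuple(omega_grid)
    key = ("targets", omega_grid)
    if key in game.cache:
        return game.cache[key]
    pures: list[TargetSolution] = []
    seen = {}
    for w in omega_grid:
        _, sol = solve_joint_mdp(game, w)
        k = sol.key()
        if k not in seen:
            seen[k] = sol
            pures.append(sol)
    out = list(pures)
    for s1, s2 in itertools.combinations(pures, 2):
        out.append(TargetSolution(
            kind="alternating",
            policies=(s1.policies[0], s2.policies[0]),
            payoffs=((s1.payoffs[0] + s2.payoffs[0]) / 2,
                     (s1.payoffs[1] + s2.payoffs[1]) / 2),
            omegas=s1.omegas + s2.omegas,
        ))
    game.cache[key] = out
    return out


def select_five_solutions(solutions: list[TargetSolution],
                          game: RepeatedStochasticGame) -> list[TargetSolution]:
    """Pick (up to) five compromises spanning the candidate payoff profiles.

    1. the most egalitarian candidate (maximal min payoff gain over the
       players' maximin values);
    2./3. the candidate maximizing each player's payoff subject to the
       partner receiving at least its maximin value, when such exist;
    4./5. candidates greedily maximizing the minimum Euclidean distance to
       the already-selected payoff profiles.

    Fewer than five distinct candidates are all returned.
    """
    if not solutions:
        raise ValueError("no candidate solutions to select from")
    mm = (maximin_value(game, 0), maximin_value(game, 1))
    # dedupe by payoff pair, preserving candidate order
    cands: list[TargetSolution] = []
    seen = set()
    for sol in solutions:
        if sol.key() not in seen:
            seen.add(sol.key())
            cands.append(sol)

    selected: list[TargetSolution] = []

    def pick(best_key):
        best = max((s for s in cands if s not in selected), key=best_key, default=None)
        if best is not None and best not in selected:
            selected.append(best)

    # 1. egalitarian stand-in: maximize the smaller maximin gain
    pick(lambda s: (min(s.payoffs[0] - mm[0], s.payoffs[1] - mm[1]),
                    -cands.index(s)))
    # 2./3. each player's best subject to partner security
    for player in (0, 1):
        partner = 1 - player
        ok = [s for s in cands if s not in selected
              and s.payoffs[partner] >= mm[partner] - 1e-9]
        if ok:
            selected.append(max(ok, key=lambda s: (s.payoffs[player], -cands.index(s))))
    # 4./5. spread: maximize min distance to selected profiles
    while len(selected) < 5:
        rest = [s for s in cands if s not in selected]
        if not rest:
            break
        pts = np.array([s.payoffs for s in selected]) if selected else np.zeros((0, 2))

        def spread(s):
            if not len(pts):
                return (np.inf, -cands.index(s))
            d = np.sqrt(((pts - np.array(s.payoffs)) ** 2).sum(axis=1)).min()
            return (d, -cands.index(s))

        selected.append(max(rest, key=spread))
    return selected


def nash_bargaining_solution(game: RepeatedStochasticGame,
                             omega_grid=None) -> TargetSolution:
    """The candidate maximizing the product of payoff gains over maximin.

    Candidates are the pure and alternating target solutions; for
    normal-form games every pure joint action is additionally a candidate.
    Ties break by larger payoff sum, then candidate order.  Candidates in
    which both players clear their security level are preferred whenever any
    exists (a product of two shortfalls is not a bargaining gain).
    """
    key = ("nbs", tuple(omega_grid) if omega_grid is not None else None)
    if key in game.cache:
        return game.cache[key]
    cands = list(enumerate_target_solutions(game, omega_grid))
    if game.is_normal_form:
        s = game.start_stage
        seen = {c.key() for c in cands}
        for a in game.joint_actions(s):
            pol = {s: a}
            sol = TargetSolution(kind="pure", policies=(pol,),
                                 payoffs=game.rewards[(s, a)], omegas=())
            if sol.key() not in seen:
                seen.add(sol.key())
                cands.append(sol)
    if not cands:
        raise ValueError(f"no candidate solutions for {game.name}")
    mm = (maximin_value(game, 0), maximin_value(game, 1))
    gains = [(s.payoffs[0] - mm[0], s.payoffs[1] - mm[1]) for s in cands]
    viable = [k for k, g in enumerate(gains) if g[0] >= -1e-9 and g[1] >= -1e-9]
    pool = viable if viable else range(len(cands))
    best = max(pool, key=lambda k: (gains[k][0] * gains[k][1],
                                    sum(cands[k].payoffs), -k))
    game.cache[key] = cands[best]
    return cands[best]


def _round_matches(round_pairs, policy: dict) -> bool:
    """Does a round's (stage, joint) trajectory follow ``policy`` throughout?"""
    return all(policy.get(stage) == joint for stage, joint in round_pairs)


def round_match_flags(history, game: RepeatedStochasticGame,
                      solution: TargetSolution | None = None) -> np.ndarray:
    """Per-round, per-phase-offset match indicators against a solution.

    Returns a boolean array of shape (n_offsets, n_rounds): entry (o, t)
    says whether round t+1 follows the solution's phase ``(t + o) % L``.
    """
    if solution is None:
        solution = nash_bargaining_solution(game)
    L = len(solution.policies)
    rounds = history.joint_action_rounds()
    flags = np.zeros((L, len(rounds)), dtype=bool)
    for o in range(L):
        for t, pairs in enumerate(rounds):
            flags[o, t] = _round_matches(pairs, solution.policies[(t + o) % L])
    return flags


def mutual_cooperation_proportion(history, game: RepeatedStochasticGame) -> float:
    """Fraction of rounds matching the Nash bargaining pattern.

    For an alternating pattern the phase offset is chosen (out of the two)
    to maximize the match count.
    """
    if not len(history):
        return 0.0
    flags = round_match_flags(history, game)
    return float(flags.sum(axis=1).max() / flags.shape[1])


class SolutionPlayer:
    """Plays one side of a target solution (used for simulation checks)."""

    def __init__(self, solution: TargetSolution, player: int):
        self.solution = solution
        self.name = f"solution-player-{player}"

    def begin_match(self, game, player, rng):
        self.game, self.player, self.rng = game, player, rng
        self.t = 1

    def speak(self, t):
        return ()

    def hear(self, t, messages):
        pass

    def act(self, stage):
        return self.solution.phase(self.t)[stage][self.player]

    def observe_step(self, stage, joint, rewards, next_stage):
        pass

    def end_round(self, record):
        self.t = record.t + 1

    def round_notes(self):
        return {}
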