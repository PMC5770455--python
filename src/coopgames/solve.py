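"""Security levels: matrix-game values, maximin, and minimax punishment.

A player's maximin (security) value is the payoff it can guarantee with a
mixed strategy regardless of the partner.  For a single-stage game this is
the value of the zero-sum matrix game on the player's own payoffs, solved as
a linear program.  For multi-stage games it is the value of the zero-sum
stochastic game obtained by letting the attacker minimize the victim's
payoff, solved by value iteration with a matrix-game solve per stage
(rounds terminate almost surely, so the undiscounted values are finite).

By LP duality the attacker's optimal strategy in that zero-sum game holds
the victim to exactly its maximin value; that strategy is the punishment
phase of trigger strategies.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

from .games import RepeatedStochasticGame


class ConvergenceError(RuntimeError):
    """Value iteration failed to reach tolerance within the sweep budget."""


def solve_matrix_game(A: np.ndarray) -> tuple[float, np.ndarray]:
    """Value and optimal row strategy of the zero-sum game ``A``.

    The row player maximizes ``min_j x @ A[:, j]`` over mixed strategies x.
    """
    A = np.asarray(A, dtype=float)
    n, m = A.shape
    if n == 1:
        return float(A.min()), np.ones(1)
    if m == 1:
        k = int(np.argmax(A[:, 0]))
        x = np.zeros(n)
        x[k] = 1.0
        return float(A[k, 0]), x
    # variables: x_1..x_n, v ; maximize v
    c = np.zeros(n + 1)
    c[-1] = -1.0
    A_ub = np.hstack([-A.T, np.ones((m, 1))])  # v - x@A[:,j] <= 0
    b_ub = np.zeros(m)
    A_eq = np.ones((1, n + 1))
    A_eq[0, -1] = 0.0
    b_eq = np.array([1.0])
    bounds = [(0, None)] * n + [(None, None)]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - highs is robust on these LPs
        raise RuntimeError(f"matrix-game LP failed: {res.message}")
    x = np.clip(res.x[:n], 0.0, None)
    return float(res.x[-1]), x / x.sum()


def minimizing_strategy(A: np.ndarray) -> np.ndarray:
    """The column player's optimal (minimizing) mixed strategy for ``A``."""
    _, y = solve_matrix_game(-np.asarray(A, dtype=float).T)
    return y


def _victim_matrix(game: RepeatedStochasticGame, stage, victim: int,
                   cont: dict) -> np.ndarray:
    """Victim-rows matrix of victim payoff-to-go at ``stage``."""
    n_v = game.n_actions(stage, victim)
    n_a = game.n_actions(stage, 1 - victim)
    M = np.empty((n_v, n_a))
    for av in range(n_v):
        for aa in range(n_a):
            joint = (av, aa) if victim == 0 else (aa, av)
            val = game.rewards[(stage, joint)][victim]
            for s2, p in game.transitions[(stage, joint)].items():
                if p > 0 and s2 not in game.goal_stages:
                    val += p * cont[s2]
            M[av, aa] = val
    return M


def _security_values(game: RepeatedStochasticGame, victim: int,
                     tol: float, max_sweeps: int) -> dict:
    """Per-stage value of the zero-sum stochastic game against ``victim``."""
    key = ("security", victim, tol)
    if key in game.cache:
        return game.cache[key]
    V = {s: 0.0 for s in game.decision_stages}
    for sweep in range(max_sweeps):
        delta = 0.0
        for s in game.decision_stages:
            v, _ = solve_matrix_game(_victim_matrix(game, s, victim, V))
            delta = max(delta, abs(v - V[s]))
            V[s] = v
        if delta <= tol:
            break
    else:
        raise ConvergenceError(
            f"maximin value iteration for {game.name} did not converge "
            f"(residual {delta:.3e} after {max_sweeps} sweeps)")
    game.cache[key] = V
    return V


def maximin_value(game: RepeatedStochasticGame, player: int,
                  tol: float = 1e-10, max_sweeps: int = 10_000) -> float:
    """The per-round payoff ``player`` can guarantee regardless of the partner."""
    return _security_values(game, player, tol, max_sweeps)[game.start_stage]


def maximin_strategy(game: RepeatedStochasticGame, player: int,
                     tol: float = 1e-10, max_sweeps: int = 10_000) -> dict:
    """Per-stage mixed strategy guaranteeing ``player`` its maximin value."""
    key = ("maximin_strategy", player, tol)
    if key not in game.cache:
        V = _security_values(game, player, tol, max_sweeps)
        pol = {}
        for s in game.decision_stages:
            _, x = solve_matrix_game(_victim_matrix(game, s, player, V))
            pol[s] = x
        game.cache[key] = pol
    return game.cache[key]


def minimax_attack_strategy(game: RepeatedStochasticGame, victim: int,
                            tol: float = 1e-10, max_sweeps: int = 10_000,
                            ) -> tuple[dict, float]:
    """Attacker's per-stage strategy minimizing the victim's best payoff.

    Returns ``(strategy, attack_value)``; the attack value equals the
    victim's maximin value by LP duality.
    """
    key = ("attack", victim, tol)
    if key not in game.cache:
        V = _security_values(game, victim, tol, max_sweeps)
        pol = {}
        for s in game.decision_stages:
            pol[s] = minimizing_strategy(_victim_matrix(game, s, victim, V))
        game.cache[key] = (pol, V[game.start_stage])
    return game.cache[key]
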