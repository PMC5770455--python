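"""The periodic-table benchmark: 2x2 games with strict ordinal preferences.

Each player ranks the four outcomes of a 2x2 game strictly, so each player's
payoffs are a permutation of {1, 2, 3, 4} (used directly as cardinal values,
which planning requires).  Two labeled games are equivalent when one maps to
the other by relabeling either player's two actions; canonicalizing the
24 x 24 = 576 labeled payoff assignments under the four relabeling
symmetries yields exactly 144 distinct game structures.
"""

from __future__ import annotations

import itertools

import numpy as np

from .games import RepeatedStochasticGame, normal_form

_OUTCOMES = ((0, 0), (0, 1), (1, 0), (1, 1))


def _encode(arr: np.ndarray) -> tuple:
    """Flatten a (2, 2, 2) payoff array into a comparable tuple."""
    return tuple(int(v) for v in arr.reshape(-1))


def relabelings(payoffs) -> list[np.ndarray]:
    """The four action-relabeled variants of a 2x2 payoff array."""
    arr = np.asarray(payoffs)
    out = []
    for flip0 in (False, True):
        for flip1 in (False, True):
            m = arr
            if flip0:
                m = m[::-1, :, :]
            if flip1:
                m = m[:, ::-1, :]
            out.append(m)
    return out


def canonical_form(payoffs) -> tuple:
    """Lexicographically smallest encoding over the relabeling symmetries."""
    return min(_encode(m) for m in relabelings(payoffs))


def all_ordinal_payoff_matrices():
    """All 576 labeled strict-ordinal 2x2 payoff arrays, in deterministic order."""
    perms = list(itertools.permutations((1, 2, 3, 4)))
    for p0 in perms:
        for p1 in perms:
            arr = np.zeros((2, 2, 2), dtype=int)
            for k, (a0, a1) in enumerate(_OUTCOMES):
                arr[a0, a1, 0] = p0[k]
                arr[a0, a1, 1] = p1[k]
            yield arr


def pure_nash_outcomes(payoffs) -> list[tuple]:
    """Pure-strategy Nash equilibria of a 2x2 payoff array."""
    arr = np.asarray(payoffs)
    eqs = []
    for a0, a1 in _OUTCOMES:
        if (arr[a0, a1, 0] >= arr[1 - a0, a1, 0]
                and arr[a0, a1, 1] >= arr[a0, 1 - a1, 1]):
            eqs.append((a0, a1))
    return eqs


def default_family_tagger(payoffs) -> str:
    """A coarse payoff-family label for a strict-ordinal 2x2 game.

    This taxonomy is a configurable default; pass a different callable to
    :func:`enumerate_ordinal_2x2` to relabel the table.
    """
    arr = np.asarray(payoffs)
    eqs = pure_nash_outcomes(arr)
    if any(arr[a0, a1, 0] == 4 and arr[a0, a1, 1] == 4 for a0, a1 in _OUTCOMES):
        return "win-win"
    # ordinal prisoner's dilemma: dominant defection, mutual cooperation
    # beats mutual defection, under some action labeling
    for m in relabelings(arr):
        if (m[1, 0, 0] > m[0, 0, 0] > m[1, 1, 0] > m[0, 1, 0]
                and m[0, 1, 1] > m[0, 0, 1] > m[1, 1, 1] > m[1, 0, 1]):
            return "prisoners-dilemma"
    if not eqs:
        return "cyclic"
    if len(eqs) == 2:
        (e1, e2) = eqs
        p1 = (arr[e1 + (0,)], arr[e1 + (1,)])
        p2 = (arr[e2 + (0,)], arr[e2 + (1,)])
        if (p1[0] - p2[0]) * (p1[1] - p2[1]) < 0:
            return "battle"  # players prefer different equilibria
        return "coordination"
    return "unique-equilibrium"


def enumerate_ordinal_2x2(tagger=default_family_tagger) -> list[RepeatedStochasticGame]:
    """One canonical representative per strict-ordinal 2x2 equivalence class.

    Returns 144 normal-form games, each tagged with a payoff-family label.
    """
    reps: dict[tuple, np.ndarray] = {}
    for arr in all_ordinal_payoff_matrices():
        key = canonical_form(arr)
        if key not in reps:
            reps[key] = np.asarray(key).reshape(2, 2, 2)
    games = []
    for k, (key, arr) in enumerate(sorted(reps.items())):
        payoffs = [[(int(arr[a0, a1, 0]), int(arr[a0, a1, 1])) for a1 in (0, 1)]
                   for a0 in (0, 1)]
        games.append(normal_form(f"ordinal-{k:03d}", payoffs,
                                 family=tagger(arr) if tagger else ""))
    return games


def benchmark_subset(n: int = 20) -> list[RepeatedStochasticGame]:
    """A deterministic spread of ``n`` games from the 144-game benchmark."""
    games = enumerate_ordinal_2x2()
    idx = np.linspace(0, len(games) - 1, n).round().astype(int)
    return [games[i] for i in idx]
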