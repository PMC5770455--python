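"""Tournament evaluation: round-robin records, the six ranking metrics, and
cooperation-dynamics summaries (time to mutual cooperation, loyalty).

A round-robin runs every pairing of algorithms (including self-play) in
every game for several seeds and stores mean per-round payoffs.  Derived
metrics: the round-robin average, the best score (share of partners against
which an algorithm earns the most), the worst-case standardized score,
final usage rates under the discrete-time replicator dynamic, and two
elimination tournaments (iterated removal of the weakest survivor by
round-robin average or by worst-case score).  Standardized scores are
z-scores computed within each game.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .match import run_match
from .planning import round_match_flags


def _make_agent(spec):
    from .baselines import registry_lookup
    if isinstance(spec, str):
        return registry_lookup(spec)
    return spec()  # factory


def match_seed(base_seed: int, game_index: int, i: int, j: int) -> int:
    """Deterministic per-match seed derived from the tournament seed."""
    ss = np.random.SeedSequence((base_seed, game_index, i, j))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class MetricTable:
    """Round-robin payoff records plus derived tournament metrics."""

    records: pd.DataFrame  # columns: alg, partner, game, seed, payoff
    algorithms: list
    games: list

    # -- aggregates -------------------------------------------------------
    def pair_means(self) -> pd.DataFrame:
        """Mean per-round payoff per (alg, partner), over games and seeds."""
        return (self.records.groupby(["alg", "partner"])["payoff"]
                .mean().unstack())

    def round_robin_average(self) -> pd.Series:
        """Mean payoff across all games and partners (higher is better)."""
        return (self.records.groupby("alg")["payoff"].mean()
                .reindex(self.algorithms))

    def standardized(self) -> pd.DataFrame:
        """Per-game z-scores of the (alg, partner, game) mean payoffs."""
        g = (self.records.groupby(["game", "alg", "partner"])["payoff"]
             .mean().reset_index())

        def z(s):
            sd = s.std(ddof=0)
            return (s - s.mean()) / sd if sd > 1e-12 else s * 0.0

        g["z"] = g.groupby("game")["payoff"].transform(z)
        return g

    def best_score(self) -> pd.Series:
        """Percent of partners against which the algorithm pays best.

        Exact ties split the credit for that partner equally.
        """
        means = (self.records.groupby(["alg", "partner"])["payoff"]
                 .mean().unstack())
        credit = pd.Series(0.0, index=self.algorithms)
        partners = list(means.columns)
        for p in partners:
            col = means[p].dropna()
            top = col.max()
            winners = col[col >= top - 1e-9].index
            for w in winners:
                credit[w] += 1.0 / len(winners)
        return credit / len(partners) * 100.0

    def worst_case_score(self) -> pd.Series:
        """Per algorithm, the minimum standardized score over games and partners."""
        z = self.standardized()
        return (z.groupby("alg")["z"].min().reindex(self.algorithms))

    def cross_payoff_matrix(self) -> pd.DataFrame:
        """Square expected-payoff matrix between algorithms (over games, seeds)."""
        m = self.pair_means().reindex(index=self.algorithms,
                                      columns=self.algorithms)
        return m

    def ranks(self, generations: int = 10_000) -> pd.DataFrame:
        """Rank (1 = best) of every algorithm under each of the six metrics."""
        rr = self.round_robin_average()
        out = pd.DataFrame(index=self.algorithms)
        out["round_robin"] = rr.rank(ascending=False, method="min")
        out["best_score"] = self.best_score().rank(ascending=False, method="min")
        out["worst_case"] = self.worst_case_score().rank(ascending=False, method="min")
        _, final = replicator_dynamics(self.cross_payoff_matrix().to_numpy(),
                                       generations=generations)
        out["replicator"] = pd.Series(final, index=self.algorithms).rank(
            ascending=False, method="min")
        for variant in ("group1", "group2"):
            order = elimination_tournament(self, variant)
            # eliminated first = worst rank
            r = {name: len(order) - k for k, name in enumerate(order)}
            out[f"elim_{variant}"] = pd.Series(r)
        return out


def round_robin(algorithms, games, n_rounds: int, seeds, talk: bool = False,
                stage_cap: int = 50) -> MetricTable:
    """Run every pairing (including self-play) in every game for every seed.

    ``algorithms`` is a sequence of registry names (or (name, factory)
    pairs); ``seeds`` an integer count or an explicit list of base seeds.
    Each unordered pairing is played once per (game, seed) and recorded
    from both perspectives, so the table covers all ordered pairings.
    Deterministic given the seed list.
    """
    specs = []
    for a in algorithms:
        if isinstance(a, str):
            specs.append((a, a))
        else:
            specs.append(a)
    names = [n for n, _ in specs]
    if len(names) != len(set(names)):
        raise ValueError("duplicate algorithm names")
    if len(names) < 2:
        raise ValueError("need at least two algorithms")
    if isinstance(seeds, int):
        seeds = list(range(seeds))
    rows = []
    for gi, game in enumerate(games):
        for i, (name_i, spec_i) in enumerate(specs):
            for j in range(i, len(specs)):
                name_j, spec_j = specs[j]
                for base in seeds:
                    h = run_match(_make_agent(spec_i), _make_agent(spec_j),
                                  game, n_rounds,
                                  seed=match_seed(base, gi, i, j),
                                  talk=talk, stage_cap=stage_cap)
                    p_i, p_j = h.mean_payoffs()
                    rows.append((name_i, name_j, game.name, base, p_i))
                    rows.append((name_j, name_i, game.name, base, p_j))
    records = pd.DataFrame(rows, columns=["alg", "partner", "game", "seed",
                                          "payoff"])
    return MetricTable(records=records, algorithms=names,
                       games=[g.name for g in games])


def replicator_dynamics(cross: np.ndarray, generations: int = 10_000,
                        init=None) -> tuple[np.ndarray, np.ndarray]:
    """Discrete-time replicator dynamic on a payoff matrix.

    x'_k = x_k f_k / sum_j x_j f_j with fitness f = (A x); payoffs are
    shifted to be strictly positive first.  Returns (trajectory, final
    frequencies); the trajectory has shape (generations + 1, K).
    """
    A = np.asarray(cross, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"cross-payoff matrix must be square, got {A.shape}")
    if np.isnan(A).any():
        raise ValueError("cross-payoff matrix has missing entries")
    A = A - A.min() + 1e-6
    K = A.shape[0]
    x = np.full(K, 1.0 / K) if init is None else np.asarray(init, dtype=float)
    traj = np.empty((generations + 1, K))
    traj[0] = x
    for g in range(1, generations + 1):
        f = A @ x
        x = x * f
        x /= x.sum()
        traj[g] = x
    return traj, x


def elimination_tournament(table: MetricTable, variant: str = "group1") -> list:
    """Iterated elimination; returns names in elimination order.

    ``group1`` removes the survivor with the lowest round-robin average
    among survivors each iteration; ``group2`` removes by lowest worst-case
    standardized score.  Ties break by the algorithm's overall round-robin
    average before elimination began, then by name.
    """
    if variant not in ("group1", "group2"):
        raise ValueError(f"unknown elimination variant {variant!r}")
    prior = table.round_robin_average()
    survivors = list(table.algorithms)
    order = []
    rec = table.records
    while len(survivors) > 1:
        sub = rec[rec["alg"].isin(survivors) & rec["partner"].isin(survivors)]
        if variant == "group1":
            score = sub.groupby("alg")["payoff"].mean()
        else:
            g = sub.groupby(["game", "alg", "partner"])["payoff"].mean().reset_index()

            def z(s):
                sd = s.std(ddof=0)
                return (s - s.mean()) / sd if sd > 1e-12 else s * 0.0

            g["z"] = g.groupby("game")["payoff"].transform(z)
            score = g.groupby("alg")["z"].min()
        score = score.reindex(survivors)
        lowest = score.min()
        tied = [a for a in survivors if score[a] <= lowest + 1e-12]
        loser = min(tied, key=lambda a: (prior[a], a))
        order.append(loser)
        survivors.remove(loser)
    order.extend(survivors)
    return order


def time_to_mutual_cooperation(histories, game) -> np.ndarray:
    """First round t such that rounds t and t+1 both match the Nash
    bargaining pattern (same phase offset); ``inf`` when never."""
    times = []
    for h in histories:
        flags = round_match_flags(h, game)
        best = np.inf
        for o in range(flags.shape[0]):
            both = flags[o, :-1] & flags[o, 1:]
            idx = np.flatnonzero(both)
            if idx.size:
                best = min(best, idx[0] + 1)  # rounds are 1-indexed
        times.append(best)
    return np.asarray(times, dtype=float)


def empirical_cdf(times: np.ndarray, max_round: int) -> tuple[np.ndarray, np.ndarray]:
    """CDF of cooperation times over rounds 1..max_round (censored at inf)."""
    xs = np.arange(1, max_round + 1)
    ps = np.array([(times <= x).mean() for x in xs])
    return xs, ps


def loyalty(histories, game) -> float:
    """Percent of pairings that, having reached two consecutive mutually
    cooperative rounds, never deviated from the pattern afterwards.

    Pairings that never cooperate are excluded from the denominator.
    """
    n_reached = 0
    n_loyal = 0
    for h in histories:
        flags = round_match_flags(h, game)
        best, loyal = np.inf, False
        for o in range(flags.shape[0]):
            both = flags[o, :-1] & flags[o, 1:]
            idx = np.flatnonzero(both)
            if not idx.size:
                continue
            t = idx[0] + 1
            stays = bool(flags[o, t + 1:].all())  # rounds after t+1
            if t < best:
                best, loyal = t, stays
            elif t == best:
                loyal = loyal or stays
        if np.isfinite(best):
            n_reached += 1
            n_loyal += loyal
    if n_reached == 0:
        return float("nan")
    return 100.0 * n_loyal / n_reached
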