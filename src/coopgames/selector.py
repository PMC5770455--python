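"""The S++ meta-algorithm: aspiration-based satisficing over experts.

S++ plays a repeated game by committing to one expert per epoch of ``m``
rounds.  At each epoch boundary it

1. computes each expert's potential (estimated best attainable per-round
   payoff),
2. prunes the expert set to those whose potential meets its aspiration
   level, ``E(t) = {e_j : rho_j(t) >= alpha(t)}``,
3. keeps the incumbent expert if it survives the pruning (satisficing
   inertia), otherwise draws uniformly from the pruned set, and
4. after the epoch, relaxes its aspiration toward the realized mean payoff
   R: ``alpha(t+m) = lambda^m * alpha(t) + (1 - lambda^m) * R``.

The aspiration starts at the maximum potential, so the algorithm first
chases its most ambitious (often exploitative) experts and works its way
down to compromises its partner will actually tolerate.  Algorithm S is the
same meta-strategy without the pruning step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .experts import Expert, build_expert_set
from .match import Agent


def update_aspiration(alpha: float, lam: float, m: int, R: float) -> float:
    """Aspiration relaxation toward the epoch's mean payoff."""
    if not 0.0 < lam < 1.0:
        raise ValueError(f"learning rate must lie strictly in (0, 1), got {lam}")
    if m < 1:
        raise ValueError(f"epoch length must be >= 1, got {m}")
    return lam ** m * alpha + (1 - lam ** m) * R


def prune_experts(potentials: dict, alpha: float) -> list:
    """Expert ids whose potential meets the aspiration.

    If no expert qualifies (the aspiration has outrun every potential), the
    experts tying for the highest potential are returned as a documented
    fallback.
    """
    kept = [eid for eid, rho in potentials.items() if rho >= alpha]
    if not kept:
        best = max(potentials.values())
        kept = [eid for eid, rho in potentials.items() if rho >= best - 1e-9]
    return kept


def select_expert(previous, candidates: list, potentials: dict, alpha: float,
                  rng: np.random.Generator, last_payoff: float | None = None):
    """Satisficing choice: keep the incumbent while it satisfies.

    The incumbent is kept when it survives the pruning (its potential still
    meets the aspiration) and the payoff it just delivered did too;
    otherwise a new expert is drawn uniformly from the candidate set.
    """
    satisfied = last_payoff is None or last_payoff >= alpha - 1e-9
    if previous in candidates and potentials[previous] >= alpha and satisfied:
        return previous
    if len(candidates) == 1:
        return candidates[0]
    return candidates[int(rng.integers(len(candidates)))]


@dataclass
class SelectorState:
    """Diagnostic snapshot of the meta-level state at an epoch boundary."""

    t: int
    alpha: float
    potentials: dict
    pruned: list
    selected: str
    epoch_payoff: float | None = None


class SPlusPlus(Agent):
    """The S++ agent.

    Parameters
    ----------
    lam : float
        Per-round aspiration learning rate, strictly in (0, 1).
    m : int
        Epoch length in rounds (commitment span of a selected expert).
    omega_grid :
        Blend-weight grid for target-solution planning (None = default).
    prune : bool
        With ``False`` this is algorithm S: satisficing without the
        potential-based pruning step.
    mbrl_gamma : float
        Discount for the MBRL expert.
    """

    name = "s_plus_plus"

    def __init__(self, lam: float = 0.95, m: int = 3, omega_grid=None,
                 prune: bool = True, mbrl_gamma: float = 0.95):
        if not 0.0 < lam < 1.0:
            raise ValueError(f"learning rate must lie strictly in (0, 1), got {lam}")
        if m < 1:
            raise ValueError(f"epoch length must be >= 1, got {m}")
        self.lam = lam
        self.m = m
        self.omega_grid = omega_grid
        self.prune = prune
        self.mbrl_gamma = mbrl_gamma

    # -- hooks for the cheap-talk subclass --------------------------------
    def _candidate_ids(self, potentials: dict) -> list:
        if self.prune:
            return prune_experts(potentials, self.alpha)
        return list(potentials)

    def _on_new_epoch(self) -> None:
        """Called after each (re)selection; the talking subclass speaks here."""

    # ---------------------------------------------------------------------
    def begin_match(self, game, player, rng):
        super().begin_match(game, player, rng)
        self.experts: list[Expert] = build_expert_set(
            game, player, self.omega_grid, mbrl_gamma=self.mbrl_gamma)
        self.by_id = {e.id: e for e in self.experts}
        for e in self.experts:
            e.reset(game, player, rng)
        self.t = 1
        self.epoch_rounds = 0
        self.epoch_total = 0.0
        self.selected: Expert | None = None
        self.trace: list[SelectorState] = []
        potentials = {e.id: e.potential() for e in self.experts}
        self.alpha = max(potentials.values())
        self._reselect(potentials)

    def _reselect(self, potentials: dict, last_payoff: float | None = None) -> None:
        candidates = self._candidate_ids(potentials)
        prev = self.selected.id if self.selected is not None else None
        chosen = select_expert(prev, candidates, potentials, self.alpha,
                               self.rng, last_payoff)
        switched = chosen != prev
        self.selected = self.by_id[chosen]
        if switched:
            self.selected.on_selected()
        self.trace.append(SelectorState(
            t=self.t, alpha=self.alpha, potentials=potentials,
            pruned=candidates, selected=chosen))
        self._on_new_epoch()

    def act(self, stage):
        return self.selected.act(stage, self.t)

    def end_round(self, record):
        self.epoch_total += record.payoffs[self.player]
        self.epoch_rounds += 1
        for e in self.experts:
            e.end_round(record, selected=(e is self.selected))
        self.t = record.t + 1
        if self.epoch_rounds >= self.m:
            R = self.epoch_total / self.epoch_rounds
            self.trace[-1].epoch_payoff = R
            self.alpha = update_aspiration(self.alpha, self.lam, self.epoch_rounds, R)
            self.epoch_rounds = 0
            self.epoch_total = 0.0
            potentials = {e.id: e.potential() for e in self.experts}
            self._reselect(potentials, last_payoff=R)

    def round_notes(self):
        return {"expert": self.selected.id, "alpha": round(self.alpha, 6)}


class SAlgorithm(SPlusPlus):
    """Algorithm S: the satisficing selector without expert pruning."""

    name = "s"

    def __init__(self, **kwargs):
        kwargs["prune"] = False
        super().__init__(**kwargs)
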