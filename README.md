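# coopgames

Cooperation algorithms for two-player repeated (stochastic) games, for
researchers studying how learning agents forge cooperative relationships
with partners whose interests only partially overlap — the territory
between zero-sum play and common-interest teamwork.

The package implements:

* **S++**, an aspiration-based expert algorithm.  From the game
  description it computes a set of expert strategies — expectant
  followers and trigger strategies over planned compromise solutions, a
  preventative strategy, the maximin strategy, and a model-based
  reinforcement learner — and selects among them by satisficing: experts
  whose potential ρ_j(t) falls below the aspiration α(t) are pruned,

      E(t) = { e_j ∈ E : ρ_j(t) ≥ α(t) },

  the chosen expert is followed for an epoch of m rounds, and the
  aspiration then relaxes toward the realized mean payoff R,

      α(t+m) = λ^m α(t) + (1 − λ^m) R,      λ ∈ (0, 1).

* **S#**, S++ extended with cheap talk: each expert carries a Mealy
  machine that voices plans, threats, praise, displeasure, punishment
  notices, and forgiveness; partner proposals filter the expert set to
  congruent offers, ρ_j(t) ≥ α(t) within E_cong(t); and trust gating
  makes the agent listen less to partners who break their word and go
  silent when its own proposals are ignored.  Without cheap talk S# is
  identical to S++.

* The planning layer behind the experts: compromise solutions from
  joint-action MDPs with blended reward y_ω(s,a) = ω·r_i + (1−ω)·r_{−i},
  maximin security levels and minimax punishment via linear programming,
  and the Nash bargaining solution (the operational definition of mutual
  cooperation) maximizing (v_i − m_i)(v_{−i} − m_{−i}).

* The 144-game benchmark of strict-ordinal 2×2 games, twelve baseline
  strategies (tit-for-tat variants, win-stay-lose-shift, Bully,
  memory-one/two stochastic strategies, fictitious play, model-based and
  tabular reinforcement learners, and expert-selection baselines), and
  tournament machinery: round-robin tables, best/worst-case scores,
  replicator dynamics, elimination tournaments, time-to-cooperation and
  loyalty analyses.

See `docs/methods.md` for the models, default parameters, and design
choices.

## Worked example

Simulate 50 rounds of the 0-1-3-5 prisoner's dilemma between two copies
of S# with cheap talk enabled:

```
$ coopgames simulate --game pd_0135 --agents s_sharp,s_sharp \
      --rounds 50 --seed 7 --talk on
game=pd_0135 rounds=50 talk=on
s_sharp: mean payoff 2.2000
s_sharp: mean payoff 2.5000
mutual cooperation: 0.540
```

The agents start out probing ambitious compromises (which is why the
50-round averages sit below 3), discover each other's willingness to
punish, coordinate on the fair solution through their exchanged
proposals, and from then on cooperate; the mutual-cooperation line is the
fraction of rounds matching the game's Nash bargaining pattern — here the
mutual-cooperation joint action worth (3, 3).

The compromises the planner finds for the same game:

```
$ coopgames plan --game pd_0135 --all
kind payoff0 payoff1 omegas
pure          0.0000   5.0000  (0.0,)
pure          3.0000   3.0000  (0.4,)
pure          5.0000   0.0000  (0.7,)
alternating   1.5000   4.0000  (0.0, 0.4)
alternating   2.5000   2.5000  (0.0, 0.7)
alternating   4.0000   1.5000  (0.4, 0.7)
```

Three pure solutions — one favoring each player and the fair (3, 3)
outcome — plus the three length-2 alternations between them.  The same
library calls are available in Python:

```python
import coopgames as cg

pd = cg.make_fixture("pd_0135")
_, solution = cg.solve_joint_mdp(pd, 0.5)
print(solution.payoffs)                      # (3.0, 3.0)
print(cg.nash_bargaining_solution(pd).payoffs)  # (3.0, 3.0)
print(len(cg.enumerate_ordinal_2x2()))       # 144

history = cg.run_match(cg.SSharp(), cg.SSharp(), pd,
                       n_rounds=200, seed=7, talk=True)
print(cg.mutual_cooperation_proportion(history, pd))
```

Other CLI verbs: `coopgames plan --omega 0.5` (one compromise with its
joint policy), `coopgames enumerate-games --families`, `coopgames agents
list`, `coopgames tournament --config tourney.yaml --out results/`, and
`coopgames report --dir results/`.

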