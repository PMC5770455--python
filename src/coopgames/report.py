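"""Match-log serialization and result aggregation.

Logs are flat, column-oriented CSV (one row per round) for diff-ability.
"""

from __future__ import annotations

import os

import pandas as pd

from .match import MatchHistory


def _fmt_messages(messages) -> str:
    return "+".join(str(m.act) for m in messages)


def match_log_frame(history: MatchHistory) -> pd.DataFrame:
    """One row per round: stages, actions, payoffs, message ids, diagnostics."""
    rows = []
    for r in history.rounds:
        n0, n1 = r.notes
        rows.append({
            "t": r.t,
            "stages": "|".join(str(s) for s in r.stages),
            "actions0": "|".join(str(j[0]) for j in r.joint_actions),
            "actions1": "|".join(str(j[1]) for j in r.joint_actions),
            "payoff0": r.payoffs[0],
            "payoff1": r.payoffs[1],
            "messages0": _fmt_messages(r.messages[0]),
            "messages1": _fmt_messages(r.messages[1]),
            "expert0": n0.get("expert", ""),
            "expert1": n1.get("expert", ""),
            "fsm0": n0.get("fsm_state", ""),
            "fsm1": n1.get("fsm_state", ""),
            "capped": r.capped,
        })
    df = pd.DataFrame(rows)
    df.attrs["game"] = history.game_name
    df.attrs["agents"] = history.agent_names
    df.attrs["seed"] = history.seed
    return df


def save_match_log(history: MatchHistory, path) -> None:
    df = match_log_frame(history)
    with open(path, "w") as fh:
        fh.write(f"# game={history.game_name} agents={history.agent_names[0]},"
                 f"{history.agent_names[1]} seed={history.seed} "
                 f"talk={history.talk}\n")
        df.to_csv(fh, index=False)


def load_match_log(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    meta = dict(kv.split("=", 1) for kv in header.lstrip("# ").split())
    df.attrs.update(meta)
    df.attrs["agents"] = tuple(meta.get("agents", ",").split(","))
    return df


def summarize_logs(directory) -> pd.DataFrame:
    """Aggregate a directory of match logs into a per-match summary table."""
    paths = sorted(p for p in os.listdir(directory) if p.endswith(".csv"))
    if not paths:
        raise FileNotFoundError(f"no match logs (*.csv) in {directory}")
    rows = []
    for p in paths:
        df = load_match_log(os.path.join(directory, p))
        rows.append({
            "log": p,
            "game": df.attrs.get("game", ""),
            "agent0": df.attrs["agents"][0],
            "agent1": df.attrs["agents"][1],
            "seed": df.attrs.get("seed", ""),
            "rounds": len(df),
            "mean_payoff0": df["payoff0"].mean(),
            "mean_payoff1": df["payoff1"].mean(),
        })
    return pd.DataFrame(rows)


def summarize_pairings(summary: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of payoffs per (game, pairing) across seeds."""
    g = summary.groupby(["game", "agent0", "agent1"])
    out = g.agg(n=("seed", "size"),
                payoff0_mean=("mean_payoff0", "mean"),
                payoff0_sem=("mean_payoff0", "sem"),
                payoff1_mean=("mean_payoff1", "mean"),
                payoff1_sem=("mean_payoff1", "sem"))
    return out.reset_index()
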