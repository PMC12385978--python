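"""Trial execution and metrics.

Runs the plan/act loop for the three T-maze experiments, aggregates
per-trial records into the headline metrics (CS-visit rate, success rate,
and — for the discrete maze — the preferred-policy selection statistics at
the first planning event), and hosts the past-window ablation.

Seeding: trial ``i`` derives everything (hidden context, obstacle, motion
noise, latent draws) from ``base_seed + i`` through named substreams, so a
trial is reproducible in isolation and evaluation is order-invariant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import tmaze_envs as tm
from .model_core import LayerConfig, ModelSpec
from .objectives import PreferenceSpec
from .planner import Planner, PlannerConfig
from .training import TrainedModel

__all__ = ["EXPERIMENTS", "ExperimentDef", "classify_policy", "run_trials",
           "run_trial", "evaluate", "run_ablation", "TrialRecord",
           "MetricsTable"]


@dataclass(frozen=True)
class ExperimentDef:
    """Static definition of one experiment: model topology, horizon, the
    preferred goal vector, and which environment to instantiate."""

    name: str
    spec: ModelSpec
    horizon: int
    preferred_goal: np.ndarray
    continuous: bool
    maze_spec: tm.ContinuousMazeSpec | None = None
    with_obstacle: bool = False
    default_epochs: int = 500_000

    def make_env(self, rngs):
        if self.continuous:
            return tm.ContinuousTMaze(self.maze_spec, rngs,
                                      with_obstacle=self.with_obstacle)
        return tm.DiscreteTMaze(rngs)


EXPERIMENTS: dict[int, ExperimentDef] = {
    1: ExperimentDef(
        name="discrete",
        spec=ModelSpec(layers=(LayerConfig(10, 2, 1.0, 0.1),),
                       obs_dim=8, goal_dim=2, proprio_dim=4),
        horizon=3,
        preferred_goal=np.array([0.0, 1.0]),
        continuous=False,
        default_epochs=500_000),
    2: ExperimentDef(
        name="continuous",
        spec=ModelSpec(layers=(LayerConfig(80, 6, 2.0, 0.005),
                               LayerConfig(20, 3, 8.0, 0.01)),
                       obs_dim=6, goal_dim=4, proprio_dim=2),
        horizon=25,
        preferred_goal=tm.GOAL_RED_ONEHOT.copy(),
        continuous=True,
        maze_spec=tm.EXP2_SPEC,
        default_epochs=200_000),
    3: ExperimentDef(
        name="obstacle",
        spec=ModelSpec(layers=(LayerConfig(80, 6, 2.0, 0.005),
                               LayerConfig(20, 3, 8.0, 0.01)),
                       obs_dim=9, goal_dim=3, proprio_dim=2),
        horizon=60,
        preferred_goal=tm.GOAL_RED_RGB.copy(),
        continuous=True,
        maze_spec=tm.EXP3_SPEC,
        with_obstacle=True,
        default_epochs=200_000),
}


def classify_policy(state_sequence) -> str:
    """Classify a 3-move discrete state sequence: ``preferred`` first checks
    the CS (state 2) and then enters a terminal arm; ``direct`` enters an
    arm without checking; everything else is ``idle``."""
    seq = [int(s) for s in state_sequence]
    if len(seq) != 3 or any(s not in (1, 2, 3, 4) for s in seq):
        raise ValueError(f"malformed state sequence {state_sequence!r}")
    arm_steps = [i for i, s in enumerate(seq) if s in (3, 4)]
    visited_cs = 2 in seq
    if visited_cs and arm_steps and min(arm_steps) > seq.index(2):
        return "preferred"
    if arm_steps and not visited_cs:
        return "direct"
    return "idle"


def decode_states(x_pred: np.ndarray) -> np.ndarray:
    """Argmax-decode the 4-dim position block of discrete predictions
    (..., Dx) into state ids 1..4."""
    return np.argmax(x_pred[..., :4], axis=-1) + 1


@dataclass
class TrialRecord:
    """Everything a single trial produced."""

    seed: int
    context: dict
    steps: list[dict] = field(default_factory=list)
    state_sequence: list | None = None
    pose_track: list | None = None
    cs_visited: bool = False
    success: bool = False
    policy_class: str | None = None
    faults: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, default=_jsonable)


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating, np.bool_)):
        return o.item()
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def write_records(records: list[TrialRecord], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


@dataclass
class MetricsTable:
    """Per-agent aggregate metrics; rates are fractions in [0, 1]."""

    rows: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows).T

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


# ---------------------------------------------------------------------------
# trial execution
# ---------------------------------------------------------------------------

def _trial_rngs(base_seed: int, n: int, stream: int):
    return [np.random.default_rng(np.random.SeedSequence([base_seed + i,
                                                          stream]))
            for i in range(n)]


def run_trials(model: TrainedModel, experiment: int, mode: str,
               n_trials: int, base_seed: int,
               num_samples: int = 100, past_window: int | None = None,
               infer_iters: int = 100, infer_rate: float = 0.1,
               goal_in_past_targets: bool = True,
               goal_in_future_targets: bool = True,
               keep_first_event: bool = True
               ) -> tuple[list[TrialRecord], Planner, dict]:
    """Run ``n_trials`` lockstep trials of one agent; returns the per-trial
    records, the planner (whose ``logs`` hold every replanning event), and
    the environment outcome summary."""
    exp = EXPERIMENTS[experiment]
    if model.weights.spec != exp.spec:
        raise ValueError("checkpoint topology does not match experiment")
    env_rngs = _trial_rngs(base_seed, n_trials, 0)
    plan_rngs = _trial_rngs(base_seed, n_trials, 1)
    env = exp.make_env(env_rngs)
    cfg = PlannerConfig(
        past_window=past_window if past_window is not None else exp.horizon,
        num_samples=num_samples,
        preference=PreferenceSpec(exp.preferred_goal),
        infer_iters=infer_iters, infer_rate=infer_rate,
        goal_in_past_targets=goal_in_past_targets,
        goal_in_future_targets=goal_in_future_targets)
    planner = Planner(model, exp.horizon, n_trials, cfg, plan_rngs, mode)

    first_event = None
    obs = env.reset_observation()
    n_actions = exp.horizon - 1
    for k in range(n_actions):
        action = planner.step(obs)
        if k == 0 and keep_first_event and mode != "habituation":
            first_event = _snapshot_first_event(planner, exp)
        if exp.continuous:
            obs = env.act(action)
        else:
            obs = env.act(decode_states(action))
    out = env.outcomes()

    records = []
    for i in range(n_trials):
        rec = TrialRecord(
            seed=base_seed + i,
            context=({"cs": env.contexts[i].cs_color} if not exp.continuous
                     else {"goal_side": env.goal_sides[i],
                           "obstacle": None if env.obstacles[i] is None
                           else env.obstacles[i].rect.x0}),
            cs_visited=bool(out["cs_visited"][i]),
            success=bool(out["success"][i]))
        for log in planner.logs:
            step = log.to_dict()
            step = {k: (v[i] if isinstance(v, list) and len(v) == n_trials
                        else v) for k, v in step.items()}
            rec.steps.append(step)
        if not exp.continuous:
            rec.state_sequence = out["state_sequences"][i].tolist()
            rec.policy_class = classify_policy(rec.state_sequence)
            rec.faults = int(out["faults"][i])
        else:
            rec.pose_track = out["pose_track"][i].tolist()
        records.append(rec)
    if first_event is not None:
        out["first_event"] = first_event
    return records, planner, out


def _snapshot_first_event(planner: Planner, exp: ExperimentDef) -> dict:
    """Candidate-level statistics of the very first replanning event (the
    step the discrete-maze analysis pools over)."""
    log = planner.logs[0]
    snap = {"G": log.G.copy(), "selected": log.selected.copy(),
            "m": log.m.copy()}
    if not exp.continuous:
        last = planner._last_candidates
        xp = last.x_pred.reshape(last.B, last.N, last.tau_f, -1)
        future = decode_states(xp)  # (B, N, tau_f)
        start = np.ones(future.shape[:2] + (exp.horizon - last.tau_f,),
                        dtype=int)
        snap["policies"] = np.concatenate([start, future], axis=-1)
        gp = last.g_pred.reshape(last.B, last.N, last.tau_f, -1)
        snap["reach_pred"] = np.argmax(gp[:, :, -1], axis=-1) == 1
    return snap


def run_trial(model: TrainedModel, experiment: int, mode: str, seed: int,
              **kwargs) -> TrialRecord:
    """Single-trial convenience wrapper (identical to the matching element
    of a batched run with the same base seed)."""
    records, _, _ = run_trials(model, experiment, mode, 1, seed, **kwargs)
    return records[0]


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def evaluate(model: TrainedModel, experiment: int, modes: list[str],
             n_trials: int, base_seed: int, **kwargs
             ) -> tuple[MetricsTable, dict[str, list[TrialRecord]]]:
    """Run every agent mode on identical trial seeds and tabulate rates."""
    if n_trials < 1:
        raise ValueError("need at least one trial")
    table = MetricsTable()
    all_records: dict[str, list[TrialRecord]] = {}
    for mode in modes:
        records, planner, out = run_trials(model, experiment, mode,
                                           n_trials, base_seed, **kwargs)
        all_records[mode] = records
        row = metrics_from_records(records)
        if "first_event" in out and not EXPERIMENTS[experiment].continuous:
            row.update(_exp1_first_event_metrics(out["first_event"]))
        table.rows[mode] = row
    return table, all_records


def metrics_from_records(records: list[TrialRecord]) -> dict:
    """Aggregate rates from persisted trial records (round-trips through
    the JSON-lines log give identical numbers)."""
    n = len(records)
    return {
        "n_trials": n,
        "cs_rate": sum(r.cs_visited for r in records) / n,
        "success_rate": sum(r.success for r in records) / n,
    }


def _exp1_first_event_metrics(ev: dict) -> dict:
    """Candidate statistics of the discrete maze's first planning event.

    The *selected*-plan rate classifies the winning candidate's position
    pattern (does it check the CS before entering an arm).  Sample-level
    statistics additionally require the imagined episode to end on the
    goal — a preferred *sample* both checks the CS and finds the goal, so
    its training-set frequency is 2 sequences in 20.
    """
    pols = ev["policies"]            # (B, N, 3)
    G = ev["G"]                      # (B, N)
    B, N, _ = pols.shape
    flat = pols.reshape(B * N, 3)
    classes = np.array([classify_policy(s) for s in flat])
    pattern_pref = (classes == "preferred").reshape(B, N)
    preferred = pattern_pref & ev["reach_pred"]
    sel = ev["selected"]
    sel_pref = pattern_pref[np.arange(B), sel]
    g_pref = G[preferred]
    g_other = G[~preferred]
    return {
        "preferred_selected_rate": float(sel_pref.mean()),
        "preferred_sample_fraction": float(preferred.mean()),
        "efe_preferred_mean": float(g_pref.mean()) if g_pref.size else np.nan,
        "efe_preferred_sd": float(g_pref.std()) if g_pref.size else np.nan,
        "efe_other_mean": float(g_other.mean()) if g_other.size else np.nan,
        "efe_other_sd": float(g_other.std()) if g_other.size else np.nan,
    }


def run_ablation(model: TrainedModel, taup_values: list[int], n_trials: int,
                 base_seed: int, experiment: int = 3, **kwargs
                 ) -> MetricsTable:
    """Past-window ablation: evaluate the EFE agent at each tau_p with
    identical trial seeds (identical hidden contexts per trial index)."""
    table = MetricsTable()
    for taup in taup_values:
        records, _, _ = run_trials(model, experiment, "efe", n_trials,
                                   base_seed, past_window=taup, **kwargs)
        table.rows[f"taup={taup}"] = metrics_from_records(records)
    return table
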