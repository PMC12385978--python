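"""T-maze worlds: discrete, continuous, and continuous-with-obstacle.

The shared task logic: the maze's bottom arm carries a *conditioning
stimulus* (CS) — a colored floor patch whose color (blue or green, 50/50
per episode) deterministically reveals which of the two top arms holds the
red goal (blue CS => left arm red, green CS => right arm red; the other arm
is white).  The agent starts at the junction with no information about the
goal side, so reliable goal-reaching requires first visiting the CS.

Experiment encodings
--------------------
* Experiment 1 (discrete): 4 positions (center, bottom, left, right) as a
  one-hot, floor color as a one-hot over (blue, green, red, white), and a
  2-dim one-hot goal-reached flag; length-3 sequences of post-move states.
* Experiment 2 (continuous): (x, y) pose, color one-hot (4) and a
  teleological 4-dim goal-sensation one-hot (red or white = the color the
  trajectory ends on, constant over the sequence); 25 steps, dt = 0.5.
* Experiment 3 (continuous + obstacle): (x, y), RGB floor color (3),
  4 diagonal range sensors clipped at 0.7, RGB goal sensation (3); 60
  steps, dt = 0.2; a half-corridor-depth obstacle sits at a uniformly
  random position along the top wall, outside the goal areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model_core import SequenceBatch

__all__ = [
    "COLOR_NAMES", "DiscreteMazeContext", "DiscretePolicy",
    "discrete_transition", "discrete_observe", "enumerate_policies",
    "make_discrete_sequence",
    "Rect", "ContinuousMazeSpec", "EXP2_SPEC", "EXP3_SPEC", "ObstacleSpec",
    "place_obstacle", "floor_color", "range_sense", "continuous_step",
    "Dataset", "make_training_set", "save_dataset", "load_dataset",
    "DiscreteTMaze", "ContinuousTMaze", "GOAL_RED_ONEHOT", "GOAL_RED_RGB",
]

# color one-hot order used throughout
COLOR_NAMES = ("blue", "green", "red", "white")
_COLOR_IDX = {c: i for i, c in enumerate(COLOR_NAMES)}
_RGB = {"white": (1.0, 1.0, 1.0), "red": (1.0, 0.0, 0.0),
        "green": (0.0, 1.0, 0.0), "blue": (0.0, 0.0, 1.0)}

GOAL_RED_ONEHOT = np.eye(4)[_COLOR_IDX["red"]]  # preferred goal, Exp 1/2
GOAL_RED_RGB = np.array(_RGB["red"])            # preferred goal, Exp 3


# ---------------------------------------------------------------------------
# discrete T-maze
# ---------------------------------------------------------------------------

# transition graph: self-loops everywhere; the center (1) reaches every
# state, the CS location (2) does too; the arms (3, 4) are absorbing
_EDGES = {1: {1, 2, 3, 4}, 2: {1, 2, 3, 4}, 3: {3}, 4: {4}}


@dataclass(frozen=True)
class DiscreteMazeContext:
    """Hidden episode configuration: the CS color.  Blue CS puts the red
    goal at state 3 (left); green CS reverses it."""

    cs_color: str

    def __post_init__(self) -> None:
        if self.cs_color not in ("blue", "green"):
            raise ValueError("cs_color must be 'blue' or 'green'")

    @property
    def goal_state(self) -> int:
        return 3 if self.cs_color == "blue" else 4

    def color_of(self, state: int) -> str:
        if state == 1:
            return "white"
        if state == 2:
            return self.cs_color
        return "red" if state == self.goal_state else "white"


@dataclass(frozen=True)
class DiscretePolicy:
    """A length-3 state sequence (s1, s2, s3) beginning at the start state
    (s1 = 1), every consecutive pair an edge of the transition graph."""

    states: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.states[0] != 1:
            raise ValueError("policies start at state 1")
        prev = self.states[0]
        for s in self.states[1:]:
            if s not in _EDGES.get(prev, ()):  # includes invalid state ids
                raise ValueError(f"illegal transition {prev} -> {s}")
            prev = s


def discrete_transition(state: int, target_state: int) -> int:
    """Apply a transition if the edge exists; illegal moves keep the state
    (absorbed, to be logged by the caller as a fault)."""
    if state not in _EDGES or target_state not in (1, 2, 3, 4):
        raise ValueError(f"states must be in 1..4, got {state}->{target_state}")
    return target_state if target_state in _EDGES[state] else state


def discrete_observe(state: int, context: DiscreteMazeContext) -> np.ndarray:
    """10-dim observation: position one-hot(4) + color one-hot(4) +
    goal-reached one-hot(2), reached iff the current color is red."""
    color = context.color_of(state)
    pos = np.eye(4)[state - 1]
    col = np.eye(4)[_COLOR_IDX[color]]
    reached = np.eye(2)[1 if color == "red" else 0]
    return np.concatenate([pos, col, reached])


PREFERRED_POLICIES = {(1, 2, 3), (1, 2, 4)}


def enumerate_policies() -> list[DiscretePolicy]:
    """All 10 valid length-3 policies from the start state: two moves
    after the initial step, arms absorbing.  The two policies that first
    check the CS and then enter an arm — (1,2,3) and (1,2,4) — are the
    preferred ones."""
    pols = []
    for s2 in sorted(_EDGES[1]):
        for s3 in sorted(_EDGES[s2]):
            pols.append(DiscretePolicy((1, s2, s3)))
    return pols


def make_discrete_sequence(policy: DiscretePolicy,
                           context: DiscreteMazeContext) -> np.ndarray:
    """Training sequence for one (policy, context): per-step observations
    with a teleological goal block — whether the *episode* ends on the red
    goal, constant across the sequence (the same outcome encoding the
    continuous experiments use for their goal-sensation channel)."""
    rows = np.stack([discrete_observe(s, context) for s in policy.states])
    ends_red = context.color_of(policy.states[-1]) == "red"
    rows[:, 8:] = np.eye(2)[1 if ends_red else 0]
    return rows


# ---------------------------------------------------------------------------
# continuous T-maze geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rect:
    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, p, margin: float = 0.0) -> bool:
        return (self.x0 - margin < p[0] < self.x1 + margin
                and self.y0 - margin < p[1] < self.y1 + margin)

    def distance(self, p) -> float:
        dx = max(self.x0 - p[0], 0.0, p[0] - self.x1)
        dy = max(self.y0 - p[1], 0.0, p[1] - self.y1)
        return float(np.hypot(dx, dy))


STEM = Rect(1.0, 0.0, 2.0, 2.0)          # vertical corridor
TOP = Rect(0.0, 2.0, 3.0, 3.0)           # horizontal corridor
ZONE_CS = Rect(1.0, 0.0, 2.0, 0.5)       # bottom colored area (CS)
ZONE_LEFT = Rect(0.0, 2.0, 0.5, 3.0)
ZONE_RIGHT = Rect(2.5, 2.0, 3.0, 3.0)
START = np.array([1.5, 1.5])
ZONE_CENTERS = {"cs": np.array([1.5, 0.25]), "left": np.array([0.25, 2.5]),
                "right": np.array([2.75, 2.5])}

# boundary segments of the T-shaped corridor union (axis-aligned, CCW)
_WALLS = [((1, 0), (2, 0)), ((2, 0), (2, 2)), ((2, 2), (3, 2)),
          ((3, 2), (3, 3)), ((3, 3), (0, 3)), ((0, 3), (0, 2)),
          ((0, 2), (1, 2)), ((1, 2), (1, 0))]

#: collision margin: the agent body keeps this distance from the obstacle,
#: so the half-corridor obstacle genuinely blocks the midline path
OBSTACLE_MARGIN = 0.15


def in_maze(p) -> bool:
    return STEM.contains(p, 1e-9) or TOP.contains(p, 1e-9)


@dataclass(frozen=True)
class ObstacleSpec:
    """Obstacle rectangle hanging from the top wall: depth half the corridor
    width, side length 0.5, placed outside the goal areas."""

    rect: Rect

    def __post_init__(self) -> None:
        r = self.rect
        if not (r.y1 == 3.0 and abs((r.y1 - r.y0) - 0.5) < 1e-9):
            raise ValueError("obstacle must hang 0.5 deep from the top wall")
        if r.x0 < ZONE_LEFT.x1 or r.x1 > ZONE_RIGHT.x0:
            raise ValueError("obstacle overlaps a goal area")


_OBSTACLE_SIDE = 0.5
_OBSTACLE_SPAN = (ZONE_LEFT.x1, ZONE_RIGHT.x0 - _OBSTACLE_SIDE)  # left-edge span


def place_obstacle(rng: np.random.Generator) -> ObstacleSpec:
    """Uniform draw of the obstacle's left edge along the admissible span."""
    x0 = float(rng.uniform(*_OBSTACLE_SPAN))
    return ObstacleSpec(Rect(x0, 2.5, x0 + _OBSTACLE_SIDE, 3.0))


@dataclass(frozen=True)
class ContinuousMazeSpec:
    """Simulation constants for one continuous experiment."""

    dt: float
    horizon: int
    max_speed: float                  # units per unit time
    rgb_colors: bool = False          # one-hot (Exp 2) vs RGB (Exp 3)
    with_ranges: bool = False
    sensor_range: float = 0.7
    noise_moving: float = 0.01
    noise_stationary: float = 0.005
    gain: float = 1.0                 # proportional-controller gain
    slow_factor: float = 0.7          # data-collection slow-down near obstacle
    slow_radius: float = 0.45

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def obs_dim(self) -> int:
        return 2 + (3 if self.rgb_colors else 4) + (4 if self.with_ranges else 0)

    @property
    def goal_dim(self) -> int:
        return 3 if self.rgb_colors else 4

    @property
    def step_length(self) -> float:
        return self.max_speed * self.dt


EXP2_SPEC = ContinuousMazeSpec(dt=0.5, horizon=25, max_speed=0.4)
EXP3_SPEC = ContinuousMazeSpec(dt=0.2, horizon=60, max_speed=0.55,
                               rgb_colors=True, with_ranges=True)


def floor_color(p, goal_side: str) -> str:
    """Floor color name at a pose; the CS is blue when the goal is left."""
    if ZONE_CS.contains(p, 1e-9):
        return "blue" if goal_side == "left" else "green"
    if ZONE_LEFT.contains(p, 1e-9):
        return "red" if goal_side == "left" else "white"
    if ZONE_RIGHT.contains(p, 1e-9):
        return "red" if goal_side == "right" else "white"
    return "white"


def color_vec(name: str, rgb: bool) -> np.ndarray:
    return np.array(_RGB[name]) if rgb else np.eye(4)[_COLOR_IDX[name]]


def _ray_hit(p, direction, segs) -> float:
    """Distance along a ray to the nearest axis-aligned segment."""
    px, py = p
    dx, dy = direction
    best = np.inf
    for (ax, ay), (bx, by) in segs:
        if ax == bx:  # vertical segment
            if dx == 0:
                continue
            t = (ax - px) / dx
            if t <= 1e-12:
                continue
            y = py + t * dy
            if min(ay, by) - 1e-12 <= y <= max(ay, by) + 1e-12:
                best = min(best, t)
        else:  # horizontal
            if dy == 0:
                continue
            t = (ay - py) / dy
            if t <= 1e-12:
                continue
            x = px + t * dx
            if min(ax, bx) - 1e-12 <= x <= max(ax, bx) + 1e-12:
                best = min(best, t)
    return best


_DIAG = np.array([[1, 1], [-1, 1], [-1, -1], [1, -1]]) / np.sqrt(2)


def range_sense(p, obstacle: ObstacleSpec | None = None,
                max_range: float = 0.7) -> np.ndarray:
    """Four ray-cast readings at 45 degrees to the cardinal directions
    (NE, NW, SW, SE), to the nearest wall or obstacle, clipped at
    ``max_range``."""
    segs = list(_WALLS)
    if obstacle is not None:
        r = obstacle.rect
        segs += [((r.x0, r.y0), (r.x1, r.y0)), ((r.x0, r.y1), (r.x1, r.y1)),
                 ((r.x0, r.y0), (r.x0, r.y1)), ((r.x1, r.y0), (r.x1, r.y1))]
    return np.array([min(_ray_hit(p, d, segs), max_range) for d in _DIAG])


def _valid(p, obstacle: ObstacleSpec | None) -> bool:
    if not in_maze(p):
        return False
    if obstacle is not None and obstacle.rect.contains(p, OBSTACLE_MARGIN):
        return False
    return True


def _slide(p, disp, obstacle: ObstacleSpec | None) -> np.ndarray:
    """Apply a displacement with impenetrable walls/obstacle: if the full
    move is blocked, slide along the free axis; otherwise stay."""
    cand = p + disp
    if _valid(cand, obstacle):
        return cand
    for trial in ((cand[0], p[1]), (p[0], cand[1])):
        if _valid(np.array(trial), obstacle):
            return np.array(trial)
    return p.copy()


def continuous_step(pose: np.ndarray, target: np.ndarray,
                    spec: ContinuousMazeSpec, rng: np.random.Generator,
                    obstacle: ObstacleSpec | None = None,
                    speed_factor: float = 1.0) -> np.ndarray:
    """One proportional-controller step toward ``target`` with Gaussian pose
    noise (sigma 0.01 moving / 0.005 stationary) and wall clipping."""
    target = np.asarray(target, dtype=float)
    if not np.all(np.isfinite(target)):
        raise ValueError("target must be finite")
    step = spec.gain * (target - pose)
    lim = spec.step_length * speed_factor
    norm = float(np.hypot(*step))
    if norm > lim:
        step = step * (lim / norm)
    moving = norm > 1e-6
    sigma = spec.noise_moving if moving else spec.noise_stationary
    disp = step + rng.normal(0.0, sigma, size=2)
    return _slide(pose, disp, obstacle)


# ---------------------------------------------------------------------------
# training-trajectory generation
# ---------------------------------------------------------------------------

def route_waypoints(arm: str, via_cs: bool,
                    obstacle: ObstacleSpec | None) -> list[np.ndarray]:
    """Waypoint chain from the start pose to the center of ``arm``'s colored
    zone, optionally via the CS zone, detouring under the obstacle."""
    goal = ZONE_CENTERS[arm]
    wps: list[np.ndarray] = []
    if via_cs:
        wps.append(ZONE_CENTERS["cs"].copy())
    under_y = 3.0 - _OBSTACLE_SIDE - OBSTACLE_MARGIN - 0.1  # passing height
    margin = OBSTACLE_MARGIN + 0.1
    entry_y = 2.5
    if obstacle is not None and obstacle.rect.x0 - margin < 1.5 < obstacle.rect.x1 + margin:
        entry_y = under_y
    wps.append(np.array([1.5, entry_y]))
    if obstacle is not None:
        ox0, ox1 = obstacle.rect.x0 - margin, obstacle.rect.x1 + margin
        lo, hi = min(1.5, goal[0]), max(1.5, goal[0])
        if ox0 < hi and ox1 > lo:  # obstacle sits on the traverse
            near, far = (ox1, ox0) if goal[0] < 1.5 else (ox0, ox1)
            wps.append(np.array([near, under_y]))
            wps.append(np.array([far, under_y]))
    wps.append(goal.copy())
    return wps


def collect_trajectory(spec: ContinuousMazeSpec, goal_side: str, arm: str,
                       via_cs: bool, obstacle: ObstacleSpec | None,
                       rng: np.random.Generator) -> np.ndarray:
    """Drive the waypoint-following data-collection controller for
    ``spec.horizon`` steps and record the observation track (T, Dx)."""
    pose = START.copy()
    wps = route_waypoints(arm, via_cs, obstacle)
    wp_i = 0
    rows = []
    for _ in range(spec.horizon):
        rows.append(_continuous_obs(pose, goal_side, spec, obstacle))
        target = wps[wp_i]
        if np.hypot(*(target - pose)) < 0.08 and wp_i < len(wps) - 1:
            wp_i += 1
            target = wps[wp_i]
        factor = 1.0
        if obstacle is not None and obstacle.rect.distance(pose) < spec.slow_radius:
            factor = spec.slow_factor
        pose = continuous_step(pose, target, spec, rng, obstacle, factor)
    return np.stack(rows)


def _continuous_obs(pose, goal_side, spec: ContinuousMazeSpec,
                    obstacle) -> np.ndarray:
    col = color_vec(floor_color(pose, goal_side), spec.rgb_colors)
    parts = [pose, col]
    if spec.with_ranges:
        parts.append(range_sense(pose, obstacle, spec.sensor_range))
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """A training set plus its provenance metadata (experiment id, seed,
    per-sequence context descriptions, column names)."""

    batch: SequenceBatch
    meta: dict = field(default_factory=dict)


_EXP_SHAPES = {1: (20, 3, 10), 2: (80, 25, 10), 3: (64, 60, 12)}


def make_training_set(experiment: int, seed: int = 0) -> Dataset:
    """Generate the canonical training set for an experiment.

    Exp 1: every canonical policy under both CS contexts (20 x 3 x 10).
    Exp 2: 4 behaviours x 2 goal sides x 10 noisy repetitions (80 x 25 x 10).
    Exp 3: 8 patterns x (4 runs with a random obstacle + 4 without)
    (64 x 60 x 12).
    """
    rng = np.random.default_rng(np.random.SeedSequence([experiment, seed]))
    if experiment == 1:
        seqs, ctxs = [], []
        for cs in ("blue", "green"):
            ctx = DiscreteMazeContext(cs)
            for pol in enumerate_policies():
                seqs.append(make_discrete_sequence(pol, ctx))
                ctxs.append({"cs": cs, "policy": list(pol.states)})
        obs = np.stack(seqs)
        batch = SequenceBatch(obs[:, :, :8], obs[:, :, 8:])
        columns = ([f"pos{i}" for i in range(1, 5)]
                   + [f"color_{c}" for c in COLOR_NAMES]
                   + ["goal_not_reached", "goal_reached"])
    elif experiment in (2, 3):
        spec = EXP2_SPEC if experiment == 2 else EXP3_SPEC
        seqs, ctxs = [], []
        for goal_side in ("left", "right"):
            for via_cs in (False, True):
                for correct in (True, False):
                    arm = goal_side if correct else _other(goal_side)
                    reps = 10 if experiment == 2 else 8
                    for rep in range(reps):
                        obstacle = None
                        if experiment == 3 and rep < 4:
                            obstacle = place_obstacle(rng)
                        x = collect_trajectory(spec, goal_side, arm, via_cs,
                                               obstacle, rng)
                        g = color_vec("red" if correct else "white",
                                      spec.rgb_colors)
                        seqs.append(np.concatenate(
                            [x, np.tile(g, (spec.horizon, 1))], axis=1))
                        ctxs.append({"goal_side": goal_side, "arm": arm,
                                     "via_cs": via_cs,
                                     "obstacle": None if obstacle is None
                                     else obstacle.rect.x0})
        obs = np.stack(seqs)
        dx = spec.obs_dim
        batch = SequenceBatch(obs[:, :, :dx], obs[:, :, dx:])
        color_cols = (["r", "g", "b"] if spec.rgb_colors
                      else [f"color_{c}" for c in COLOR_NAMES])
        columns = ["x", "y"] + color_cols
        if spec.with_ranges:
            columns += [f"range{i}" for i in range(4)]
        columns += [f"goal_{c}" for c in
                    (["r", "g", "b"] if spec.rgb_colors
                     else COLOR_NAMES)]
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    shape = (batch.obs.shape[0], batch.obs.shape[1],
             batch.obs.shape[2] + batch.goal.shape[2])
    assert shape == _EXP_SHAPES[experiment], shape
    meta = {"experiment": experiment, "seed": seed, "columns": columns,
            "contexts": ctxs,
            "note": "goal side in {left,right}; CS blue <=> goal left"}
    return Dataset(batch, meta)


def _other(side: str) -> str:
    return "right" if side == "left" else "left"


def save_dataset(ds: Dataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arr = np.concatenate([ds.batch.obs, ds.batch.goal], axis=-1)
    B, T, D = arr.shape
    rows = np.column_stack([
        np.repeat(np.arange(B), T), np.tile(np.arange(T), B),
        arr.reshape(B * T, D)])
    header = "sequence,t," + ",".join(ds.meta["columns"])
    np.savetxt(out / "data.csv", rows, delimiter=",", header=header,
               comments="", fmt="%.10g")
    with open(out / "meta.yaml", "w") as fh:
        yaml.safe_dump(ds.meta, fh)


def load_dataset(in_dir) -> Dataset:
    src = Path(in_dir)
    with open(src / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    rows = np.loadtxt(src / "data.csv", delimiter=",", skiprows=1)
    B = int(rows[:, 0].max()) + 1
    T = int(rows[:, 1].max()) + 1
    arr = rows[:, 2:].reshape(B, T, -1)
    dx = arr.shape[2] - (4 if meta["experiment"] in (1, 2) else 3)
    if meta["experiment"] == 1:
        dx = 8
    return Dataset(SequenceBatch(arr[:, :, :dx], arr[:, :, dx:]), meta)


# ---------------------------------------------------------------------------
# trial-time environment frontends (batched over trials)
# ---------------------------------------------------------------------------

class DiscreteTMaze:
    """Batched discrete maze: per-trial hidden CS context, absorbing
    terminal arms, illegal moves kept in place and counted as faults."""

    horizon = 3
    obs_dim, goal_dim, proprio_dim = 8, 2, 4

    def __init__(self, rngs: list[np.random.Generator]):
        self.contexts = [DiscreteMazeContext(
            "blue" if rng.random() < 0.5 else "green") for rng in rngs]
        self.states = np.ones(len(rngs), dtype=int)
        self.faults = np.zeros(len(rngs), dtype=int)
        self.state_log: list[np.ndarray] = [self.states.copy()]

    def reset_observation(self) -> np.ndarray:
        return self.observe()

    def act(self, target_states: np.ndarray) -> np.ndarray:
        """Apply one decoded move per trial; returns the (Dx) observations."""
        new = np.array([discrete_transition(int(s), int(t))
                        for s, t in zip(self.states, target_states)])
        self.faults += (new != target_states).astype(int)
        self.states = new
        self.state_log.append(new.copy())
        return self.observe()

    def observe(self) -> np.ndarray:
        return np.stack([discrete_observe(int(s), c)[:self.obs_dim]
                         for s, c in zip(self.states, self.contexts)])

    def outcomes(self) -> dict:
        seqs = np.stack(self.state_log, axis=1)  # (B, steps incl. start)
        reached = np.array([c.goal_state for c in self.contexts])
        return {
            "state_sequences": seqs,
            "cs_visited": (seqs == 2).any(axis=1),
            "success": seqs[:, -1] == reached,
            "faults": self.faults.copy(),
        }


class ContinuousTMaze:
    """Batched continuous maze with optional obstacle; the first observation
    (the start pose) is produced by :meth:`reset_observation`."""

    def __init__(self, spec: ContinuousMazeSpec,
                 rngs: list[np.random.Generator], with_obstacle: bool = False):
        self.spec = spec
        self.rngs = rngs
        B = len(rngs)
        self.goal_sides = ["left" if rng.random() < 0.5 else "right"
                           for rng in rngs]
        self.obstacles: list[ObstacleSpec | None] = [
            place_obstacle(rng) if with_obstacle else None for rng in rngs]
        self.poses = np.tile(START, (B, 1))
        self.pose_log: list[np.ndarray] = [self.poses.copy()]

    @property
    def horizon(self) -> int:
        return self.spec.horizon

    @property
    def obs_dim(self) -> int:
        return self.spec.obs_dim

    @property
    def goal_dim(self) -> int:
        return self.spec.goal_dim

    proprio_dim = 2

    def reset_observation(self) -> np.ndarray:
        return self.observe()

    def observe(self) -> np.ndarray:
        return np.stack([
            _continuous_obs(p, side, self.spec, obst)
            for p, side, obst in zip(self.poses, self.goal_sides,
                                     self.obstacles)])

    def act(self, targets: np.ndarray) -> np.ndarray:
        self.poses = np.stack([
            continuous_step(p, t, self.spec, rng, obst)
            for p, t, rng, obst in zip(self.poses, targets, self.rngs,
                                       self.obstacles)])
        self.pose_log.append(self.poses.copy())
        return self.observe()

    def outcomes(self) -> dict:
        track = np.stack(self.pose_log, axis=1)  # (B, steps+1, 2)
        cs = np.array([any(ZONE_CS.contains(p) for p in tr)
                       for tr in track])
        succ = []
        for p, side in zip(self.poses, self.goal_sides):
            zone = ZONE_LEFT if side == "left" else ZONE_RIGHT
            succ.append(zone.contains(p))
        return {"pose_track": track, "cs_visited": cs,
                "success": np.array(succ)}
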