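"""Kinematic point agent: replay-based planning and discrete-heading motion.

The agent replaces a biomechanical body with the simplest locomotion model
that preserves the control scheme: it moves at constant speed along one of
8 compass headings (multiples of 45 deg), stopping at walls.  Navigation
alternates a 1-s planning period (awake replay, segmented into look-ahead
sub-trajectories, softmax choice over their maximal MSN activity) with a
2-s movement period, until the goal region is entered or time runs out.

The softmax decision rule over K sub-trajectories is

    P(n_k) = exp(beta * max_t V) / sum_i exp(beta * max_t V),

where ``beta`` sets the greediness (0 = uniform) and the max runs over the
MSN activity during each sub-trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax

from .attractor_network import CANParams
from .maze_geometry import MazeLayout, MazeSpecError
from .place_code import PlacePopulation
from .replay_engine import SubTrajectory, awake_replay, segment_subtrajectories

__all__ = [
    "HEADINGS", "AgentState", "DecisionPolicy", "NavigationModel",
    "TrialResult", "direction_probabilities", "select_heading",
    "snap_to_heading", "move", "in_goal_region", "run_test_trial",
    "exploration_trial",
]

#: Unit vectors of the 8 compass headings, index k at angle 45*k degrees
#: counter-clockwise from east.
_SQ = math.sqrt(0.5)
HEADINGS = np.array([
    (1.0, 0.0), (_SQ, _SQ), (0.0, 1.0), (-_SQ, _SQ),
    (-1.0, 0.0), (-_SQ, -_SQ), (0.0, -1.0), (_SQ, -_SQ),
])


@dataclass
class AgentState:
    """Kinematic state: position (m), compass heading index, speed (m/s)."""

    position: tuple[float, float]
    heading: int = 0
    speed: float = 0.5


@dataclass(frozen=True)
class DecisionPolicy:
    """Planning and movement constants of the navigation loop."""

    beta: float = 10.0          # softmax greediness
    d: float = 0.5              # planning-disc radius (m)
    plan_duration: float = 1.0  # awake-replay period (s)
    move_duration: float = 2.0  # movement period (s)
    A_awake: float = 50.0       # awake-replay input amplitude
    speed: float = 0.5          # locomotion speed (m/s)
    goal_radius: float = 0.5    # goal-region radius (m)
    goal_shape: str = "disc"    # "disc" | "square"
    lookahead: float | None = 2.0  # path-length budget for excursion scores (m)
    plan_event_duration: float | None = 0.1  # s per awake look-ahead probe
    #: Penalty (in softmax score units) per half-turn of heading change.
    #: The body the agent stands in for turns slowly, so among options of
    #: similar value it prefers to keep running straight; a decisive value
    #: difference still dominates.  0 disables the prior.
    turn_cost: float = 2.0

    def __post_init__(self) -> None:
        if self.beta < 0 or self.d <= 0:
            raise ValueError("require beta >= 0 and d > 0")
        if self.goal_shape not in ("disc", "square"):
            raise ValueError("goal_shape must be 'disc' or 'square'")


@dataclass
class NavigationModel:
    """Learned quantities needed to navigate: place code, coupling, values."""

    pop: PlacePopulation
    coupling: np.ndarray        # effective recurrent coupling (M, M)
    msn_weights: np.ndarray     # W (M,)
    can_params: CANParams
    replay_stride: float = 0.01


@dataclass
class TrialResult:
    success: bool
    time_to_goal: float         # s (NaN for failures)
    trajectory: list[tuple[float, float, float, str]]  # (t, x, y, event)
    n_plans: int = 0
    n_fallbacks: int = 0        # planning periods with no sub-trajectory
    path: np.ndarray | None = None  # dense (N, 2) positions for audits


def direction_probabilities(segments: list[SubTrajectory], beta: float,
                            ) -> np.ndarray:
    """Softmax over ``beta * msn_max``; probabilities sum to one."""
    if not segments:
        raise ValueError("no sub-trajectories to choose from")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    scores = np.array([s.msn_max for s in segments], dtype=float)
    if np.isnan(scores).any():
        raise ValueError("sub-trajectories carry no MSN activity (msn_max is NaN)")
    return softmax(beta * scores)


def _turn_fraction(direction: np.ndarray, heading: int) -> float:
    """Angle between a direction and a compass heading, as fraction of pi."""
    theta = math.atan2(direction[1], direction[0]) - heading * math.pi / 4.0
    theta = (theta + math.pi) % (2 * math.pi) - math.pi
    return abs(theta) / math.pi


def snap_to_heading(direction: np.ndarray) -> int:
    """Nearest of the 8 compass headings; exact ties snap counter-clockwise."""
    theta = math.degrees(math.atan2(direction[1], direction[0])) % 360.0
    return int(math.floor(theta / 45.0 + 0.5)) % 8


def select_heading(probs: np.ndarray, segments: list[SubTrajectory],
                   rng: np.random.Generator) -> int:
    """Sample a sub-trajectory and snap its direction to a compass heading."""
    k = int(rng.choice(len(segments), p=probs))
    return snap_to_heading(segments[k].direction)


def _free_mask(layout: MazeLayout) -> np.ndarray:
    mask = np.ones((layout.n_rows, layout.n_cols), dtype=bool)
    for (r, c) in layout.blocked:
        mask[r, c] = False
    return mask


def move(position: tuple[float, float], heading: int, duration: float,
         layout: MazeLayout, speed: float = 0.5, dt: float = 0.001,
         ) -> np.ndarray:
    """Advance along a compass heading with wall collision.

    The motion is integrated in sub-steps of ``speed * dt`` metres; the
    first sub-step that would enter a blocked cell (or, on a diagonal,
    cut the corner between two cells) is cancelled and the agent stays
    put for the remainder of the period.  Returns the ``(N+1, 2)`` array
    of sub-step positions including the start; the last row is the final
    position, never inside a blocked cell.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    u = HEADINGS[heading % 8]
    n = int(round(duration / dt))
    steps = speed * dt * np.arange(0, n + 1)
    pts = np.asarray(position, dtype=float) + steps[:, None] * u
    eps = 1e-9
    inside = ((pts[:, 0] >= 0) & (pts[:, 0] <= layout.width - eps)
              & (pts[:, 1] >= 0) & (pts[:, 1] <= layout.height - eps))
    cols = np.clip((pts[:, 0] / layout.spacing).astype(int), 0, layout.n_cols - 1)
    rows = np.clip((pts[:, 1] / layout.spacing).astype(int), 0, layout.n_rows - 1)
    mask = _free_mask(layout)
    ok = inside & mask[rows, cols]
    if u[0] != 0 and u[1] != 0:
        # no corner-cutting: both axis-adjacent cells of a diagonal cell
        # change must be free
        prev_r, prev_c = rows[:-1], cols[:-1]
        diag = (rows[1:] != prev_r) & (cols[1:] != prev_c)
        corner_ok = mask[prev_r, cols[1:]] & mask[rows[1:], prev_c]
        ok[1:] &= ~diag | corner_ok
    bad = np.flatnonzero(~ok)
    stop = bad[0] if bad.size else n + 1
    return pts[:stop]


def in_goal_region(pos: tuple[float, float], goal: tuple[float, float],
                   radius: float = 0.5, shape: str = "disc") -> bool:
    """Goal test: disc of given radius (default), or the enclosing square."""
    dx = pos[0] - goal[0]
    dy = pos[1] - goal[1]
    if shape == "square":
        return max(abs(dx), abs(dy)) <= radius
    return math.hypot(dx, dy) <= radius


def run_test_trial(start: tuple[float, float], policy: DecisionPolicy,
                   model: NavigationModel, layout: MazeLayout,
                   max_duration: float = 120.0,
                   rng: np.random.Generator | None = None,
                   keep_path: bool = False) -> TrialResult:
    """One goal-directed trial: alternate planning and movement periods.

    Success means entering the goal region before ``max_duration`` elapses;
    planning periods consume trial time.  All stochasticity (the softmax
    sample and the fallback heading when a planning period yields no
    sub-trajectory) flows from ``rng``.
    """
    rng = np.random.default_rng() if rng is None else rng
    if not layout.is_free(layout.cell_of(start)):
        raise MazeSpecError(f"trial start {start!r} lies on a blocked cell")
    goal = layout.goal
    pos = (float(start[0]), float(start[1]))
    t = 0.0
    traj: list[tuple[float, float, float, str]] = [(t, *pos, "start")]
    dense: list[np.ndarray] = [np.array([pos])]
    n_plans = n_fallbacks = 0
    if in_goal_region(pos, goal, policy.goal_radius, policy.goal_shape):
        return TrialResult(True, 0.0, traj, 0, 0,
                           np.vstack(dense) if keep_path else None)
    success, t_goal = False, math.nan
    heading = int(rng.integers(8))
    collided = False

    def _clear(h: int, frm: tuple[float, float]) -> bool:
        """Whether the agent can advance at least ~0.3 m along heading h."""
        path = move(frm, h, 0.8, layout, speed=policy.speed)
        return len(path) > 1 and np.linalg.norm(path[-1] - path[0]) >= 0.3

    while t < max_duration and not success:
        # -- planning period ---------------------------------------------
        trace = awake_replay(model.coupling, model.pop, pos,
                             policy.plan_duration, policy.A_awake,
                             model.can_params, stride=model.replay_stride,
                             event_duration=policy.plan_event_duration)
        segments = segment_subtrajectories(trace, pos, policy.d,
                                           msn_weights=model.msn_weights,
                                           lookahead=policy.lookahead)
        n_plans += 1
        # a direction is only a real option if the body can move along it:
        # discard look-aheads whose snapped heading is walled off
        if segments:
            segments = [s for s in segments
                        if _clear(snap_to_heading(s.direction), pos)]
        if segments:
            if policy.turn_cost and not collided:
                # straight-run prior; suspended after a collision, where the
                # current heading points into a wall
                scores = np.array([policy.beta * s.msn_max
                                   - policy.turn_cost
                                   * _turn_fraction(s.direction, heading)
                                   for s in segments])
                from scipy.special import softmax as _softmax
                probs = _softmax(scores)
            else:
                probs = direction_probabilities(segments, policy.beta)
            heading = select_heading(probs, segments, rng)
            traj.append((t, *pos, "plan"))
        else:
            # no usable look-ahead: keep running if the way is clear,
            # otherwise re-orient uniformly among clear headings
            if collided or not _clear(heading, pos):
                options = [h for h in range(8) if _clear(h, pos)]
                if options:
                    heading = int(options[rng.integers(len(options))])
            n_fallbacks += 1
            traj.append((t, *pos, "plan_fallback"))
        t += policy.plan_duration
        if t >= max_duration:
            break
        # -- movement period ---------------------------------------------
        move_time = min(policy.move_duration, max_duration - t)
        path = move(pos, heading, move_time, layout, speed=policy.speed)
        if keep_path:
            dense.append(path[:: max(1, len(path) // 200)])
        gx, gy = goal
        inside = None
        if policy.goal_shape == "disc":
            d2 = (path[:, 0] - gx) ** 2 + (path[:, 1] - gy) ** 2
            hits = np.flatnonzero(d2 <= policy.goal_radius ** 2)
        else:
            cheb = np.maximum(np.abs(path[:, 0] - gx), np.abs(path[:, 1] - gy))
            hits = np.flatnonzero(cheb <= policy.goal_radius)
        if hits.size:
            inside = int(hits[0])
        if inside is not None:
            t_goal = t + inside * 0.001
            pos = (float(path[inside, 0]), float(path[inside, 1]))
            traj.append((t_goal, *pos, "goal"))
            success = True
            break
        collided = len(path) < int(round(move_time / 0.001)) + 1
        pos = (float(path[-1, 0]), float(path[-1, 1]))
        t += move_time
        traj.append((t, *pos, "collide" if collided else "move"))
    return TrialResult(success, t_goal, traj, n_plans, n_fallbacks,
                       np.vstack(dense) if keep_path else None)


def exploration_trial(layout: MazeLayout, duration: float,
                      rng: np.random.Generator, speed: float = 0.5,
                      turn_period: float = 3.0, record_dt: float = 0.02,
                      start: tuple[float, float] | None = None) -> np.ndarray:
    """Random-walk exploration: uniform compass heading every turn period.

    A collision re-orients the walk immediately (the animal turns away from
    a wall rather than pressing into it), so the full trial duration is
    spent covering the maze.  Returns the ``(N, 2)`` array of positions
    sampled every ``record_dt`` seconds -- the inputs of the Hebbian
    inter-PC learning.
    """
    free = layout.free_cells()
    if start is None:
        cell = free[int(rng.integers(len(free)))]
        start = layout.cell_center(cell)
    pos = np.asarray(start, dtype=float)
    sub_dt = 0.001
    stride = max(1, int(round(record_dt / sub_dt)))
    path_all: list[np.ndarray] = [pos[None, :]]
    n_total = int(round(duration / sub_dt))
    walked = 0
    t_next_turn = 0
    heading = int(rng.integers(8))
    while walked < n_total:
        if walked >= t_next_turn:
            heading = int(rng.integers(8))
            t_next_turn = walked + int(round(turn_period / sub_dt))
        seg_steps = min(t_next_turn, n_total) - walked
        path = move(tuple(pos), heading, seg_steps * sub_dt, layout,
                    speed=speed, dt=sub_dt)
        if len(path) > 1:
            path_all.append(path[1:])
            pos = path[-1]
            walked += len(path) - 1
        if len(path) < seg_steps + 1:      # hit a wall: re-orient now
            options = [h for h in range(8)
                       if len(move(tuple(pos), h, 5 * sub_dt, layout,
                                   speed=speed, dt=sub_dt)) > 5]
            if options:
                heading = int(options[rng.integers(len(options))])
                t_next_turn = walked + int(round(turn_period / sub_dt))
            else:           # boxed in (should not happen): burn one step
                path_all.append(pos[None, :])
                walked += 1
    dense = np.vstack(path_all)
    return dense[stride::stride]
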