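"""Generation and segmentation of replay trajectories.

Rest replay: the network is kicked by a brief transient input at the goal
and then runs with no input; the activity bump wanders along maze paths,
re-visiting the environment (the substrate of off-line learning).  If the
bump dies out it is re-ignited by re-applying the goal transient; a trace
that spends long dead is flagged as degenerate.

Awake replay: a persistent input of intermediate amplitude anchors the bump
at the animal's location; feedback inhibition periodically drives it out on
a look-ahead excursion before it jumps back.  Each excursion outside a disc
of radius ``d`` around the animal is one *sub-trajectory* with an initial
direction -- the candidate movement directions used for planning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attractor_network import CANParams, NetworkState, RunTrace, run
from .maze_geometry import MazeLayout
from .place_code import PlacePopulation

__all__ = ["ReplayTrace", "SubTrajectory", "rest_replay", "awake_replay",
           "segment_subtrajectories", "segments_to_records", "node_coverage",
           "DEAD_TOLERANCE"]

#: Total rate below which the bump counts as dead (numerical floor).
DEAD_TOLERANCE = 1e-6


@dataclass
class ReplayTrace:
    """Bump trajectory sampled at a fixed stride.

    ``positions`` holds the population vector of the sampled rate vectors;
    rows are NaN where the bump was dead.
    """

    times: np.ndarray       # (S,)
    positions: np.ndarray   # (S, 2), NaN when the bump is dead
    rates: np.ndarray       # (S, M) sampled rate vectors
    regime: str             # "rest" | "awake"
    warnings: list[str] = field(default_factory=list)
    final: NetworkState | None = None

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def save(self, path) -> None:
        """Write times, positions and sampled rates to an NPZ bundle."""
        np.savez(path, times=self.times, positions=self.positions,
                 rates=self.rates, regime=np.array(self.regime),
                 warnings=np.array(self.warnings, dtype=object))


#: Geodesic radius (m) of the dominant-bump decoder used for trace positions.
DECODE_RADIUS = 1.0


def _positions_from_rates(rates: np.ndarray, pop: PlacePopulation) -> np.ndarray:
    """Dominant-bump positions for a stack of rate vectors (NaN when dead).

    Activity is restricted to the geodesic neighbourhood of the most active
    cell before the activity-weighted mean is taken, so the decoded point
    tracks the strongest bump rather than the centroid of coexisting bumps
    (see :meth:`PlacePopulation.local_population_vector`).
    """
    S = rates.shape[0]
    out = np.full((S, 2), np.nan)
    alive = rates.sum(axis=1) > DEAD_TOLERANCE
    if not alive.any():
        return out
    km = rates.argmax(axis=1)
    cells = np.asarray(pop.center_cells)
    kr, kc = cells[km, 0], cells[km, 1]
    near = pop.cell_dist[:, kr, kc].T <= DECODE_RADIUS   # (S, M)
    local = np.where(near, rates, 0.0)
    totals = local.sum(axis=1)
    alive &= totals > 0
    out[alive] = (local[alive] @ pop.centers) / totals[alive, None]
    return out


class _TransientReseeder:
    """Input schedule: goal transient at t=0, re-applied when the bump dies."""

    def __init__(self, E_goal: np.ndarray, transient: float, reseed: bool):
        self.E_goal = E_goal
        self.zero = np.zeros_like(E_goal)
        self.transient = transient
        self.reseed = reseed
        self.on_until = transient
        self.reseed_count = 0
        self.dead_steps = 0

    def __call__(self, t: float) -> np.ndarray:
        return self.E_goal if t < self.on_until else self.zero

    def observe(self, t: float, r: np.ndarray) -> None:
        if r.sum() < DEAD_TOLERANCE:
            self.dead_steps += 1
            if self.reseed and t >= self.on_until:
                self.on_until = t + self.transient
                self.reseed_count += 1


def rest_replay(coupling: np.ndarray, pop: PlacePopulation,
                goal: tuple[float, float], duration: float, params: CANParams,
                amplitude: float = 10.0, transient: float = 0.01,
                stride: float = 0.01, reseed_on_death: bool = True,
                event_duration: float | None = 2.0,
                callback=None) -> ReplayTrace:
    """Rest replay: a train of goal-ignited replay events with no input.

    Every ``event_duration`` seconds (and whenever the bump dies) the rates
    are cleared and the 10-ms goal transient is re-applied, starting a new
    replay event -- the analogue of discrete sharp-wave-ripple events during
    rest.  The slow feedback inhibition is *not* cleared between events, so
    each event is steered away from recently replayed paths and the event
    train progressively covers the maze.  ``event_duration=None`` runs one
    single uninterrupted event.

    ``callback(step_index, r, I)`` piggy-backs per-step computations (the
    striatal learning rule) on the integration; if it exposes
    ``reset_trace()`` it is told when a new event begins.
    """
    if duration <= 0:
        return ReplayTrace(np.empty(0), np.empty((0, 2)), np.empty((0, pop.n_cells)),
                           "rest", warnings=["empty: zero duration requested"])
    M = pop.n_cells
    schedule = _TransientReseeder(pop.external_input(goal, amplitude),
                                  transient, reseed_on_death)
    reset_trace = getattr(callback, "reset_trace", None)
    if event_duration is None:
        cycle = None
    else:
        durations = (event_duration if np.iterable(event_duration)
                     else [event_duration])
        cycle = [max(1, int(round(d / params.dt))) for d in durations]

    parts: list[RunTrace] = []
    state = NetworkState.zeros(M)
    warnings: list[str] = []
    n_steps_total = int(round(duration / params.dt))
    done = 0
    n_events = 0
    while done < n_steps_total:
        chunk = (n_steps_total - done if cycle is None
                 else min(cycle[n_events % len(cycle)], n_steps_total - done))
        n_events += 1
        offset = done

        def _cb(k: int, r: np.ndarray, I: np.ndarray) -> None:
            before = schedule.reseed_count
            schedule.observe((offset + k) * params.dt, r)
            if schedule.reseed_count != before and reset_trace is not None:
                # a re-ignited bump is a fresh event: stale traces from the
                # death site must not be credited by the goal transient
                reset_trace()
            if callback is not None:
                callback(offset + k, r, I)

        schedule.on_until = offset * params.dt + transient  # ignite event
        part = run(state, coupling, schedule, chunk * params.dt, params,
                   record_stride=stride, callback=_cb)
        parts.append(part)
        done += chunk
        # next event: clear rates, keep inhibition
        state = NetworkState(np.zeros(M), part.final.I, part.final.t)
        if reset_trace is not None:
            reset_trace()

    times = np.concatenate([p.times[(1 if i else 0):] for i, p in enumerate(parts)])
    rates = np.vstack([p.rates[(1 if i else 0):] for i, p in enumerate(parts)])
    dead_time = schedule.dead_steps * params.dt
    # a healthy event train re-ignites a few times per second at most; a
    # network that cannot hold a bump at all reseeds at ~1/(transient+tau_r)
    if dead_time > 1.0 or schedule.reseed_count > 20.0 * max(1.0, duration):
        warnings.append(
            f"degenerate replay: bump dead for {dead_time:.2f} s, "
            f"{schedule.reseed_count} reseeds"
        )
    return ReplayTrace(times, _positions_from_rates(rates, pop),
                       rates, "rest", warnings, parts[-1].final)


def awake_replay(coupling: np.ndarray, pop: PlacePopulation,
                 x: tuple[float, float], duration: float, A: float,
                 params: CANParams, stride: float = 0.01,
                 event_duration: float | None = 0.25) -> ReplayTrace:
    """Replay under a persistent input of amplitude ``A`` centered at ``x``.

    The planning window is structured as a train of short look-ahead
    events: every ``event_duration`` seconds the rates are cleared (the
    persistent input re-ignites the bump at the animal within a few
    milliseconds) while the slow inhibition persists, so each probe
    escapes along a direction not taken by the previous ones and the
    window samples the explorable paths.  ``event_duration=None`` runs
    one uninterrupted event.
    """
    if A <= 0:
        raise ValueError("awake replay requires a positive input amplitude")
    if duration <= 0:
        return ReplayTrace(np.empty(0), np.empty((0, 2)), np.empty((0, pop.n_cells)),
                           "awake", warnings=["empty: zero duration requested"])
    M = pop.n_cells
    E = pop.external_input(x, A)
    n_steps_total = int(round(duration / params.dt))
    event_steps = (int(round(event_duration / params.dt))
                   if event_duration else None)
    parts: list[RunTrace] = []
    state = NetworkState.zeros(M)
    done = 0
    while done < n_steps_total:
        chunk = (n_steps_total - done if event_steps is None
                 else min(event_steps, n_steps_total - done))
        part = run(state, coupling, E, chunk * params.dt, params,
                   record_stride=stride)
        parts.append(part)
        done += chunk
        state = NetworkState(np.zeros(M), part.final.I, part.final.t)
    times = np.concatenate([p.times[(1 if i else 0):] for i, p in enumerate(parts)])
    rates = np.vstack([p.rates[(1 if i else 0):] for i, p in enumerate(parts)])
    positions = _positions_from_rates(rates, pop)
    warnings = []
    if np.isnan(positions[:, 0]).mean() > 0.5:
        warnings.append("degenerate replay: bump dead for most of the trace")
    return ReplayTrace(times, positions, rates, "awake",
                       warnings, parts[-1].final)


@dataclass
class SubTrajectory:
    """One look-ahead excursion outside the planning disc.

    ``t0``/``t1`` are the exit and re-entry times (re-entry clamped to the
    trace end for a trailing un-closed excursion), ``direction`` is the unit
    vector ``(p(t0) - x) / ||p(t0) - x||`` and ``msn_max`` the maximal MSN
    activity over the excursion samples (NaN when no weights were supplied).
    """

    t0: float
    t1: float
    direction: np.ndarray
    msn_max: float
    i0: int
    i1: int


def segment_subtrajectories(trace: ReplayTrace, x: tuple[float, float],
                            d: float = 0.5,
                            msn_weights: np.ndarray | None = None,
                            lookahead: float | None = 2.0,
                            ) -> list[SubTrajectory]:
    """Split a replay trace into excursions outside the radius-``d`` disc.

    Crossings are located at the sampled stride (first sample beyond /
    back inside the radius, no interpolation).  Samples with a dead bump
    (NaN position) count as inside.  A trailing excursion that never
    re-enters is kept, closed at the trace end.

    ``lookahead`` limits the MSN maximum to the excursion's first metres of
    path: a long excursion may curve far from its initial direction, and
    value found after the bend says nothing about the direction the animal
    would actually move in.  ``None`` scores the whole excursion.
    """
    if d <= 0:
        raise ValueError("planning radius d must be positive")
    if trace.n_samples < 2:
        return []
    x = np.asarray(x, dtype=float)
    dists = np.linalg.norm(trace.positions - x, axis=1)
    outside = dists >= d          # NaN -> False (inside)
    outside &= ~np.isnan(dists)
    V = None
    if msn_weights is not None:
        V = trace.rates @ np.asarray(msn_weights, dtype=float)
    segments: list[SubTrajectory] = []
    i = 0
    S = trace.n_samples
    while i < S:
        if not outside[i]:
            i += 1
            continue
        i0 = i
        while i < S and outside[i]:
            i += 1
        i1 = i if i < S else S - 1   # re-entry sample, or trace end
        vec = trace.positions[i0] - x
        norm = float(np.linalg.norm(vec))
        # the sub-trajectory is the open interval (t0, t1): the re-entry
        # sample (bump back at the animal) must not enter the maximum, or
        # every excursion would inherit the home value
        msn_max = float("nan")
        if V is not None:
            j1 = max(i1, i0 + 1)
            if lookahead is not None:
                seg_pos = trace.positions[i0:j1]
                steps = np.linalg.norm(np.diff(seg_pos, axis=0), axis=1)
                pathlen = np.concatenate([[0.0], np.nancumsum(steps)])
                within = np.flatnonzero(pathlen <= lookahead)
                j1 = i0 + (int(within[-1]) + 1 if within.size else 1)
            msn_max = float(np.max(V[i0:j1]))
        segments.append(SubTrajectory(
            t0=float(trace.times[i0]), t1=float(trace.times[i1]),
            direction=vec / norm, msn_max=msn_max, i0=i0, i1=i1,
        ))
    return segments


def segments_to_records(segments: list[SubTrajectory]) -> list[dict]:
    """Segment table rows (t0, t1, n_x, n_y, msn_max) for CSV export."""
    return [{"t0": s.t0, "t1": s.t1, "n_x": float(s.direction[0]),
             "n_y": float(s.direction[1]), "msn_max": s.msn_max}
            for s in segments]


def node_coverage(trace: ReplayTrace, layout: MazeLayout) -> float:
    """Fraction of free cells visited by the snapped sampled bump positions."""
    visited: set[tuple[int, int]] = set()
    for p in trace.positions:
        if np.isnan(p[0]):
            continue
        visited.add(layout.snap((float(p[0]), float(p[1]))))
    return len(visited) / len(layout.free_cells())
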