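"""End-to-end experiment protocols: goal-fixed, goal-changing, detour, shortcut.

Each experiment is a sequence of phases:

* **exploration** -- the agent random-walks the maze; the inter-PC matrix
  ``J`` relaxes toward the rate correlation (and, after a goal change, the
  PC-to-goal-cell weights ``U`` are re-learned by the reward-modulated rule).
* **rest replay** -- the attractor network replays the maze off-line while
  the three-factor rule writes the PC-MSN weights ``W``.
* **test** -- softmax-planned trials from a fixed start grid; the metrics
  are the success fraction and the normalized latency (time to goal divided
  by the geodesic start-goal distance) of successful trials.

The place population lives on the full grid so that cell identities (and
hence ``J``, ``W``, ``U``) persist across layout changes; cells buried
under walls are silent.  Before the learned ``J`` enters the network it is
rescaled to a fixed peak coupling strength (see
:func:`replaynav.plasticity_pc.scale_to_peak`) and shifted by the global
inhibition.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fixtures
from .attractor_network import CANParams
from .maze_geometry import MazeLayout, geodesic_distance
from .navigation_agent import (DecisionPolicy, NavigationModel,
                               exploration_trial, in_goal_region,
                               run_test_trial)
from .place_code import PlacePopulation
from .plasticity_pc import (adjacent_pairs, correlation_normalize,
                            effective_coupling, hebbian_update_batch,
                            scale_to_adjacent, scale_to_peak, zero_matrix)
from .replay_engine import rest_replay
from .striatal_learning import (ReplayLearner, StriatalParams, goal_weights,
                                update_goal_weights)

__all__ = [
    "ExperimentConfig", "ExperimentState", "Metrics",
    "run_goal_fixed", "run_goal_changing", "run_detour", "run_shortcut",
    "run_experiment", "parameter_sweep", "test_start_grid",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """All tunables of one experiment chain (defaults: desk scale)."""

    # place code / Hebbian learning
    sigma: float = 0.3          # place-field length scale (m)
    alpha1: float = 0.001       # inter-PC learning rate
    hebbian_period: float = 0.6  # s of samples averaged per Hebbian update
    # attractor coupling
    #: target median coupling strength of adjacent cell pairs after
    #: rescaling; sets the excitability of the attractor network
    coupling_gain: float = 1.4
    coupling_norm: str = "cosine"  # "cosine" (occupancy-debiased) | "raw"
    g_inh: float = -0.3         # global inhibition added to the coupling
    rest_event_duration: float = 2.0  # s per goal-ignited replay event
    can: CANParams = field(default_factory=CANParams)
    # striatal stage
    striatal: StriatalParams = field(default_factory=StriatalParams)
    #: MSN read-out gain for planning: W is scaled so the peak value over
    #: free nodes equals this before entering the softmax.  The learned W
    #: itself is untouched (its magnitude grows with alpha2*duration and is
    #: not meaningful on its own); the read-out scale sets where the
    #: direction choice sits between greedy and exploratory.
    value_scale: float = 0.06
    # phase schedule (desk scale)
    explore_trials: int = 20
    explore_duration: float = 60.0   # s per exploration trial
    turn_period: float = 3.0         # s between random heading changes
    record_dt: float = 0.02          # s between recorded positions
    rest_duration: float = 30.0      # s of rest replay (initial learning)
    relearn_rest_duration: float = 60.0  # s of rest replay after layout change
    #: s of rest replay after a goal change: overwriting a learned value map
    #: takes several times longer than learning it from scratch, because the
    #: stale peak must first be out-grown by the new one.
    goal_change_rest_duration: float = 120.0
    rest_amplitude: float = 10.0     # transient input amplitude
    transient: float = 0.01          # s of transient goal input
    test_trials: int = 25
    max_trial_duration: float = 120.0
    policy: DecisionPolicy = field(default_factory=DecisionPolicy)
    # variant flags
    simultaneous_updates: bool = False   # learn J and W in both phases
    unified_equation: bool = False       # CAN dynamics during exploration
    unified_amplitude: float = 80.0      # input amplitude for that variant
    seed: int = 0

    @classmethod
    def from_dict(cls, doc: dict) -> "ExperimentConfig":
        doc = dict(doc)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; "
                             f"valid keys: {sorted(known)}")
        if "can" in doc and isinstance(doc["can"], dict):
            doc["can"] = CANParams(**doc["can"])
        if "striatal" in doc and isinstance(doc["striatal"], dict):
            doc["striatal"] = StriatalParams(**doc["striatal"])
        if "policy" in doc and isinstance(doc["policy"], dict):
            doc["policy"] = DecisionPolicy(**doc["policy"])
        return cls(**doc)

    def replace(self, **kwargs) -> "ExperimentConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class ExperimentState:
    """Learned synaptic state carried between experiment phases."""

    layout: MazeLayout
    pop: PlacePopulation
    J: np.ndarray
    W: np.ndarray
    U: np.ndarray

    def coupling(self, cfg: ExperimentConfig) -> np.ndarray:
        J = self.J
        if cfg.coupling_norm == "cosine":
            J = correlation_normalize(J)
        pairs = adjacent_pairs(self.layout)
        return effective_coupling(scale_to_adjacent(J, pairs,
                                                    cfg.coupling_gain),
                                  cfg.g_inh)

    def navigation_model(self, cfg: ExperimentConfig) -> NavigationModel:
        W = self.W
        if cfg.value_scale and np.any(W):
            free = np.array(self.layout.free_cells())
            v_peak = float((self.pop.rates_at_cells(free) @ W).max())
            if v_peak > 0:
                W = W * (cfg.value_scale / v_peak)
        return NavigationModel(self.pop, self.coupling(cfg), W, cfg.can)

    def save(self, directory: str | Path) -> None:
        from .maze_geometry import layout_to_json
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "synapses.npz", J=self.J, W=self.W, U=self.U)
        (directory / "layout.json").write_text(layout_to_json(self.layout))


@dataclass
class Metrics:
    """Outcome of a test phase."""

    success_rate: float
    normalized_latency: float        # mean s/m over successful trials (NaN if none)
    trials: pd.DataFrame             # per-trial records
    warnings: list[str] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        self.trials.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# phases

def _seed_for(seed: int, label: str) -> np.random.Generator:
    # crc32 is stable across processes (str hash() is salted)
    ss = np.random.SeedSequence([seed, zlib.crc32(label.encode()) % (2**31)])
    return np.random.default_rng(ss)


def explore_phase(layout: MazeLayout, pop: PlacePopulation, J: np.ndarray,
                  cfg: ExperimentConfig, rng: np.random.Generator,
                  U: np.ndarray | None = None,
                  learner: "ReplayLearner | None" = None) -> np.ndarray:
    """Random-walk exploration with Hebbian updates of ``J``.

    Recorded positions are grouped into windows of ``hebbian_period``
    seconds; each window contributes one batch-averaged update.  If ``U``
    is given, the reward-modulated goal-weight rule runs at every recorded
    position (``U`` is updated in place).  If ``learner`` is given
    (simultaneous-updates variant), the three-factor MSN rule also runs on
    the exploration rates.
    """
    batch = max(1, int(round(cfg.hebbian_period / cfg.record_dt)))
    goal = layout.goal
    for _ in range(cfg.explore_trials):
        positions = exploration_trial(layout, cfg.explore_duration, rng,
                                      speed=cfg.policy.speed,
                                      turn_period=cfg.turn_period,
                                      record_dt=cfg.record_dt)
        cells = np.array([layout.snap((p[0], p[1])) for p in positions])
        if cfg.unified_equation:
            coupling = effective_coupling(
                scale_to_adjacent(correlation_normalize(J),
                                  adjacent_pairs(layout), cfg.coupling_gain),
                cfg.g_inh)
            rates = _unified_rates(pop, cells, coupling, cfg)
        else:
            rates = pop.rates_at_cells(cells)
        for k0 in range(0, len(rates), batch):
            J = hebbian_update_batch(J, rates[k0:k0 + batch], cfg.alpha1)
        if U is not None:
            for p, r in zip(positions, rates):
                at_goal = in_goal_region((p[0], p[1]), goal,
                                         cfg.policy.goal_radius,
                                         cfg.policy.goal_shape)
                U[:] = update_goal_weights(U, r, at_goal, cfg.striatal.alpha3)
        if learner is not None:
            for k, r in enumerate(rates):
                learner(k + 1, r, r)
    return J


def _unified_rates(pop: PlacePopulation, cells: np.ndarray,
                   coupling: np.ndarray, cfg: ExperimentConfig) -> np.ndarray:
    """Exploration rates under the unified-equation variant.

    The attractor network is integrated along the trial with a persistent
    input that follows the agent; the rate vector at the end of each
    recorded window (peak-normalized, so the Hebbian target stays
    comparable to the closed-form rates) stands in for the closed-form
    geodesic rates.
    """
    from .attractor_network import run, NetworkState

    inputs = cfg.unified_amplitude * pop.rates_at_cells(cells)  # (N, M)
    n_sub = max(1, int(round(cfg.record_dt / cfg.can.dt)))
    k_holder = {"i": 0}

    def schedule(t: float) -> np.ndarray:
        return inputs[min(k_holder["i"], len(inputs) - 1)]

    out = np.empty_like(inputs)
    state = NetworkState.zeros(pop.n_cells)
    for i in range(len(inputs)):
        k_holder["i"] = i
        trace = run(state, coupling, schedule, n_sub * cfg.can.dt, cfg.can,
                    record_stride=n_sub * cfg.can.dt)
        state = trace.final
        peak = state.r.max()
        out[i] = state.r / peak if peak > 0 else state.r
    return out


def rest_phase(state: ExperimentState, cfg: ExperimentConfig,
               duration: float | None = None) -> tuple[np.ndarray, list[str]]:
    """Rest replay with three-factor learning; returns new ``W`` + warnings."""
    duration = cfg.rest_duration if duration is None else duration
    striatal = cfg.striatal
    learner = ReplayLearner(state.W, state.U, striatal, cfg.can.dt)
    coupling = state.coupling(cfg)

    callback = learner
    if cfg.simultaneous_updates:
        callback = _SimultaneousUpdater(learner, state, cfg)
    trace = rest_replay(coupling, state.pop, state.layout.goal, duration,
                        cfg.can, amplitude=cfg.rest_amplitude,
                        transient=cfg.transient,
                        event_duration=cfg.rest_event_duration,
                        callback=callback)
    if cfg.simultaneous_updates:
        state.J = callback.J
    return learner.W, trace.warnings


class _SimultaneousUpdater:
    """Variant: Hebbian updates of J also run during replay (batched 1 s)."""

    def __init__(self, learner: ReplayLearner, state: ExperimentState,
                 cfg: ExperimentConfig):
        self.learner = learner
        self.cfg = cfg
        self.J = state.J.copy()
        self._buf: list[np.ndarray] = []
        self._batch = int(round(1.0 / cfg.can.dt))

    def reset_trace(self) -> None:
        self.learner.reset_trace()

    def __call__(self, k: int, r: np.ndarray, I: np.ndarray) -> None:
        self.learner(k, r, I)
        peak = r.max()
        if peak > 0:
            self._buf.append(r / peak)
        if len(self._buf) >= self._batch:
            self.J = hebbian_update_batch(self.J, np.array(self._buf),
                                          self.cfg.alpha1)
            self._buf.clear()


def test_start_grid(layout: MazeLayout, n_trials: int,
                    goal_radius: float = 0.5) -> list[tuple[float, float]]:
    """Fixed, evenly spread start positions outside the goal region."""
    goal = layout.goal
    candidates = [layout.cell_center(c) for c in layout.free_cells()]
    candidates = [p for p in candidates
                  if not in_goal_region(p, goal, goal_radius + layout.spacing)]
    idx = np.linspace(0, len(candidates) - 1, n_trials).round().astype(int)
    return [candidates[i] for i in idx]


def test_phase(state: ExperimentState, cfg: ExperimentConfig,
               rng: np.random.Generator) -> Metrics:
    """Run the fixed-grid test trials and compute the metrics."""
    model = state.navigation_model(cfg)
    starts = test_start_grid(state.layout, cfg.test_trials,
                             cfg.policy.goal_radius)
    records = []
    for i, start in enumerate(starts):
        result = run_test_trial(start, cfg.policy, model, state.layout,
                                max_duration=cfg.max_trial_duration, rng=rng)
        dist = geodesic_distance(state.layout, start, state.layout.goal)
        latency = result.time_to_goal / dist if result.success and dist > 0 \
            else float("nan")
        records.append({
            "trial": i, "start_x": start[0], "start_y": start[1],
            "success": result.success, "time_to_goal": result.time_to_goal,
            "geodesic_to_goal": dist, "normalized_latency": latency,
            "n_plans": result.n_plans, "n_fallbacks": result.n_fallbacks,
        })
    trials = pd.DataFrame.from_records(records)
    lat = trials.loc[trials.success, "normalized_latency"].mean()
    return Metrics(success_rate=float(trials.success.mean()),
                   normalized_latency=float(lat), trials=trials)


# ---------------------------------------------------------------------------
# experiment chains

def _fresh_state(layout: MazeLayout, cfg: ExperimentConfig) -> ExperimentState:
    pop = PlacePopulation.from_grid(layout, cfg.sigma)
    M = pop.n_cells
    U = goal_weights(pop, layout.goal, cfg.striatal.xi)
    return ExperimentState(layout, pop, zero_matrix(M), np.zeros(M), U)


def run_goal_fixed(cfg: ExperimentConfig,
                   layout: MazeLayout | None = None,
                   ) -> tuple[Metrics, ExperimentState]:
    """Exploration, rest-replay learning, and test trials on the base maze."""
    layout = fixtures.goal_fixed_layout() if layout is None else layout
    state = _fresh_state(layout, cfg)
    rng = _seed_for(cfg.seed, "goal_fixed.explore")
    learner = None
    if cfg.simultaneous_updates:
        learner = ReplayLearner(state.W, state.U, cfg.striatal, cfg.record_dt)
    state.J = explore_phase(layout, state.pop, state.J, cfg, rng,
                            learner=learner)
    if learner is not None:
        state.W = learner.W
    state.W, warnings = rest_phase(state, cfg)
    metrics = test_phase(state, cfg, _seed_for(cfg.seed, "goal_fixed.test"))
    metrics.warnings.extend(warnings)
    return metrics, state


def run_goal_changing(cfg: ExperimentConfig, state: ExperimentState,
                      new_layout: MazeLayout | None = None,
                      ) -> tuple[Metrics, ExperimentState]:
    """Move the goal, re-learn ``U`` by reward and ``W`` by replay, re-test."""
    new_layout = fixtures.goal_changing_layout() if new_layout is None \
        else new_layout
    state = ExperimentState(new_layout, state.pop.rebind(new_layout),
                            state.J.copy(), state.W.copy(), state.U.copy())
    rng = _seed_for(cfg.seed, "goal_changing.explore")
    # goal moved: U is re-learned from experienced reward, J stays
    explore_phase(new_layout, state.pop, state.J.copy(), cfg, rng, U=state.U)
    state.W, warnings = rest_phase(state, cfg,
                                   duration=cfg.goal_change_rest_duration)
    metrics = test_phase(state, cfg, _seed_for(cfg.seed, "goal_changing.test"))
    metrics.warnings.extend(warnings)
    return metrics, state


def _relearn_layout(cfg: ExperimentConfig, state: ExperimentState,
                    new_layout: MazeLayout, label: str,
                    ) -> tuple[Metrics, ExperimentState]:
    state = ExperimentState(new_layout, state.pop.rebind(new_layout),
                            state.J.copy(), state.W.copy(), state.U.copy())
    rng = _seed_for(cfg.seed, f"{label}.explore")
    state.J = explore_phase(new_layout, state.pop, state.J, cfg, rng)
    state.U = goal_weights(state.pop, new_layout.goal, cfg.striatal.xi)
    state.W, warnings = rest_phase(state, cfg,
                                   duration=cfg.relearn_rest_duration)
    metrics = test_phase(state, cfg, _seed_for(cfg.seed, f"{label}.test"))
    metrics.warnings.extend(warnings)
    return metrics, state


def run_detour(cfg: ExperimentConfig, state: ExperimentState,
               new_layout: MazeLayout | None = None,
               ) -> tuple[Metrics, ExperimentState]:
    """Close two passages; re-learn ``J`` and ``W``; re-test."""
    new_layout = fixtures.detour_layout() if new_layout is None else new_layout
    return _relearn_layout(cfg, state, new_layout, "detour")


def run_shortcut(cfg: ExperimentConfig, state: ExperimentState,
                 new_layout: MazeLayout | None = None,
                 ) -> tuple[Metrics, ExperimentState]:
    """Remove walls from the detour maze; re-learn; re-test."""
    new_layout = fixtures.shortcut_layout() if new_layout is None \
        else new_layout
    return _relearn_layout(cfg, state, new_layout, "shortcut")


def paper_config(seed: int = 0) -> ExperimentConfig:
    """Full-scale configuration: the original phase schedule.

    50 exploration trials of 120 s, 60 s initial rest replay, 100 test
    trials.  Pair with a full-scale maze (e.g. an upscaled fixture via
    :func:`replaynav.fixtures.upscale`); runtimes are roughly an order of
    magnitude above the desk profile.
    """
    return ExperimentConfig(
        explore_trials=50, explore_duration=120.0,
        rest_duration=60.0, relearn_rest_duration=120.0,
        goal_change_rest_duration=240.0, test_trials=100, seed=seed,
    )


_EXPERIMENTS = {
    "goal-fixed": run_goal_fixed,
    "goal-changing": run_goal_changing,
    "detour": run_detour,
    "shortcut": run_shortcut,
}


def run_experiment(name: str, cfg: ExperimentConfig,
                   state: ExperimentState | None = None,
                   ) -> tuple[Metrics, ExperimentState]:
    """Run one named experiment; later experiments require the prior state."""
    if name not in _EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; "
                         f"choose from {sorted(_EXPERIMENTS)}")
    if name == "goal-fixed":
        return run_goal_fixed(cfg)
    if state is None:
        raise ValueError(f"experiment {name!r} requires the saved state of "
                         "an earlier phase")
    return _EXPERIMENTS[name](cfg, state)


def _with_param(cfg: ExperimentConfig, key: str, value) -> ExperimentConfig:
    """Set a (possibly dotted, e.g. ``policy.A_awake``) config key."""
    head, _, rest = key.partition(".")
    valid = [f.name for f in dataclasses.fields(cfg)]
    if head not in valid:
        raise ValueError(f"unknown config key {key!r}; valid keys: {valid}")
    if rest:
        sub = getattr(cfg, head)
        sub_valid = [f.name for f in dataclasses.fields(sub)]
        if rest not in sub_valid:
            raise ValueError(f"unknown config key {key!r}; valid sub-keys of "
                             f"{head!r}: {sub_valid}")
        return dataclasses.replace(
            cfg, **{head: dataclasses.replace(sub, **{rest: value})})
    return dataclasses.replace(cfg, **{head: value})


def parameter_sweep(cfg: ExperimentConfig, parameter: str,
                    values: list) -> pd.DataFrame:
    """Repeat the goal-fixed experiment across values of one config key.

    A sweep point whose learning collapses (e.g. no exploration: the bump
    is pinned at the goal and the three-factor rule diverges) is recorded
    as success 0 with a note, rather than aborting the whole sweep.
    """
    from .striatal_learning import MSNDivergenceError
    rows = []
    for v in values:
        try:
            metrics, _ = run_goal_fixed(_with_param(cfg, parameter, v))
            rows.append({
                "parameter": parameter, "value": v,
                "success_rate": metrics.success_rate,
                "normalized_latency": metrics.normalized_latency,
                "note": "; ".join(metrics.warnings),
            })
        except MSNDivergenceError as exc:
            rows.append({
                "parameter": parameter, "value": v, "success_rate": 0.0,
                "normalized_latency": float("nan"), "note": str(exc),
            })
    return pd.DataFrame.from_records(
        rows, columns=["parameter", "value", "success_rate",
                       "normalized_latency", "note"])
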