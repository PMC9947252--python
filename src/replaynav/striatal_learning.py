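"""Striatal read-outs and dopamine-modulated three-factor learning.

The place-cell population projects to a single medium-spiny-neuron (MSN)
population with weights ``W`` (read-out ``V = W . r``, a value-like signal)
and to a goal-cell population with weights ``U`` (read-out ``G = U . r``).
During rest replay the PC-MSN weights are learned with a three-factor rule:

    dW_i/dt = alpha2 * z_i(t) * delta(t)
    z_i(t)  = r_i(t) V(t)              while r_i V > q   (replacing trace)
    dz_i/dt = -z_i / tau_z             while r_i V <= q
    delta   = G(t) + dV/dt             (dopamine deviation from baseline)

The trace ``z`` is a chemical (Ca2+) co-firing trace at each synapse; the
*replacing* assignment resets it to the instantaneous joint rate rather than
accumulating it, which prevents frequently replayed but goal-distant places
from being over-valued.  ``delta`` combines the goal-cell drive with the
time derivative of the MSN activity -- a continuous-time temporal-difference
signal that propagates value backwards along replayed paths.

The MSN carries a small tonic baseline ``v0`` inside the learning rule
(``V_learn = v0 + W . r``): without spontaneous MSN activity the co-firing
trace of a zero-initialized ``W`` could never cross threshold and learning
could not bootstrap.  The baseline is constant, so it leaves ``dV/dt`` and
all softmax-based decisions unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .place_code import PlacePopulation

__all__ = [
    "StriatalParams", "DopamineSignal", "MSNDivergenceError",
    "msn_activity", "goal_weights", "goal_activity",
    "update_trace", "accumulating_trace_variant", "dopamine",
    "update_msn_weights", "update_goal_weights", "ReplayLearner",
]


class MSNDivergenceError(RuntimeError):
    """PC-MSN weights became non-finite; use a smaller learning rate."""


@dataclass(frozen=True)
class StriatalParams:
    """Constants of the striatal learning stage.

    ``alpha2`` is a continuous-time rate (per second) integrated with the
    simulation step; setting ``alpha2_per_step`` interprets it per update
    instead.  ``trace_mode`` selects the replacing rule (default) or the
    conventional accumulating rule (ablation).
    """

    alpha2: float = 0.01       # PC-MSN learning rate
    q: float = 0.1             # co-firing threshold
    tau_z: float = 0.5         # trace decay constant (s)
    xi: float = 0.3            # goal-weight length scale (m)
    alpha3: float = 0.01       # PC-goal-cell learning rate (reward-modulated)
    v0: float = 1.0            # tonic MSN baseline inside the learning rule
    trace_mode: str = "replacing"
    alpha2_per_step: bool = False
    #: Peak-normalize the incoming rate vector: replay rates then live on
    #: the same unit-peak scale as the closed-form place-field rates that
    #: the thresholds (q) and learning rates were chosen for.
    normalize_rates: bool = True
    #: Time constant (s) of the low-pass filter applied to V before the
    #: temporal derivative is taken.  Dopamine transients integrate over
    #: ~100 ms; without the filter, millisecond bump-shape jitter in V
    #: rectifies against the co-firing trace into a spurious, position-
    #: independent weight floor.  0 disables the filter.
    v_filter_tau: float = 0.0

    def __post_init__(self) -> None:
        if self.trace_mode not in ("replacing", "accumulating"):
            raise ValueError(f"unknown trace_mode {self.trace_mode!r}")
        if self.tau_z <= 0 or self.xi <= 0:
            raise ValueError("tau_z and xi must be positive")


@dataclass(frozen=True)
class DopamineSignal:
    """Dopamine deviation from baseline, ``delta = G + dV/dt``."""

    delta: float
    G: float
    V_dot: float


def msn_activity(W: np.ndarray, r: np.ndarray) -> float:
    """MSN population read-out ``V = sum_i W_i r_i``."""
    W, r = np.asarray(W, dtype=float), np.asarray(r, dtype=float)
    if W.shape != r.shape:
        raise ValueError(f"length mismatch: W {W.shape} vs r {r.shape}")
    return float(W @ r)


def goal_weights(pop: PlacePopulation, x_g: tuple[float, float],
                 xi: float) -> np.ndarray:
    """Analytic PC-to-goal-cell weights ``U_i = exp(-D(x_i, x_g)/xi)``."""
    if xi <= 0:
        raise ValueError("xi must be positive")
    return np.exp(-pop.distances_to(x_g) / xi)


def goal_activity(U: np.ndarray, r: np.ndarray) -> float:
    """Goal-cell population read-out ``G = sum_i U_i r_i``."""
    U, r = np.asarray(U, dtype=float), np.asarray(r, dtype=float)
    if U.shape != r.shape:
        raise ValueError(f"length mismatch: U {U.shape} vs r {r.shape}")
    return float(U @ r)


def update_trace(z: np.ndarray, r: np.ndarray, V: float, params: StriatalParams,
                 dt: float) -> np.ndarray:
    """Replacing-trace update: assign where co-firing, decay elsewhere.

    Where ``r_i V > q`` the trace is *set* to ``r_i V`` (previous value
    discarded); elsewhere it decays by the exact factor ``exp(-dt/tau_z)``.
    The boundary ``r_i V == q`` decays (the co-firing indicator is strict).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    joint = np.asarray(r, dtype=float) * V
    cofiring = joint > params.q
    out = z * np.exp(-dt / params.tau_z)
    out[cofiring] = joint[cofiring]
    return out


def accumulating_trace_variant(z: np.ndarray, r: np.ndarray, V: float,
                               params: StriatalParams, dt: float) -> np.ndarray:
    """Conventional accumulating trace ``dz/dt = -z/tau_z + r V`` (ablation)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return z * np.exp(-dt / params.tau_z) + np.asarray(r, dtype=float) * V * dt


def dopamine(G: float, V_now: float, V_prev: float | None, dt: float,
             ) -> DopamineSignal:
    """Dopamine deviation ``delta = G + (V_now - V_prev)/dt``.

    At the first step of a run there is no previous MSN activity and the
    derivative term is defined as zero.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    V_dot = 0.0 if V_prev is None else (V_now - V_prev) / dt
    return DopamineSignal(delta=G + V_dot, G=G, V_dot=V_dot)


def update_msn_weights(W: np.ndarray, z: np.ndarray, delta: DopamineSignal,
                       params: StriatalParams, dt: float) -> np.ndarray:
    """Three-factor weight step ``W <- W + alpha2 * z * delta * dt``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    gain = params.alpha2 if params.alpha2_per_step else params.alpha2 * dt
    out = W + gain * z * delta.delta
    if not np.isfinite(out.sum()):
        raise MSNDivergenceError(
            "PC-MSN weights diverged; reduce alpha2 (collapse occurs above ~1e-2)"
        )
    return out


def update_goal_weights(U: np.ndarray, r: np.ndarray, at_goal: bool,
                        alpha3: float) -> np.ndarray:
    """Reward-modulated goal-weight step ``U <- U + alpha3 (r - U) h``.

    ``h`` is 1 inside the goal region (``at_goal``) and 0 elsewhere; with
    repeated rewarded visits ``U`` converges exponentially toward the rate
    vector evaluated inside the goal region.
    """
    if not at_goal:
        return U
    return U + alpha3 * (np.asarray(r, dtype=float) - U)


class ReplayLearner:
    """Per-step three-factor learning, attached to a replay integration.

    Instances are callbacks for :func:`replaynav.replay_engine.rest_replay`:
    at every integration step they read the current rate vector, update the
    co-firing trace, compute the dopamine signal and move the PC-MSN
    weights.  ``W`` and ``U`` are owned copies; read them back after the
    run.
    """

    def __init__(self, W: np.ndarray, U: np.ndarray, params: StriatalParams,
                 dt: float, record_stride: float | None = None):
        self.W = np.array(W, dtype=float)
        self.U = np.array(U, dtype=float)
        self.params = params
        self.dt = dt
        self.z = np.zeros_like(self.W)
        self._V_prev: float | None = None
        self._V_filt: float | None = None
        self._decay = np.exp(-dt / params.tau_z)
        self._filt_a = (dt / params.v_filter_tau
                        if params.v_filter_tau > 0 else 1.0)
        self._stride = (max(1, int(round(record_stride / dt)))
                        if record_stride else None)
        self.history: list[dict] = []

    def reset_trace(self) -> None:
        """Start a fresh replay event: clear the trace and the V memory."""
        self.z[:] = 0.0
        self._V_prev = None
        self._V_filt = None

    def __call__(self, k: int, r: np.ndarray, I: np.ndarray) -> None:
        p = self.params
        if p.normalize_rates:
            peak = r.max()
            if peak > 0:
                r = r / peak
        V = float(self.W @ r) + p.v0
        G = float(self.U @ r)
        joint = r * V
        if p.trace_mode == "replacing":
            self.z *= self._decay
            cofiring = joint > p.q
            self.z[cofiring] = joint[cofiring]
        else:
            self.z *= self._decay
            self.z += joint * self.dt
        if self._V_filt is None:
            self._V_filt = V
        else:
            self._V_filt += self._filt_a * (V - self._V_filt)
        sig = dopamine(G, self._V_filt, self._V_prev, self.dt)
        self.W = update_msn_weights(self.W, self.z, sig, p, self.dt)
        self._V_prev = self._V_filt
        if self._stride and k % self._stride == 0:
            self.history.append(
                {"t": k * self.dt, "V": V - p.v0, "G": G, "delta": sig.delta}
            )
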