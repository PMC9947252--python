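"""Continuous attractor network (CAN) with feedback inhibition.

Rate dynamics of the place-cell population under recurrent coupling,
external (visual) input and slow feedback inhibition from interneurons:

    tau_r * dr_i/dt = -r_i + [ sum_{j!=i} C_ij r_j + E_i - I_i - h0 ]_+
    tau_I * dI_i/dt = -I_i + c_I r_i

with ``[x]_+ = max(x, 0)``.  The fast excitation (tau_r ~ ms) supports a
localized activity bump on the learned coupling; the slow inhibition
(tau_I ~ 0.5 s) builds up under the bump and pushes it away, so the bump
travels along paths of the maze -- the substrate of replay.  A strong
external input pins the bump at the animal's location; with no input the
bump drifts freely; at intermediate amplitude it periodically escapes and
jumps back, producing look-ahead excursions.

Integration is explicit Euler at ``dt`` (default 1 ms, stable for
``tau_r = 2 ms``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["CANParams", "NetworkState", "RunTrace", "IntegrationDivergedError",
           "step", "run"]


class IntegrationDivergedError(RuntimeError):
    """NaN/Inf appeared in the network state during integration."""


#: Exponentially decaying states are flushed to zero below this level:
#: biologically meaningless and, left subnormal, ruinous for BLAS speed.
_FLUSH = 1e-12


@dataclass(frozen=True)
class CANParams:
    """Constants of the rate dynamics.

    ``inhibitory_transfer`` applies the same threshold-linear transfer and
    threshold to the interneuron equation (a control variant); by default
    the inhibition integrates ``c_I r`` linearly.
    """

    tau_r: float = 0.002   # excitatory time constant (s)
    tau_I: float = 0.5     # inhibitory time constant (s)
    c_I: float = 10.0      # feedback inhibition strength
    h0: float = 0.0        # activation threshold
    dt: float = 0.001      # Euler step (s)
    inhibitory_transfer: bool = False
    r_cap: float | None = 8.0   # peak-rate normalization bound (None: off)

    def __post_init__(self) -> None:
        if min(self.tau_r, self.tau_I, self.dt) <= 0:
            raise ValueError("tau_r, tau_I and dt must be positive")
        if self.dt > self.tau_r:
            raise ValueError(
                f"dt={self.dt} exceeds tau_r={self.tau_r}; explicit Euler unstable"
            )
        if self.r_cap is not None and self.r_cap <= 0:
            raise ValueError("r_cap must be positive (or None)")


@dataclass
class NetworkState:
    """Instantaneous rates and inhibition at time ``t``."""

    r: np.ndarray
    I: np.ndarray
    t: float = 0.0

    @classmethod
    def zeros(cls, n_cells: int, t: float = 0.0) -> "NetworkState":
        return cls(np.zeros(n_cells), np.zeros(n_cells), t)


@dataclass
class RunTrace:
    """States sampled at a fixed stride during :func:`run`."""

    times: np.ndarray        # (S,)
    rates: np.ndarray        # (S, M)
    inhibition: np.ndarray   # (S, M)
    final: NetworkState
    warnings: list[str] = field(default_factory=list)


def step(state: NetworkState, coupling: np.ndarray, E: np.ndarray,
         params: CANParams) -> NetworkState:
    """One explicit-Euler step; the coupling diagonal is ignored."""
    r, I = state.r, state.I
    if coupling.shape != (r.size, r.size) or np.size(E) != r.size:
        raise ValueError("dimension mismatch between state, coupling and input")
    rec = coupling @ r - np.diag(coupling) * r
    drive = np.maximum(rec + E - I - params.h0, 0.0)
    r_new = r + (params.dt / params.tau_r) * (-r + drive)
    inh_in = params.c_I * r
    if params.inhibitory_transfer:
        inh_in = np.maximum(inh_in - params.h0, 0.0)
    I_new = I + (params.dt / params.tau_I) * (-I + inh_in)
    if not (np.isfinite(r_new.sum()) and np.isfinite(I_new.sum())):
        raise IntegrationDivergedError(
            f"network state diverged at t={state.t + params.dt:.4f} s"
        )
    if params.r_cap is not None:
        peak = r_new.max()
        if peak > params.r_cap:
            r_new = r_new * (params.r_cap / peak)
    r_new[r_new < _FLUSH] = 0.0
    I_new[np.abs(I_new) < _FLUSH] = 0.0
    return NetworkState(r_new, I_new, state.t + params.dt)


def run(state: NetworkState, coupling: np.ndarray,
        input_schedule: Callable[[float], np.ndarray] | np.ndarray | None,
        duration: float, params: CANParams,
        record_stride: float = 0.01,
        callback: Callable[[int, np.ndarray, np.ndarray], None] | None = None,
        ) -> RunTrace:
    """Integrate the dynamics for ``duration`` seconds.

    ``input_schedule`` may be a callable ``t -> E`` evaluated once per step,
    a constant vector, or ``None`` (no input).  States are recorded every
    ``record_stride`` seconds (including the initial state).  ``callback``
    is invoked after every step with ``(step_index, r, I)`` -- used by
    learning rules that piggy-back on the integration; the arrays must not
    be mutated.  The dynamics are deterministic: identical inputs give
    identical traces.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    M = state.r.size
    n_steps = int(round(duration / params.dt))
    stride_steps = max(1, int(round(record_stride / params.dt)))
    if callable(input_schedule):
        get_input = input_schedule
    else:
        const = np.zeros(M) if input_schedule is None else np.asarray(input_schedule)
        get_input = lambda t: const  # noqa: E731

    # Split the coupling once so the hot loop is a single BLAS matvec.
    C = np.array(coupling, dtype=float)
    np.fill_diagonal(C, 0.0)

    n_rec = n_steps // stride_steps + 1
    times = np.empty(n_rec)
    rates = np.empty((n_rec, M))
    inhib = np.empty((n_rec, M))
    r = state.r.astype(float).copy()
    I = state.I.astype(float).copy()
    t = state.t
    k_rec = 0
    times[0], rates[0], inhib[0] = t, r, I
    k_rec = 1
    dt_r = params.dt / params.tau_r
    dt_I = params.dt / params.tau_I
    cap = params.r_cap
    for k in range(1, n_steps + 1):
        E = get_input(t)
        drive = C @ r
        drive += E
        drive -= I
        if params.h0:
            drive -= params.h0
        np.maximum(drive, 0.0, out=drive)
        inh_in = params.c_I * r  # pre-step rates, matching step()
        if params.inhibitory_transfer:
            np.maximum(inh_in - params.h0, 0.0, out=inh_in)
        r += dt_r * (drive - r)
        I += dt_I * (inh_in - I)
        if cap is not None:
            peak = r.max()
            if peak > cap:
                r *= cap / peak
        r[r < _FLUSH] = 0.0
        I[I < _FLUSH] = 0.0
        t = state.t + k * params.dt
        if not np.isfinite(r.sum()):
            raise IntegrationDivergedError(f"network state diverged at t={t:.4f} s")
        if callback is not None:
            callback(k, r, I)
        if k % stride_steps == 0:
            times[k_rec], rates[k_rec], inhib[k_rec] = t, r, I
            k_rec += 1
    return RunTrace(times[:k_rec], rates[:k_rec], inhib[:k_rec],
                    NetworkState(r, I, t))
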