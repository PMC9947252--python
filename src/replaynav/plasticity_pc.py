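"""Hebbian-like learning of the inter-place-cell synaptic matrix.

During exploration the recurrent matrix ``J`` relaxes toward the running
correlation of place-cell rates,

    J <- J + alpha1 * (r^T r - J),

whose fixed point is ``J*_ij = E[r_i(x) r_j(x)]`` over the exploration
distribution of positions.  Because the fields are geodesic, ``J*`` decays
with the shortest-path distance between preferential locations and thereby
encodes the adjacency structure of the maze, walls included.

The magnitude of ``J*`` scales inversely with the number of distinct
locations visited (the correlation of two localized fields is small when
averaged over a large maze), so before the matrix is used as the coupling
of the attractor network it is rescaled to a fixed peak strength
(:func:`scale_to_peak`); only the shape of ``J`` is informative.
"""

from __future__ import annotations

import numpy as np

from .place_code import PlacePopulation

__all__ = [
    "zero_matrix",
    "hebbian_update",
    "hebbian_update_batch",
    "empirical_fixed_point",
    "correlation_normalize",
    "adjacent_pairs",
    "scale_to_adjacent",
    "scale_to_peak",
    "effective_coupling",
]


def zero_matrix(n_cells: int) -> np.ndarray:
    """Initial inter-PC matrix ``J^(0) = 0``."""
    return np.zeros((n_cells, n_cells))


def hebbian_update(J: np.ndarray, r: np.ndarray, alpha1: float) -> np.ndarray:
    """One Hebbian-like step ``J <- J + alpha1 (r^T r - J)``; returns new J.

    Symmetry is preserved and, for rates in [0, 1] starting from ``J = 0``,
    entries stay in [0, 1] (convex combination of outer products).
    """
    r = np.asarray(r, dtype=float)
    if J.shape != (r.size, r.size):
        raise ValueError(f"shape mismatch: J {J.shape} vs rate vector of {r.size}")
    return J + alpha1 * (np.outer(r, r) - J)


def hebbian_update_batch(J: np.ndarray, R: np.ndarray, alpha1: float) -> np.ndarray:
    """One Hebbian-like step using the batch-averaged outer product.

    ``R`` is an ``(N, M)`` stack of rate vectors (e.g. every position
    visited during one locomotion period); the update target is the mean of
    their outer products, computed with one BLAS call:

        J <- J + alpha1 * (mean_k r_k^T r_k - J).

    Using the period-averaged correlation (rather than one update per
    sample) keeps the effective memory of the learning rule long enough to
    span the whole exploration history, while still weighting every visited
    position.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or J.shape != (R.shape[1], R.shape[1]):
        raise ValueError(f"shape mismatch: J {J.shape} vs rate batch {R.shape}")
    target = (R.T @ R) / R.shape[0]
    return J + alpha1 * (target - J)


def empirical_fixed_point(positions, pop: PlacePopulation) -> np.ndarray:
    """Brute-force oracle for the learned matrix: mean of ``r^T r``.

    ``positions`` is a non-empty sequence of 2-D positions; the mean is the
    stochastic-approximation fixed point of the Hebbian-like rule under the
    empirical visit distribution.
    """
    positions = list(positions)
    if not positions:
        raise ValueError("empirical_fixed_point requires at least one position")
    M = pop.n_cells
    acc = np.zeros((M, M))
    for x in positions:
        r = pop.firing_rates(x)
        acc += np.outer(r, r)
    return acc / len(positions)


def correlation_normalize(J: np.ndarray) -> np.ndarray:
    """Normalize the learned correlation to cosine form, ``J_ij / sqrt(J_ii J_jj)``.

    The raw fixed point ``E[r_i r_j]`` is weighted by the exploration
    occupancy: cells in heavily visited regions carry systematically larger
    correlations than equally adjacent cells in lightly visited regions,
    which leaves weak links in the coupling where exploration was sparse.
    Dividing by the per-cell activity scale (the square root of the
    diagonal) removes this bias -- the analogue of homeostatic synaptic
    scaling -- leaving a coupling that depends on geodesic adjacency alone.
    Rows of silent cells (zero diagonal) stay zero.
    """
    d = np.sqrt(np.diag(J).clip(min=0.0))
    d[d <= 0] = np.inf
    return J / np.outer(d, d)


def adjacent_pairs(layout) -> np.ndarray:
    """Index pairs of grid-adjacent free cells, for a full-grid population.

    Row-major full-grid indexing (``i = row * n_cols + col``); only pairs
    whose two cells are both free in ``layout`` are returned.
    """
    pairs = []
    for r in range(layout.n_rows):
        for c in range(layout.n_cols):
            if not layout.is_free((r, c)):
                continue
            i = r * layout.n_cols + c
            for (nr, nc) in ((r + 1, c), (r, c + 1)):
                if layout.is_free((nr, nc)):
                    pairs.append((i, nr * layout.n_cols + nc))
    return np.array(pairs, dtype=int).reshape(-1, 2)


def scale_to_adjacent(J: np.ndarray, pairs: np.ndarray,
                      gain: float) -> np.ndarray:
    """Rescale ``J`` so the *median* coupling of adjacent cell pairs is ``gain``.

    The median over thousands of nearest-neighbour pairs is stable across
    exploration histories to a fraction of a percent, whereas the maximal
    entry (see :func:`scale_to_peak`) fluctuates by tens of percent and
    with it the excitability of the attractor network.  Pinning the median
    keeps the network in the same dynamical regime for every learned ``J``.
    """
    med = float(np.median(J[pairs[:, 0], pairs[:, 1]]))
    if med <= 0:
        return J.copy()
    return J * (gain / med)


def scale_to_peak(J: np.ndarray, peak: float) -> np.ndarray:
    """Rescale ``J`` so its maximal off-diagonal entry equals ``peak``.

    A zero matrix is returned unchanged.  The rescaling removes the
    dependence of the correlation magnitude on maze size and exploration
    length; ``peak`` then sets the recurrent gain of the attractor network.
    """
    off = J - np.diag(np.diag(J))
    m = off.max()
    if m <= 0:
        return J.copy()
    return J * (peak / m)


def effective_coupling(J: np.ndarray, g_inh: float) -> np.ndarray:
    """Recurrent coupling with uniform global inhibition, ``J + g_inh``.

    ``g_inh <= 0`` is added to every entry; the diagonal is excluded later
    by the network dynamics (the recurrent sum runs over ``j != i``).
    """
    if g_inh > 0:
        raise ValueError("global inhibition strength must be <= 0")
    return J + g_inh
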