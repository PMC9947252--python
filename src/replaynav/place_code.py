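"""Geodesic place fields, external (visual) input, and the population vector.

Each place cell ``i`` has a preferential location ``x_i`` (a grid-cell
center) and fires at rate ``r_i(x) = exp(-D(x_i, x) / sigma)`` where ``D``
is the shortest around-wall path distance.  Fields therefore decay along
paths and respect walls, unlike Gaussian (Euclidean) place fields.

A :class:`PlacePopulation` can be built either from the free cells of one
layout, or on the full grid (``from_grid``) so that the same cell population
persists across layout changes: cells whose preferential location is buried
under a wall in the current layout are simply silent (unreachable distance,
zero rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maze_geometry import MazeLayout, MazeSpecError, bfs_distances

__all__ = ["PlacePopulation", "AllSilentError", "population_vector"]


class AllSilentError(ValueError):
    """Population vector requested for an all-zero rate vector."""


@dataclass(frozen=True)
class PlacePopulation:
    """Population of geodesic place cells bound to one maze layout.

    ``cell_dist[i, r, c]`` holds the geodesic distance (m) from the
    preferential location of cell ``i`` to grid cell ``(r, c)`` in the bound
    layout (``inf`` if blocked or unreachable).
    """

    layout: MazeLayout
    sigma: float
    center_cells: tuple[tuple[int, int], ...]
    centers: np.ndarray          # (M, 2) positions in metres
    cell_dist: np.ndarray        # (M, n_rows, n_cols) metres

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_layout(cls, layout: MazeLayout, sigma: float) -> "PlacePopulation":
        """One place cell per free cell of ``layout`` (row-major order)."""
        return cls._build(layout, sigma, tuple(layout.free_cells()))

    @classmethod
    def from_grid(cls, layout: MazeLayout, sigma: float) -> "PlacePopulation":
        """One place cell per grid cell, blocked cells silent.

        Use this for experiments whose layout changes: the cell identity
        (index) is stable across layouts of the same grid shape.
        """
        cells = tuple(
            (r, c) for r in range(layout.n_rows) for c in range(layout.n_cols)
        )
        return cls._build(layout, sigma, cells)

    @classmethod
    def _build(cls, layout, sigma, cells) -> "PlacePopulation":
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        M = len(cells)
        dist = np.full((M, layout.n_rows, layout.n_cols), np.inf)
        for i, cell in enumerate(cells):
            if layout.is_free(cell):
                dist[i] = bfs_distances(layout, cell) * layout.spacing
        centers = np.array([layout.cell_center(c) for c in cells], dtype=float)
        return cls(layout, sigma, cells, centers, dist)

    def rebind(self, layout: MazeLayout) -> "PlacePopulation":
        """Same cell population, distances recomputed on a new layout.

        The new layout must share the grid shape and pitch so cell indices
        keep their meaning.
        """
        if (layout.n_rows, layout.n_cols) != (self.layout.n_rows, self.layout.n_cols) \
                or layout.spacing != self.layout.spacing:
            raise MazeSpecError("rebind requires an identical grid shape and pitch")
        return self._build(layout, self.sigma, self.center_cells)

    # -- rate maps --------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.center_cells)

    def distances_to(self, x: tuple[float, float]) -> np.ndarray:
        """Geodesic distance (m) from every preferential location to ``x``."""
        r, c = self.layout.snap(x)
        return self.cell_dist[:, r, c]

    def firing_rates(self, x: tuple[float, float]) -> np.ndarray:
        """Rates ``exp(-D(x_i, x)/sigma)`` at position ``x``; in [0, 1]."""
        with np.errstate(over="ignore"):
            return np.exp(-self.distances_to(x) / self.sigma)

    def rates_at_cells(self, cells: np.ndarray) -> np.ndarray:
        """Rate vectors for an ``(N, 2)`` int array of free cells -> ``(N, M)``."""
        cells = np.asarray(cells, dtype=int).reshape(-1, 2)
        d = self.cell_dist[:, cells[:, 0], cells[:, 1]]  # (M, N)
        return np.exp(-d.T / self.sigma)

    def external_input(self, x: tuple[float, float], A: float) -> np.ndarray:
        """Visual input ``E_i = A * exp(-D(x_i, x)/sigma)``; requires A >= 0."""
        if A < 0:
            raise ValueError("input amplitude A must be non-negative")
        return A * self.firing_rates(x)

    def center_distances(self) -> np.ndarray:
        """Geodesic ``(M, M)`` distance matrix between preferential locations."""
        rows = np.array([r for r, _ in self.center_cells])
        cols = np.array([c for _, c in self.center_cells])
        return self.cell_dist[:, rows, cols]

    def population_vector(self, rates: np.ndarray) -> np.ndarray:
        return population_vector(rates, self.centers)

    def local_population_vector(self, rates: np.ndarray,
                                radius: float = 1.0) -> np.ndarray:
        """Position of the *dominant* activity bump.

        The plain population vector is the centroid of all activity: when
        two bumps coexist (e.g. a look-ahead wave plus the re-ignited bump
        at the animal), the centroid lies between them and tracks neither.
        Restricting the activity-weighted mean to cells within ``radius``
        (geodesic) of the most active cell decodes the strongest bump.
        """
        rates = np.asarray(rates, dtype=float)
        k = int(np.argmax(rates))
        if rates[k] <= 0:
            raise AllSilentError(
                "population vector undefined for an all-zero rate vector")
        kr, kc = self.center_cells[k]
        local = rates * (self.cell_dist[:, kr, kc] <= radius)
        return population_vector(local, self.centers)


def population_vector(rates: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Activity-weighted mean of field centers, ``sum(r_i x_i) / sum(r_i)``.

    The normalization makes the read-out commensurable with positions in
    metres regardless of total activity.  Raises :class:`AllSilentError`
    when the rate vector carries no activity (undefined position).
    """
    rates = np.asarray(rates, dtype=float)
    total = rates.sum()
    if not np.isfinite(total) or total <= 0:
        raise AllSilentError("population vector undefined for an all-zero rate vector")
    return (rates @ np.asarray(centers, dtype=float)) / total
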