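"""Grid mazes and geodesic (shortest-path) distances.

A maze is a rectangular grid of square cells of side ``spacing`` metres.
Walls are represented as blocked cells (one cell thick).  Distances between
cells are computed on the 4-connected free-cell graph by breadth-first
search (the Lee routing algorithm), so they are shortest *around-wall* path
lengths in multiples of the grid pitch, not Euclidean distances.

Coordinate convention: origin at the south-west corner, x east, y north,
positions in metres.  Grid cell ``(row, col)`` covers the half-open square
``[col*spacing, (col+1)*spacing) x [row*spacing, (row+1)*spacing)`` and its
node position (used for place-field centers) is the cell center.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MazeLayout",
    "MazeSpecError",
    "UNREACHABLE",
    "build_layout",
    "layout_from_ascii",
    "layout_to_ascii",
    "layout_from_json",
    "layout_to_json",
    "bfs_distances",
    "geodesic_distance",
    "all_pairs_distances",
    "place_centers",
]

#: Marker for pairs of nodes in disconnected components.
UNREACHABLE = math.inf


class MazeSpecError(ValueError):
    """Raised when a maze specification is malformed or inconsistent."""


@dataclass(frozen=True)
class MazeLayout:
    """Validated grid-maze geometry.

    Parameters
    ----------
    width, height:
        Outer dimensions in metres; must be integer multiples of ``spacing``.
    spacing:
        Grid pitch in metres.
    blocked:
        Set of blocked ``(row, col)`` cells (walls).
    goal:
        Goal position ``(x, y)`` in metres; must lie on a free cell.
    name:
        Free-form label.
    """

    width: float
    height: float
    spacing: float
    blocked: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    goal: tuple[float, float] = (0.0, 0.0)
    name: str = "maze"

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise MazeSpecError("spacing must be positive")
        for dim, val in (("width", self.width), ("height", self.height)):
            n = val / self.spacing
            if val <= 0 or abs(n - round(n)) > 1e-9:
                raise MazeSpecError(
                    f"{dim}={val} is not a positive integer multiple of "
                    f"spacing={self.spacing}"
                )
        object.__setattr__(self, "blocked", frozenset(tuple(b) for b in self.blocked))
        for (r, c) in self.blocked:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise MazeSpecError(f"blocked cell ({r}, {c}) outside grid bounds")
        if len(self.blocked) >= self.n_rows * self.n_cols:
            raise MazeSpecError("maze has no free cell")
        gx, gy = self.goal
        if not (0 <= gx <= self.width and 0 <= gy <= self.height):
            raise MazeSpecError(f"goal {self.goal} outside maze bounds")
        if self.cell_of(self.goal) in self.blocked:
            raise MazeSpecError(f"goal {self.goal} lies on a blocked cell")

    # -- geometry helpers -------------------------------------------------

    @property
    def n_rows(self) -> int:
        return round(self.height / self.spacing)

    @property
    def n_cols(self) -> int:
        return round(self.width / self.spacing)

    def cell_of(self, pos: tuple[float, float]) -> tuple[int, int]:
        """Grid cell containing a continuous position (half-open membership)."""
        x, y = pos
        if not (0 <= x <= self.width and 0 <= y <= self.height):
            raise MazeSpecError(f"position {pos!r} outside maze bounds")
        col = min(int(x / self.spacing), self.n_cols - 1)
        row = min(int(y / self.spacing), self.n_rows - 1)
        return row, col

    def cell_center(self, cell: tuple[int, int]) -> tuple[float, float]:
        r, c = cell
        return ((c + 0.5) * self.spacing, (r + 0.5) * self.spacing)

    def is_free(self, cell: tuple[int, int]) -> bool:
        r, c = cell
        return (
            0 <= r < self.n_rows
            and 0 <= c < self.n_cols
            and (r, c) not in self.blocked
        )

    def free_cells(self) -> list[tuple[int, int]]:
        """Free cells in row-major order (row 0 = south)."""
        return [
            (r, c)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
            if (r, c) not in self.blocked
        ]

    def snap(self, pos: tuple[float, float]) -> tuple[int, int]:
        """Nearest free cell to a continuous position.

        Euclidean distance from the cell center, ties broken by lowest
        ``(row, col)``.  Raises if the position is outside the maze bounds.
        """
        x, y = pos
        if not (0 <= x <= self.width and 0 <= y <= self.height):
            raise MazeSpecError(f"position {pos!r} outside maze bounds")
        cell = self.cell_of(pos)
        if self.is_free(cell):
            return cell
        best, best_d2 = None, math.inf
        for (r, c) in self.free_cells():
            cx, cy = self.cell_center((r, c))
            d2 = (cx - x) ** 2 + (cy - y) ** 2
            if d2 < best_d2 - 1e-12:
                best, best_d2 = (r, c), d2
        assert best is not None
        return best

    def with_goal(self, goal: tuple[float, float]) -> "MazeLayout":
        return MazeLayout(self.width, self.height, self.spacing,
                          self.blocked, tuple(goal), self.name)

    def with_blocked(self, blocked, name: str | None = None) -> "MazeLayout":
        return MazeLayout(self.width, self.height, self.spacing,
                          frozenset(blocked), self.goal,
                          self.name if name is None else name)


# -- readers / writers ----------------------------------------------------

def build_layout(spec: dict) -> MazeLayout:
    """Build a validated :class:`MazeLayout` from a JSON-style mapping.

    Expected keys: ``name, width, height, spacing, goal: [x, y],
    blocked: [[row, col], ...]``.
    """
    required = ("width", "height", "spacing", "goal")
    for key in required:
        if key not in spec:
            raise MazeSpecError(f"maze spec missing required field {key!r}")
    try:
        goal = (float(spec["goal"][0]), float(spec["goal"][1]))
    except (TypeError, ValueError, IndexError) as exc:
        raise MazeSpecError(f"malformed field 'goal': {spec['goal']!r}") from exc
    blocked = []
    for item in spec.get("blocked", []):
        try:
            r, c = int(item[0]), int(item[1])
        except (TypeError, ValueError, IndexError) as exc:
            raise MazeSpecError(f"malformed entry in field 'blocked': {item!r}") from exc
        blocked.append((r, c))
    return MazeLayout(
        width=float(spec["width"]),
        height=float(spec["height"]),
        spacing=float(spec["spacing"]),
        blocked=frozenset(blocked),
        goal=goal,
        name=str(spec.get("name", "maze")),
    )


def layout_from_json(text: str) -> MazeLayout:
    return build_layout(json.loads(text))


def layout_to_json(layout: MazeLayout) -> str:
    doc = {
        "name": layout.name,
        "width": layout.width,
        "height": layout.height,
        "spacing": layout.spacing,
        "goal": list(layout.goal),
        "blocked": sorted(list(b) for b in layout.blocked),
    }
    return json.dumps(doc, indent=1)


def layout_from_ascii(art: str, spacing: float, name: str = "maze") -> MazeLayout:
    """Parse an ASCII-art maze: '#' blocked, '.' free, 'G' goal cell.

    The first text line is the *northmost* row; all lines must have equal
    length.  The goal is placed at the center of the 'G' cell.
    """
    lines = [ln for ln in art.strip("\n").splitlines()]
    if not lines:
        raise MazeSpecError("empty ASCII maze")
    width_cells = len(lines[0])
    if any(len(ln) != width_cells for ln in lines):
        raise MazeSpecError("ASCII maze rows have unequal lengths")
    n_rows = len(lines)
    blocked: set[tuple[int, int]] = set()
    goal_cell: tuple[int, int] | None = None
    for i, ln in enumerate(lines):
        row = n_rows - 1 - i  # text top line = north = highest row index
        for col, ch in enumerate(ln):
            if ch == "#":
                blocked.add((row, col))
            elif ch == "G":
                if goal_cell is not None:
                    raise MazeSpecError("ASCII maze has more than one goal cell")
                goal_cell = (row, col)
            elif ch != ".":
                raise MazeSpecError(f"unknown ASCII maze character {ch!r}")
    if goal_cell is None:
        raise MazeSpecError("ASCII maze has no goal cell 'G'")
    layout = MazeLayout(
        width=width_cells * spacing,
        height=n_rows * spacing,
        spacing=spacing,
        blocked=frozenset(blocked),
        goal=(0.0, 0.0),
        name=name,
    )
    return layout.with_goal(layout.cell_center(goal_cell))


def layout_to_ascii(layout: MazeLayout) -> str:
    goal_cell = layout.cell_of(layout.goal)
    lines = []
    for row in range(layout.n_rows - 1, -1, -1):
        chars = []
        for col in range(layout.n_cols):
            if (row, col) in layout.blocked:
                chars.append("#")
            elif (row, col) == goal_cell:
                chars.append("G")
            else:
                chars.append(".")
        lines.append("".join(chars))
    return "\n".join(lines)


# -- geodesics ------------------------------------------------------------

def bfs_distances(layout: MazeLayout, source: tuple[int, int]) -> np.ndarray:
    """Hop counts from ``source`` to every cell via 4-connected BFS.

    Returns an ``(n_rows, n_cols)`` array of hop counts; blocked or
    unreachable cells hold :data:`UNREACHABLE`.  Multiply by
    ``layout.spacing`` for metres.
    """
    if not layout.is_free(source):
        raise MazeSpecError(f"BFS source {source} is not a free cell")
    dist = np.full((layout.n_rows, layout.n_cols), UNREACHABLE)
    dist[source] = 0.0
    queue: deque[tuple[int, int]] = deque([source])
    while queue:
        r, c = queue.popleft()
        d = dist[r, c] + 1.0
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if layout.is_free((nr, nc)) and d < dist[nr, nc]:
                dist[nr, nc] = d
                queue.append((nr, nc))
    return dist


def geodesic_distance(
    layout: MazeLayout, a: tuple[float, float], b: tuple[float, float]
) -> float:
    """Shortest around-wall path length (m) between two positions.

    Positions are snapped to their nearest free cell; returns
    :data:`UNREACHABLE` for disconnected components.
    """
    na, nb = layout.snap(a), layout.snap(b)
    if na == nb:
        return 0.0
    return float(bfs_distances(layout, na)[nb] * layout.spacing)


def all_pairs_distances(layout: MazeLayout) -> np.ndarray:
    """Symmetric ``(M, M)`` matrix of geodesic distances (m) over free cells.

    Row/column order matches :func:`place_centers` (row-major free cells).
    """
    cells = layout.free_cells()
    rows = np.array([r for r, _ in cells])
    cols = np.array([c for _, c in cells])
    M = len(cells)
    out = np.full((M, M), UNREACHABLE)
    for k, cell in enumerate(cells):
        grid = bfs_distances(layout, cell)
        out[k, :] = grid[rows, cols]
    return out * layout.spacing


def place_centers(layout: MazeLayout) -> np.ndarray:
    """Centers (m) of all free cells in row-major order, shape ``(M, 2)``."""
    return np.array(
        [layout.cell_center(cell) for cell in layout.free_cells()], dtype=float
    ).reshape(-1, 2)
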