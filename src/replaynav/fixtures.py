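"""Built-in maze layouts for the four experiments, at desk scale.

These are hand-authored, reduced-scale approximations of the four maze
configurations used by the experiments (8 x 8 m, 0.4 m grid pitch, ~370
place cells): a three-chamber maze whose two internal walls each carry two
passages.  The *detour* layout closes one passage in each wall (the
south-west and the north-east one), forcing long ways around; the
*shortcut* layout then removes the right wall in three segments, opening a
direct route from the east chamber to the central goal.  The goal-changing
experiment reuses the base maze with the goal moved to the west chamber.

All four layouts share the grid shape, so a full-grid place population
(:meth:`~replaynav.place_code.PlacePopulation.from_grid`) keeps cell
identities across layout changes.
"""

from __future__ import annotations

from .maze_geometry import MazeLayout, layout_from_ascii

__all__ = [
    "goal_fixed_layout", "goal_changing_layout", "detour_layout",
    "shortcut_layout", "DESK_SPACING",
]

DESK_SPACING = 0.4  # m

# 20 x 20 cells; first line is the north edge. '#': wall, 'G': goal cell.
# Each internal wall spans rows 4..15 and leaves a 4-cell (1.6 m) passage
# at both ends -- wide enough for the activity bump to replay through.
_BASE = """\
....................
....................
....................
....................
......#......#......
......#......#......
......#......#......
......#......#......
......#......#......
......#...G..#......
......#......#......
......#......#......
......#......#......
......#......#......
......#......#......
......#......#......
....................
....................
....................
....................
"""

# Detour: the south passage of the west wall and the north passage of the
# east wall are closed (two critical passages).
_DETOUR = """\
.............#......
.............#......
.............#......
.............#......
......#......#......
......#......#......
......#......#......
......#......#......
......#......#......
......#...G..#......
......#......#......
......#......#......
......#......#......
......#......#......
......#......#......
......#......#......
......#.............
......#.............
......#.............
......#.............
"""

# Shortcut: the east wall of the detour maze is removed in three segments
# (rows 4..7, 8..11, 12..15 of column 13); its closed north passage stays.
_SHORTCUT = """\
.............#......
.............#......
.............#......
.............#......
......#.............
......#.............
......#.............
......#.............
......#.............
......#...G.........
......#.............
......#.............
......#.............
......#.............
......#.............
......#.............
......#.............
......#.............
......#.............
......#.............
"""


def goal_fixed_layout(spacing: float = DESK_SPACING) -> MazeLayout:
    """Base maze with the goal in the central chamber."""
    return layout_from_ascii(_BASE, spacing, name="goal_fixed")


def goal_changing_layout(spacing: float = DESK_SPACING) -> MazeLayout:
    """Base maze with the goal moved to the south corridor."""
    layout = layout_from_ascii(_BASE, spacing, name="goal_changing")
    return layout.with_goal(layout.cell_center((2, 10)))


def detour_layout(spacing: float = DESK_SPACING) -> MazeLayout:
    """Base maze with two critical passages closed."""
    return layout_from_ascii(_DETOUR, spacing, name="detour")


def shortcut_layout(spacing: float = DESK_SPACING) -> MazeLayout:
    """Detour maze with the east wall removed in three segments."""
    return layout_from_ascii(_SHORTCUT, spacing, name="shortcut")


def upscale(layout: MazeLayout, factor: int,
            spacing: float | None = None) -> MazeLayout:
    """Refine a layout ``factor``-fold: each cell becomes a factor^2 block.

    Used by the full-scale profile to run the fixture topologies with a
    denser place-cell grid (walls become ``factor`` cells thick).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    spacing = layout.spacing / factor if spacing is None else spacing
    blocked = {
        (r * factor + i, c * factor + j)
        for (r, c) in layout.blocked
        for i in range(factor) for j in range(factor)
    }
    scale = factor * spacing / layout.spacing  # physical stretch factor
    return MazeLayout(
        width=layout.n_cols * factor * spacing,
        height=layout.n_rows * factor * spacing,
        spacing=spacing, blocked=frozenset(blocked),
        goal=(layout.goal[0] * scale, layout.goal[1] * scale),
        name=f"{layout.name}_x{factor}",
    )
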