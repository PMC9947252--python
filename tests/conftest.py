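import numpy as np
import pytest

from replaynav.maze_geometry import MazeLayout, layout_from_ascii
from replaynav.place_code import PlacePopulation


@pytest.fixture(scope="session")
def open_3x3():
    """3 x 3 open grid, 1 m pitch."""
    return MazeLayout(width=3.0, height=3.0, spacing=1.0, goal=(1.5, 1.5),
                      name="open3")


@pytest.fixture(scope="session")
def corridor_1x3():
    """1 x 3 corridor, 1 m pitch."""
    return MazeLayout(width=3.0, height=1.0, spacing=1.0, goal=(0.5, 0.5),
                      name="corridor")


@pytest.fixture(scope="session")
def walled_5x5():
    """5 x 5 maze with a wall stripe leaving one passage (south)."""
    art = """\
..#..
..#..
..#..
..#..
..G..
"""
    return layout_from_ascii(art, spacing=1.0, name="walled5")


@pytest.fixture(scope="session")
def sealed_chamber():
    """A maze with a fully sealed chamber in the north-east corner."""
    art = """\
...##
...#.
...##
.....
G....
"""
    return layout_from_ascii(art, spacing=1.0, name="sealed")


@pytest.fixture(scope="session")
def open_10x10():
    return MazeLayout(width=10.0, height=10.0, spacing=1.0, goal=(5.0, 5.0),
                      name="open10")


@pytest.fixture(scope="session")
def pop_5x5():
    """Place population on a 5 x 5 open maze, 0.5 m pitch, sigma 0.3."""
    layout = MazeLayout(width=2.5, height=2.5, spacing=0.5, goal=(1.25, 1.25),
                        name="open5")
    return PlacePopulation.from_layout(layout, sigma=0.3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
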