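"""Softmax planning, heading snap, kinematic movement, trial loop."""

import math

import numpy as np
import pytest

from replaynav.maze_geometry import MazeLayout, MazeSpecError, layout_from_ascii
from replaynav.replay_engine import SubTrajectory
from replaynav.navigation_agent import (HEADINGS, direction_probabilities,
                                        in_goal_region, move, select_heading,
                                        snap_to_heading)


def seg(direction, msn):
    direction = np.asarray(direction, dtype=float)
    return SubTrajectory(0.0, 0.1, direction / np.linalg.norm(direction),
                         msn, 0, 1)


class TestSoftmax:
    def test_equal_scores_uniform(self):
        segs = [seg([1, 0], 0.3)] * 4
        np.testing.assert_allclose(direction_probabilities(segs, 10.0), 0.25)

    def test_zero_beta_uniform(self, rng):
        segs = [seg([1, 0], s) for s in rng.uniform(0, 5, size=6)]
        np.testing.assert_allclose(direction_probabilities(segs, 0.0), 1 / 6)

    def test_two_option_logistic(self):
        # score gap 0.2 at beta 10: P = 1 / (1 + e^-2)
        segs = [seg([1, 0], 0.7), seg([0, 1], 0.5)]
        p = direction_probabilities(segs, 10.0)
        assert p[0] == pytest.approx(1 / (1 + math.exp(-2.0)))

    def test_shift_invariance(self, rng):
        scores = rng.uniform(0, 2, size=5)
        a = direction_probabilities([seg([1, 0], s) for s in scores], 10.0)
        b = direction_probabilities([seg([1, 0], s + 7.3) for s in scores], 10.0)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_sums_to_one(self, rng):
        for beta in [0.0, 1.0, 10.0, 100.0]:
            segs = [seg([1, 0], s) for s in rng.uniform(0, 1, size=7)]
            assert direction_probabilities(segs, beta).sum() == pytest.approx(1.0)

    def test_greediness_monotone(self, rng):
        scores = [0.1, 0.9, 0.4]
        segs = [seg([1, 0], s) for s in scores]
        p_best = [direction_probabilities(segs, b)[1] for b in [0, 1, 5, 10, 50]]
        assert all(a <= b + 1e-12 for a, b in zip(p_best[:-1], p_best[1:]))

    def test_empty_segments_signal(self):
        with pytest.raises(ValueError):
            direction_probabilities([], 10.0)


class TestHeadingSnap:
    def test_near_east(self):
        assert snap_to_heading(np.array([1.0, 0.01])) == 0

    def test_exact_northeast(self):
        assert snap_to_heading(np.array([1.0, 1.0]) / math.sqrt(2)) == 1

    @pytest.mark.parametrize("k", range(8))
    def test_all_compass_points_identity(self, k):
        assert snap_to_heading(HEADINGS[k]) == k

    def test_tie_snaps_counter_clockwise(self):
        # 22.5 degrees: exactly between east (0 deg) and north-east (45 deg)
        v = np.array([math.cos(math.radians(22.5)), math.sin(math.radians(22.5))])
        assert snap_to_heading(v) == 1

    def test_seeded_selection_reproducible(self, rng):
        segs = [seg([1, 0], 0.5), seg([0, 1], 0.5), seg([-1, 0], 0.5)]
        probs = direction_probabilities(segs, 10.0)
        picks1 = [select_heading(probs, segs, np.random.default_rng(5))
                  for _ in range(5)]
        picks2 = [select_heading(probs, segs, np.random.default_rng(5))
                  for _ in range(5)]
        assert picks1 == picks2


class TestMove:
    def test_open_field_east(self, open_10x10):
        path = move((2.0, 5.0), 0, 2.0, open_10x10, speed=0.5)
        np.testing.assert_allclose(path[-1], [3.0, 5.0], atol=1e-9)

    def test_stops_at_wall(self, walled_5x5):
        # heading east from (1.7, 4.5): wall stripe cell starts at x = 2.0
        path = move((1.7, 4.5), 0, 4.0, walled_5x5, speed=0.5)
        assert path[-1][0] <= 2.0
        assert path[-1][0] == pytest.approx(2.0, abs=0.01)

    def test_blocked_immediately_stays(self, walled_5x5):
        start = (1.999, 4.5)
        path = move(start, 0, 1.0, walled_5x5, speed=0.5)
        assert np.linalg.norm(path[-1] - np.array(start)) < 0.01

    def test_never_enters_blocked_cell(self, walled_5x5, rng):
        for _ in range(30):
            start_cell = walled_5x5.free_cells()[
                int(rng.integers(len(walled_5x5.free_cells())))]
            start = walled_5x5.cell_center(start_cell)
            heading = int(rng.integers(8))
            path = move(start, heading, 3.0, walled_5x5, speed=0.5)
            for p in path[:: max(1, len(path) // 50)]:
                assert walled_5x5.cell_of(tuple(p)) not in walled_5x5.blocked

    def test_no_diagonal_corner_cutting(self):
        # free SW and NE cells, blocked NW and SE: the NE diagonal would
        # cut the corner between the two walls
        layout = layout_from_ascii("#G\n.#", spacing=1.0)
        path = move((0.5, 0.5), 1, 3.0, layout, speed=0.5)
        assert np.linalg.norm(path[-1] - np.array([0.5, 0.5])) < 0.75

    def test_boundary_containment(self, open_3x3):
        path = move((2.5, 2.5), 2, 10.0, open_3x3, speed=0.5)  # north
        assert path[-1][1] <= 3.0


class TestGoalRegion:
    def test_disc(self):
        assert in_goal_region((0.4, 0.0), (0.0, 0.0), 0.5)
        assert not in_goal_region((0.4, 0.4), (0.0, 0.0), 0.5)

    def test_square_variant(self):
        assert in_goal_region((0.4, 0.4), (0.0, 0.0), 0.5, shape="square")
        assert not in_goal_region((0.6, 0.0), (0.0, 0.0), 0.5, shape="square")


class TestTrialLoop:
    def test_start_inside_goal_immediate_success(self, open_3x3):
        from replaynav.attractor_network import CANParams
        from replaynav.navigation_agent import (DecisionPolicy,
                                                NavigationModel,
                                                run_test_trial)
        from replaynav.place_code import PlacePopulation
        pop = PlacePopulation.from_layout(open_3x3, sigma=0.3)
        model = NavigationModel(pop, np.zeros((9, 9)), np.zeros(9), CANParams())
        res = run_test_trial((1.4, 1.4), DecisionPolicy(), model, open_3x3)
        assert res.success and res.time_to_goal == 0.0 and res.n_plans == 0

    def test_zero_budget_failure(self, open_3x3):
        from replaynav.attractor_network import CANParams
        from replaynav.navigation_agent import (DecisionPolicy,
                                                NavigationModel,
                                                run_test_trial)
        from replaynav.place_code import PlacePopulation
        pop = PlacePopulation.from_layout(open_3x3, sigma=0.3)
        model = NavigationModel(pop, np.zeros((9, 9)), np.zeros(9), CANParams())
        res = run_test_trial((0.5, 0.5), DecisionPolicy(), model, open_3x3,
                             max_duration=0.0)
        assert not res.success and res.n_plans == 0

    def test_blocked_start_rejected(self, walled_5x5):
        from replaynav.attractor_network import CANParams
        from replaynav.navigation_agent import (DecisionPolicy,
                                                NavigationModel,
                                                run_test_trial)
        from replaynav.place_code import PlacePopulation
        pop = PlacePopulation.from_layout(walled_5x5, sigma=0.3)
        M = pop.n_cells
        model = NavigationModel(pop, np.zeros((M, M)), np.zeros(M), CANParams())
        with pytest.raises(MazeSpecError):
            run_test_trial((2.5, 2.5), DecisionPolicy(), model, walled_5x5)


class TestExploration:
    def test_positions_stay_free_and_cover(self, walled_5x5, rng):
        from replaynav.navigation_agent import exploration_trial
        pos = exploration_trial(walled_5x5, 30.0, rng)
        assert len(pos) == int(30.0 / 0.02)
        for p in pos[::7]:
            assert walled_5x5.cell_of(tuple(p)) not in walled_5x5.blocked
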