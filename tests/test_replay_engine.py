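"""Replay generation and sub-trajectory segmentation."""

import numpy as np
import pytest

from replaynav.attractor_network import CANParams
from replaynav.place_code import PlacePopulation
from replaynav.replay_engine import (ReplayTrace, awake_replay, node_coverage,
                                     rest_replay, segment_subtrajectories)


def make_trace(positions, stride=0.01, n_cells=3):
    positions = np.asarray(positions, dtype=float)
    times = np.arange(len(positions)) * stride
    rates = np.ones((len(positions), n_cells))
    return ReplayTrace(times, positions, rates, "awake")


class TestSegmentation:
    def test_never_exits_empty(self):
        trace = make_trace([[0, 0]] * 20)
        assert segment_subtrajectories(trace, (0, 0), d=0.5) == []

    def test_short_trace_empty(self):
        trace = make_trace([[0, 0]])
        assert segment_subtrajectories(trace, (0, 0), d=0.5) == []

    def test_single_excursion_direction(self):
        path = [[0, 0], [0.2, 0], [0.6, 0], [1.0, 0], [0.6, 0], [0.1, 0]]
        segs = segment_subtrajectories(make_trace(path), (0, 0), d=0.5)
        assert len(segs) == 1
        seg = segs[0]
        np.testing.assert_allclose(seg.direction, [1.0, 0.0])
        assert seg.t0 == pytest.approx(0.02)
        assert seg.t1 == pytest.approx(0.05)

    def test_three_excursions_match_bruteforce(self):
        """Three constructed excursions east, north, west; boundaries from
        an independent threshold-crossing scan."""
        x = np.array([0.0, 0.0])
        d = 0.5
        path = ([[0, 0], [1, 0], [0.8, 0], [0, 0]]        # east
                + [[0, 0.1], [0, 0.9], [0.2, 0.2]]        # north
                + [[-0.9, 0], [-1.5, 0], [0.1, 0]])       # west
        trace = make_trace(path)
        segs = segment_subtrajectories(trace, tuple(x), d)
        # brute-force scan
        outside = [bool(np.linalg.norm(np.asarray(p) - x) >= d) for p in path]
        expected = []
        i = 0
        while i < len(path):
            if outside[i]:
                j = i
                while j < len(path) and outside[j]:
                    j += 1
                expected.append((i, min(j, len(path) - 1)))
                i = j
            else:
                i += 1
        assert [(s.i0, s.i1) for s in segs] == expected
        dirs = [s.direction for s in segs]
        np.testing.assert_allclose(dirs[0], [1, 0])
        np.testing.assert_allclose(dirs[1], [0, 1])
        np.testing.assert_allclose(dirs[2], [-1, 0])

    def test_exit_points_at_least_d_away(self):
        rng = np.random.default_rng(0)
        path = rng.normal(0, 0.8, size=(200, 2))
        trace = make_trace(path)
        for seg in segment_subtrajectories(trace, (0, 0), d=0.5):
            assert np.linalg.norm(trace.positions[seg.i0]) >= 0.5
            np.testing.assert_allclose(np.linalg.norm(seg.direction), 1.0)

    def test_segments_ordered_and_disjoint(self):
        rng = np.random.default_rng(1)
        trace = make_trace(rng.normal(0, 0.8, size=(300, 2)))
        segs = segment_subtrajectories(trace, (0, 0), d=0.5)
        assert len(segs) > 1
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.t0 < a.t1 <= b.t0

    def test_trailing_excursion_kept(self):
        path = [[0, 0], [0.2, 0], [0.9, 0], [1.5, 0]]
        segs = segment_subtrajectories(make_trace(path), (0, 0), d=0.5)
        assert len(segs) == 1
        assert segs[0].t1 == pytest.approx(0.03)  # closed at trace end

    def test_msn_max_excludes_reentry_sample(self):
        path = [[0, 0], [1, 0], [2, 0], [0, 0]]
        trace = make_trace(path, n_cells=1)
        trace.rates = np.array([[5.0], [1.0], [2.0], [9.0]])
        segs = segment_subtrajectories(trace, (0, 0), d=0.5,
                                       msn_weights=np.array([1.0]))
        assert segs[0].msn_max == pytest.approx(2.0)  # not 9.0 (home sample)

    def test_nan_positions_count_as_inside(self):
        path = np.array([[0, 0], [np.nan, np.nan], [1, 0], [0, 0]])
        segs = segment_subtrajectories(make_trace(path), (0, 0), d=0.5)
        assert [(s.i0, s.i1) for s in segs] == [(2, 3)]

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            segment_subtrajectories(make_trace([[0, 0]] * 3), (0, 0), d=0.0)


@pytest.fixture(scope="module")
def small_can():
    """Population + idealized learned coupling on a small open maze."""
    from replaynav.maze_geometry import MazeLayout
    from replaynav.plasticity_pc import (correlation_normalize,
                                         effective_coupling, scale_to_peak)
    layout = MazeLayout(4.0, 4.0, 0.4, goal=(2.0, 2.0), name="small")
    pop = PlacePopulation.from_layout(layout, sigma=0.3)
    R = pop.rates_at_cells(np.array(layout.free_cells()))
    J = (R.T @ R) / R.shape[0]
    C = effective_coupling(scale_to_peak(correlation_normalize(J), 2.5), -0.3)
    return layout, pop, C


class TestReplayRuns:
    def test_zero_duration_empty(self, small_can):
        layout, pop, C = small_can
        trace = rest_replay(C, pop, layout.goal, 0.0, CANParams())
        assert trace.n_samples == 0 and trace.warnings

    def test_zero_coupling_degenerate_warning(self, small_can):
        layout, pop, _ = small_can
        trace = rest_replay(np.zeros((pop.n_cells, pop.n_cells)), pop,
                            layout.goal, 3.0, CANParams())
        assert any("degenerate" in w for w in trace.warnings)

    def test_rest_replay_moves_and_conforms(self, small_can):
        layout, pop, C = small_can
        trace = rest_replay(C, pop, layout.goal, 5.0, CANParams())
        assert not trace.warnings
        p = trace.positions
        start = p[~np.isnan(p[:, 0])][0]
        dists = np.linalg.norm(p - start, axis=1)
        assert np.nanmax(dists) > 2 * 0.3  # moves beyond 2 sigma

    def test_awake_determinism(self, small_can):
        layout, pop, C = small_can
        a = awake_replay(C, pop, (1.0, 1.0), 0.5, 50.0, CANParams())
        b = awake_replay(C, pop, (1.0, 1.0), 0.5, 50.0, CANParams())
        np.testing.assert_array_equal(a.rates, b.rates)

    def test_awake_requires_positive_amplitude(self, small_can):
        layout, pop, C = small_can
        with pytest.raises(ValueError):
            awake_replay(C, pop, (1.0, 1.0), 0.5, 0.0, CANParams())

    def test_node_coverage_counts_snapped_nodes(self, small_can):
        layout, pop, _ = small_can
        center = layout.cell_center((5, 5))
        trace = make_trace([center] * 5)
        assert node_coverage(trace, layout) == pytest.approx(
            1 / len(layout.free_cells()))
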