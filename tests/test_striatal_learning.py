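"""MSN/goal-cell read-outs and the three-factor learning rule."""

import math

import numpy as np
import pytest

from replaynav.maze_geometry import MazeLayout
from replaynav.place_code import PlacePopulation
from replaynav.striatal_learning import (DopamineSignal, MSNDivergenceError,
                                         ReplayLearner, StriatalParams,
                                         accumulating_trace_variant, dopamine,
                                         goal_activity, goal_weights,
                                         msn_activity, update_goal_weights,
                                         update_msn_weights, update_trace)


@pytest.fixture
def params():
    return StriatalParams()


class TestReadouts:
    def test_msn_linear(self, rng):
        W, r = rng.uniform(size=7), rng.uniform(size=7)
        assert msn_activity(W, r) == pytest.approx(float(W @ r))
        assert msn_activity(W, 2 * r) == pytest.approx(2 * msn_activity(W, r))
        assert msn_activity(np.zeros(7), r) == 0.0

    def test_msn_projection(self):
        W = np.zeros(4); W[2] = 1.0
        r = np.array([0.1, 0.2, 0.7, 0.4])
        assert msn_activity(W, r) == pytest.approx(0.7)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            msn_activity(np.ones(3), np.ones(4))
        with pytest.raises(ValueError):
            goal_activity(np.ones(3), np.ones(4))

    def test_goal_weights_unity_at_goal(self, pop_5x5):
        U = goal_weights(pop_5x5, (1.25, 1.25), xi=0.3)
        i = pop_5x5.center_cells.index(pop_5x5.layout.snap((1.25, 1.25)))
        assert U[i] == pytest.approx(1.0)

    def test_goal_weights_one_xi(self, pop_5x5):
        U = goal_weights(pop_5x5, tuple(pop_5x5.centers[0]), xi=0.5)
        assert U[1] == pytest.approx(math.exp(-1.0))  # neighbour at 0.5 m

    def test_goal_weights_follow_walls(self, walled_5x5):
        """U decays along the around-wall path, not across the stripe."""
        pop = PlacePopulation.from_layout(walled_5x5, sigma=0.3)
        U = goal_weights(pop, (1.5, 4.5), xi=0.3)
        D = pop.distances_to((1.5, 4.5))
        np.testing.assert_allclose(U, np.exp(-D / 0.3))
        i_across = pop.center_cells.index((4, 3))
        assert U[i_across] < math.exp(-5)  # euclid gap is only 2 m

    def test_goal_bump_beats_far_bump(self, pop_5x5):
        U = goal_weights(pop_5x5, (1.25, 1.25), xi=0.3)
        r_goal = pop_5x5.firing_rates((1.25, 1.25))
        r_far = pop_5x5.firing_rates((0.25, 0.25))
        assert goal_activity(U, r_goal) > goal_activity(U, r_far)


class TestTrace:
    def test_replacing_assignment(self, params):
        z = np.array([0.9, 0.0])
        r = np.array([1.0, 0.0])
        out = update_trace(z, r, V=0.5, params=params, dt=0.001)
        assert out[0] == pytest.approx(0.5)  # replaced, not accumulated

    def test_decay_branch_exact_exponential(self, params):
        z = np.array([1.0])
        out = update_trace(z, np.zeros(1), V=0.0, params=params,
                           dt=params.tau_z)
        assert out[0] == pytest.approx(math.exp(-1.0))

    def test_boundary_equality_decays(self, params):
        # r*V == q exactly: the co-firing indicator is strict '>'
        z = np.array([1.0])
        r = np.array([1.0])
        out = update_trace(z, r, V=params.q, params=params, dt=0.001)
        assert out[0] < 1.0

    def test_accumulating_variant_steady_state(self, params):
        """Constant drive c: z converges to c * tau_z."""
        z = np.zeros(1)
        c = 0.8
        for _ in range(20000):
            z = accumulating_trace_variant(z, np.array([1.0]), c, params,
                                           dt=0.001)
        assert z[0] == pytest.approx(c * params.tau_z, rel=1e-2)

    def test_accumulating_accumulates_replacing_does_not(self, params):
        r, V = np.array([1.0]), 1.0
        z_rep = update_trace(np.zeros(1), r, V, params, 0.001)
        z_rep2 = update_trace(z_rep, r, V, params, 0.001)
        z_acc = accumulating_trace_variant(np.zeros(1), r, V, params, 0.001)
        z_acc2 = accumulating_trace_variant(z_acc, r, V, params, 0.001)
        assert z_rep2[0] == pytest.approx(z_rep[0])
        assert z_acc2[0] > z_acc[0] * 1.5


class TestDopamine:
    def test_constant_v_no_goal(self):
        assert dopamine(0.0, 1.0, 1.0, 0.001).delta == 0.0

    def test_arithmetic(self):
        sig = dopamine(2.0, 0.0, 1.0, 1.0)
        assert sig.delta == pytest.approx(1.0)
        assert sig.G == 2.0 and sig.V_dot == -1.0

    def test_first_step_derivative_zero(self):
        sig = dopamine(1.5, 7.0, None, 0.001)
        assert sig.V_dot == 0.0 and sig.delta == 1.5

    def test_decomposition_invariant(self, rng):
        for _ in range(10):
            G, Vn, Vp = rng.normal(size=3)
            sig = dopamine(G, Vn, Vp, 0.01)
            assert sig.delta == pytest.approx(sig.G + sig.V_dot)


class TestWeightUpdates:
    def test_zero_delta_no_change(self, params):
        W = np.ones(3)
        out = update_msn_weights(W, np.ones(3), DopamineSignal(0, 0, 0),
                                 params, 0.001)
        np.testing.assert_array_equal(out, W)

    def test_zero_trace_no_change(self, params):
        W = np.ones(3)
        out = update_msn_weights(W, np.zeros(3), DopamineSignal(5, 5, 0),
                                 params, 0.001)
        np.testing.assert_array_equal(out, W)

    def test_continuous_time_step_size(self):
        params = StriatalParams(alpha2=0.01)
        out = update_msn_weights(np.zeros(1), np.ones(1),
                                 DopamineSignal(1.0, 1.0, 0.0), params, 0.001)
        assert out[0] == pytest.approx(1e-5)

    def test_per_step_interpretation(self):
        params = StriatalParams(alpha2=0.01, alpha2_per_step=True)
        out = update_msn_weights(np.zeros(1), np.ones(1),
                                 DopamineSignal(1.0, 1.0, 0.0), params, 0.001)
        assert out[0] == pytest.approx(0.01)

    def test_divergence_raises(self, params):
        with pytest.raises(MSNDivergenceError):
            update_msn_weights(np.array([1e308]), np.array([1e308]),
                               DopamineSignal(1e308, 1e308, 0), params, 1.0)

    def test_goal_weight_rule(self, rng):
        U = rng.uniform(size=5)
        r = rng.uniform(size=5)
        np.testing.assert_array_equal(update_goal_weights(U, r, False, 0.5), U)
        np.testing.assert_allclose(update_goal_weights(U, r, True, 1.0), r)

    def test_goal_weights_converge_exponentially(self, rng):
        """n rewarded visits at the same place: U -> r with residual
        (1-alpha3)^n, the closed form of the exponential average."""
        U0 = rng.uniform(size=4)
        r = rng.uniform(size=4)
        alpha3, n = 0.2, 25
        U = U0.copy()
        for _ in range(n):
            U = update_goal_weights(U, r, True, alpha3)
        np.testing.assert_allclose(U, r + (1 - alpha3) ** n * (U0 - r))


class TestReplayLearner:
    def test_bootstrap_requires_baseline(self, pop_5x5):
        """With v0 = 0 and W = 0 the co-firing trace never crosses
        threshold and the weights stay frozen; the tonic baseline breaks
        the deadlock."""
        r = pop_5x5.firing_rates((1.25, 1.25))
        U = goal_weights(pop_5x5, (1.25, 1.25), xi=0.3)
        frozen = ReplayLearner(np.zeros(pop_5x5.n_cells), U,
                               StriatalParams(v0=0.0), dt=0.001)
        alive = ReplayLearner(np.zeros(pop_5x5.n_cells), U,
                              StriatalParams(v0=1.0), dt=0.001)
        for k in range(100):
            frozen(k + 1, r, r)
            alive(k + 1, r, r)
        assert np.all(frozen.W == 0.0)
        assert alive.W.max() > 0.0

    def test_reset_trace_clears_state(self, pop_5x5):
        r = pop_5x5.firing_rates((0.3, 0.3))
        U = goal_weights(pop_5x5, (1.25, 1.25), xi=0.3)
        learner = ReplayLearner(np.zeros(pop_5x5.n_cells), U,
                                StriatalParams(), dt=0.001)
        learner(1, r, r)
        assert learner.z.max() > 0
        learner.reset_trace()
        assert np.all(learner.z == 0)
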