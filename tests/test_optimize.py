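"""Metaheuristic core: chaotic init, time control, JSO/WaOA moves."""

import numpy as np
import pytest

from mitodet.optimize import (
    JSOParams, SearchBounds, SwarmState, chaotic_init, hybrid_minimize,
    jso_step, time_control, waoa_escape, waoa_feed, waoa_migrate,
    _wrap_bounds,
)

UNIT = SearchBounds(np.zeros(3), np.ones(3))


def sphere(x):
    return float(np.sum(np.square(x)))


def make_state(positions, objective=sphere, bounds=UNIT, t=1, t_max=10):
    state = SwarmState.from_positions(np.asarray(positions, float), bounds,
                                      objective, t_max=t_max)
    state.t = t
    return state


class TestChaoticInit:
    def test_first_logistic_iterate(self):
        pos = chaotic_init(2, SearchBounds([0.0], [1.0]), JSOParams(q0=0.3))
        assert pos[0, 0] == pytest.approx(4 * 0.3 * 0.7)  # 0.84

    def test_degenerate_seed_rejected(self):
        with pytest.raises(ValueError, match="q0"):
            JSOParams(q0=0.5)
        with pytest.raises(ValueError, match="q0"):
            JSOParams(q0=0.75)

    def test_positions_within_bounds(self):
        bounds = SearchBounds(np.array([-2.0, 5.0]), np.array([3.0, 6.0]))
        pos = chaotic_init(20, bounds, JSOParams(q0=0.11))
        assert np.all(pos >= bounds.lb) and np.all(pos <= bounds.ub)


class TestTimeControl:
    def test_zero_at_final_iteration(self):
        rng = np.random.default_rng(0)
        assert all(time_control(50, 50, rng) == 0.0 for _ in range(20))

    def test_maximal_at_start_with_extreme_draw(self, stub_rng):
        assert time_control(0, 10, stub_rng(uniforms=[1.0])) == pytest.approx(1.0)

    def test_always_in_unit_interval(self):
        rng = np.random.default_rng(1)
        draws = [time_control(t, 100, rng) for t in range(101) for _ in range(100)]
        assert min(draws) >= 0.0 and max(draws) <= 1.0


class TestBoundaryWrap:
    def test_wrap_examples_match_hand_arithmetic(self):
        bounds = SearchBounds(np.zeros(2), np.ones(2))
        out = _wrap_bounds(np.array([1.2, -0.2]), bounds)
        assert out[0] == pytest.approx(0.2)  # (1.2 - 1) + 0
        assert out[1] == pytest.approx(0.8)  # (-0.2 - 0) + 1

    def test_wrap_always_lands_inside_bounds(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        bounds = SearchBounds(np.array([-1.0, 0.0]), np.array([1.0, 2.0]))

        @settings(max_examples=200, derandomize=True)
        @given(st.lists(st.floats(-50, 50), min_size=2, max_size=2))
        def check(coords):
            out = _wrap_bounds(np.array(coords), bounds)
            assert np.all(out >= bounds.lb) and np.all(out <= bounds.ub)

        check()


class TestJSOStep:
    def test_ocean_current_with_zero_r_is_identity(self, stub_rng):
        state = make_state([[0.2, 0.2, 0.2], [0.6, 0.6, 0.6]])
        before = state.positions.copy()
        # per agent: TCF draw 1.0 -> tcf=0.9 >= kappa; then r1=r2=0
        rng = stub_rng(uniforms=[1.0, 0, 0, 0, 0, 0, 0,
                                 1.0, 0, 0, 0, 0, 0, 0])
        jso_step(state, JSOParams(), sphere, rng)
        np.testing.assert_allclose(state.positions, before)

    def test_type_b_full_step_toward_fitter_partner(self, stub_rng):
        # two agents; agent 1 (worse) moves fully onto agent 0 with r=1
        state = make_state([[0.1, 0.1, 0.1], [0.9, 0.9, 0.9]], t=9, t_max=10)
        # agent 0: tcf from 0.5 -> |0.1*0| = 0 < kappa; gate draw 0.0 <= 1-tcf
        # -> type B; partner=1 (worse), r=0 -> stays.
        # agent 1: same path with r=1 -> lands on agent 0's position.
        rng = stub_rng(
            uniforms=[0.5, 0.0, 0.0, 0.0, 0.0,
                      0.5, 0.0, 1.0, 1.0, 1.0],
            integers=[0, 0],
        )
        jso_step(state, JSOParams(), sphere, rng)
        np.testing.assert_allclose(state.positions[1], [0.1, 0.1, 0.1])

    def test_non_finite_objective_never_accepted(self):
        calls = {"n": 0}

        def nasty(x):
            calls["n"] += 1
            return np.nan if calls["n"] > 2 else sphere(x)

        state = make_state([[0.4] * 3, [0.6] * 3], objective=nasty)
        before = state.positions.copy()
        jso_step(state, JSOParams(), nasty, np.random.default_rng(0))
        np.testing.assert_allclose(state.positions, before)


class TestWaOAPhases:
    def test_feed_zero_rand_is_identity(self, stub_rng):
        state = make_state([[0.3] * 3, [0.7] * 3])
        before = state.positions.copy()
        rng = stub_rng(uniforms=[0] * 6, integers=[1] * 6)
        waoa_feed(state, sphere, rng)
        np.testing.assert_allclose(state.positions, before)

    def test_agent_at_best_with_ri_one_stays(self, stub_rng):
        state = make_state([[0.2] * 3, [0.9] * 3])
        rng = stub_rng(uniforms=[0.8] * 3 + [0.0] * 3, integers=[1] * 6)
        waoa_feed(state, sphere, rng)
        # agent 0 IS the best: (Wst - 1*Z) = 0 -> no move for any rand
        np.testing.assert_allclose(state.positions[0], [0.2] * 3)

    def test_migrate_partner_copy_with_unit_rand(self, stub_rng):
        state = make_state([[0.2] * 3, [0.8] * 3])
        # agent 0: partner 1 worse, rand 0 -> stays
        # agent 1: partner 0 fitter, RI=1, rand=1 -> Z + (Z0 - Z) = Z0
        rng = stub_rng(uniforms=[0] * 3 + [1] * 3,
                       integers=[0] + [1] * 3 + [0] + [1] * 3)
        waoa_migrate(state, sphere, rng)
        np.testing.assert_allclose(state.positions[1], [0.2] * 3)

    def test_migrate_partner_never_self(self):
        rng = np.random.default_rng(4)
        state = make_state(np.linspace(0.1, 0.9, 15).reshape(5, 3))
        for _ in range(50):
            waoa_migrate(state, sphere, rng)  # would degenerate if l == i
        assert np.all(state.fitnesses >= 0)

    def test_escape_shrinking_neighborhood_bounded_by_t(self):
        bounds = SearchBounds(-np.ones(4), np.ones(4))
        rng = np.random.default_rng(8)
        state = SwarmState.from_positions(
            np.zeros((3, 4)) + 0.01, bounds, sphere, t_max=50
        )
        state.t = 10
        before = state.positions.copy()
        waoa_escape(state, lambda x: -sphere(x), rng)  # force acceptance
        step = np.abs(state.positions - before)
        assert np.all(step <= 2.0 / 10 + 1e-12)

    def test_escape_accepts_only_improvements(self):
        state = make_state([[0.01] * 3, [0.02] * 3], t=1)
        rng = np.random.default_rng(3)
        f_before = state.fitnesses.copy()
        waoa_escape(state, sphere, rng)
        assert np.all(state.fitnesses <= f_before)

    def test_unknown_neighborhood_mode_rejected(self):
        state = make_state([[0.1] * 3, [0.2] * 3])
        with pytest.raises(ValueError, match="neighborhood_mode"):
            waoa_escape(state, sphere, np.random.default_rng(0), "bogus")


class TestInvariants:
    def test_greedy_best_monotone_on_random_quadratics(self):
        rng = np.random.default_rng(5)
        bounds = SearchBounds(-np.ones(4) * 3, np.ones(4) * 3)
        center = rng.normal(size=4)

        def quad(x):
            return float(np.sum((x - center) ** 2))

        state = SwarmState.from_positions(
            rng.uniform(-3, 3, size=(8, 4)), bounds, quad, t_max=100
        )
        best = state.best_fitness
        ops = [lambda s: jso_step(s, JSOParams(), quad, rng),
               lambda s: waoa_feed(s, quad, rng),
               lambda s: waoa_migrate(s, quad, rng),
               lambda s: waoa_escape(s, quad, rng)]
        for t in range(1, 101):
            state.t = min(t, 100)
            ops[t % 4](state)
            assert state.best_fitness <= best + 1e-15
            assert np.all(state.positions >= bounds.lb - 1e-12)
            assert np.all(state.positions <= bounds.ub + 1e-12)
            best = state.best_fitness

    def test_identical_seeds_identical_trajectories(self):
        bounds = SearchBounds(-np.ones(3), np.ones(3))
        s1, h1 = hybrid_minimize(sphere, bounds, n=6, iterations=20, seed=13)
        s2, h2 = hybrid_minimize(sphere, bounds, n=6, iterations=20, seed=13)
        assert np.array_equal(s1.positions, s2.positions)
        assert h1 == h2

    def test_hybrid_reduces_sphere_quickly(self):
        bounds = SearchBounds(np.full(5, -5.12), np.full(5, 5.12))
        state, hist = hybrid_minimize(sphere, bounds, n=20, iterations=50, seed=1)
        assert state.best_fitness < hist[0]
        assert state.best_fitness < 1e-2
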