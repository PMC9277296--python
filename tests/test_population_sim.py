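"""Closed-loop population simulator: draws, ratios, events, convergence."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ratiometric import (
    PopulationState,
    detect_events,
    draw_population,
    make_controller,
    ratio,
    simulate,
    steady_state_error,
    verify_event_equivalence,
)
from ratiometric.memory_model import CONTROLLABLE


class TestDrawPopulation:
    def test_same_seed_reproduces_draw(self):
        a = draw_population(400, ("uniform", 1, 5), ("normal", 0, 4), seed=7)
        b = draw_population(400, ("uniform", 1, 5), ("normal", 0, 4), seed=7)
        assert np.array_equal(a.eta, b.eta) and np.array_equal(a.x, b.x)
        assert a.n == 400

    def test_narrow_eta_range_is_fully_controllable(self):
        pop = draw_population(400, ("uniform", 1, 5), ("normal", 0, 4), seed=0)
        assert np.all(pop.controllability(5.0) == CONTROLLABLE)

    def test_variance_convention_for_normal_spec(self):
        pop = draw_population(20000, ("uniform", 1, 5), ("normal", 0, 4), seed=1)
        assert pop.x.std() == pytest.approx(2.0, rel=0.05)  # variance 4 -> std 2
        pop2 = draw_population(
            20000, ("uniform", 1, 5), {"kind": "normal", "mean": 0, "std": 4}, seed=1
        )
        assert pop2.x.std() == pytest.approx(4.0, rel=0.05)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            draw_population(0, ("uniform", 1, 5), ("normal", 0, 4), seed=0)
        with pytest.raises(ValueError):
            draw_population(10, ("uniform", 5, 1), ("normal", 0, 4), seed=0)


class TestRatio:
    @pytest.mark.parametrize("n_b,n,expected", [(200, 400, 0.5), (300, 400, 0.75), (0, 50, 0.0)])
    def test_group_fractions(self, n_b, n, expected):
        x = np.concatenate([-np.ones(n - n_b), np.ones(n_b)])
        state = PopulationState(x, np.ones(n))
        r_a, r_b = ratio(state)
        assert r_b == expected
        assert r_a + r_b == 1.0

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            PopulationState(np.array([]), np.array([]))


class TestOpenLoopAndForced:
    def test_open_loop_ratio_constant_no_events(self):
        pop = draw_population(200, ("uniform", 1, 5), ("normal", 0, 4), seed=3)
        traj = simulate(pop, "open_loop", 0.5, 0.5, dt=1e-3)
        assert traj.samples["r_B"].nunique() == 1
        assert traj.events == []
        assert verify_event_equivalence(traj).passed  # vacuous

    def test_saturating_input_sends_everyone_to_b(self):
        ctrl = make_controller({"kind": "constant", "u_max": 5.0, "u_const": 5.0})
        pop = draw_population(50, ("uniform", 1, 5), ("normal", 0, 4), seed=4)
        traj = simulate(pop, ctrl, 0.5, 3.0, dt=1e-3)
        assert traj.samples["r_B"].iloc[-1] == 1.0
        # independent per-cell oracle: 1-D integration of each cell alone
        pop2 = draw_population(50, ("uniform", 1, 5), ("normal", 0, 4), seed=4)
        for eta, x0 in zip(pop2.eta[:10], pop2.x[:10]):
            sol = solve_ivp(lambda t, x: eta * x - x**3 + 5.0, (0, 3.0), [x0], rtol=1e-8)
            assert sol.y[0, -1] > 0

    def test_zero_input_sign_invariance(self):
        # the origin separates the basins, so no cell can change group at u=0
        pop = draw_population(300, ("uniform", 0.5, 6), ("normal", 0, 1), seed=5)
        traj = simulate(pop, "open_loop", 0.5, 1.0, dt=1e-3)
        assert len(traj.events) == 0


class TestClosedLoop:
    def test_relay_shutdown_reaches_exact_zero_and_stays(self):
        pop = draw_population(400, ("uniform", 1, 5), ("normal", 0, 4), seed=11)
        traj = simulate(pop, {"kind": "relay_shutdown", "u_max": 5.0}, 0.5, 1.0)
        assert abs(traj.final_error) < 1 / 800
        e_after = [ev.e_after for ev in traj.events]
        mags = [abs(traj.meta["e0"])] + [abs(e) for e in e_after]
        assert all(b <= a + 1e-12 for a, b in zip(mags, mags[1:]))

    def test_error_quantized_in_steps_of_one_over_n(self):
        n = 400
        pop = draw_population(n, ("uniform", 1, 5), ("normal", 0, 4), seed=13)
        traj = simulate(pop, {"kind": "relay_bangbang", "u_max": 5.0}, 0.5, 0.5)
        assert len(traj.events) > 0
        es = np.array([traj.meta["e0"]] + [ev.e_after for ev in traj.events])
        steps = np.diff(es)
        assert np.allclose(np.abs(steps), 1.0 / n, atol=1e-12)

    def test_partition_conservation(self):
        pop = draw_population(150, ("uniform", -1, 14), ("normal", -2, 1), seed=17)
        traj = simulate(pop, {"kind": "pi", "u_max": 5.0, "k_p": 30, "k_i": 10}, 0.5, 1.0)
        s = traj.samples
        assert np.allclose(s["r_A"] + s["r_B"], 1.0)
        assert (s["N"] == 150).all()

    def test_event_times_nondecreasing(self):
        pop = draw_population(200, ("uniform", -1, 14), ("normal", -2, 1), seed=19)
        traj = simulate(pop, {"kind": "relay_shutdown", "u_max": 5.0}, 0.5, 1.5)
        times = [ev.time for ev in traj.events]
        assert all(b >= a for a, b in zip(times, times[1:]))

    def test_nonfinite_state_aborts_with_diagnostic(self):
        pop = PopulationState(np.array([5.0, -5.0]), np.array([5.0, 5.0]))
        with pytest.raises(FloatingPointError, match="non-finite"):
            simulate(pop, "open_loop", 0.5, 5.0, dt=1.0)

    def test_rejects_bad_arguments(self):
        pop = draw_population(10, ("uniform", 1, 5), ("normal", 0, 4), seed=0)
        with pytest.raises(ValueError):
            simulate(pop, "open_loop", 1.5, 1.0)
        with pytest.raises(ValueError):
            simulate(pop, "open_loop", 0.5, -1.0)


class TestDetectEvents:
    def test_single_monotone_crossing(self):
        t = np.linspace(0, 1, 11)
        x = np.linspace(-1, 1, 11)[:, None]
        events = detect_events(t, x)
        assert len(events) == 1
        assert events[0].direction == "A->B"

    def test_no_crossing_no_events(self):
        t = np.linspace(0, 1, 5)
        x = np.full((5, 3), -0.5)
        assert detect_events(t, x) == []

    def test_matches_inline_event_log(self):
        pop = draw_population(60, ("uniform", 1, 5), ("normal", 0, 4), seed=23)
        traj = simulate(pop, {"kind": "relay_shutdown", "u_max": 5.0}, 0.3, 0.5,
                        record_dense=True)
        redetected = detect_events(traj.meta["dense_t"], traj.meta["dense_x"])
        assert [(e.cell_id, e.direction) for e in redetected] == [
            (e.cell_id, e.direction) for e in traj.events
        ]


class TestSteadyStateError:
    def test_constant_error(self):
        pop = draw_population(20, ("uniform", 1, 5), ("normal", 0, 4), seed=29)
        traj = simulate(pop, "open_loop", 0.5, 0.2, dt=1e-3)
        traj.samples["e"] = 0.05
        assert steady_state_error(traj, 0.5) == pytest.approx(0.05)

    def test_symmetric_oscillation_averages_out(self):
        pop = draw_population(20, ("uniform", 1, 5), ("normal", 0, 4), seed=29)
        traj = simulate(pop, "open_loop", 0.5, 0.2, dt=1e-3)
        n = len(traj.samples)
        traj.samples["e"] = np.where(np.arange(n) % 2 == 0, 1 / 20, -1 / 20)
        assert steady_state_error(traj, 1.0) <= 1 / 20 / (n // 2)

    def test_window_fraction_validated(self):
        pop = draw_population(20, ("uniform", 1, 5), ("normal", 0, 4), seed=29)
        traj = simulate(pop, "open_loop", 0.5, 0.1, dt=1e-2)
        with pytest.raises(ValueError):
            steady_state_error(traj, 0.0)
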