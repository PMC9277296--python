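"""Toggle-switch chamber: single-cell dynamics, actuation, population rules."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ratiometric.toggle_consortium import (
    ActuationConstraints,
    Chamber,
    ToggleParams,
    actuate_dial_a_wave,
    actuate_t_junction,
    classify_phenotype,
    reference_states,
    run_closed_loop,
    step_chamber,
    toggle_derivatives,
)

PARAMS = ToggleParams()


def integrate_cell(y0, u_aTc, u_IPTG, minutes, dt=0.5):
    y = np.asarray([y0], dtype=float)
    for _ in range(int(minutes / dt)):
        k1 = toggle_derivatives(y, u_aTc, u_IPTG, PARAMS)
        k2 = toggle_derivatives(y + dt / 2 * k1, u_aTc, u_IPTG, PARAMS)
        k3 = toggle_derivatives(y + dt / 2 * k2, u_aTc, u_IPTG, PARAMS)
        k4 = toggle_derivatives(y + dt * k3, u_aTc, u_IPTG, PARAMS)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y[0]


class TestSingleCellDynamics:
    def test_two_distinct_attractors_at_zero_input(self):
        ref = reference_states()
        assert ref["LacI_high"] > 5 * ref["LacI_low"]
        assert ref["TetR_high"] > 5 * ref["TetR_low"]
        # both attractors persist under perturbed restarts
        y = integrate_cell(ref["A_state"] * 1.3, 0.0, 0.0, 1000)
        assert not classify_phenotype(y, ref)
        y = integrate_cell(ref["B_state"] * 1.3, 0.0, 0.0, 1000)
        assert classify_phenotype(y, ref)

    def test_saturating_aTc_drives_LacI_high(self):
        ref = reference_states()
        y = integrate_cell(ref["B_state"], 60.0, 0.0, 600)
        assert not classify_phenotype(y, ref)  # state A

    def test_saturating_IPTG_drives_TetR_high(self):
        ref = reference_states()
        y = integrate_cell(ref["A_state"], 0.0, 0.5, 600)
        assert classify_phenotype(y, ref)  # state B

    def test_derivatives_reject_negative_inputs(self):
        with pytest.raises(ValueError):
            toggle_derivatives(np.zeros(6), -1.0, 0.0)


class TestClassification:
    def test_high_LacI_is_A_high_TetR_is_B(self):
        ref = reference_states()
        a = np.array([0, 0, ref["LacI_high"], ref["TetR_low"], 0, 0], dtype=float)
        b = np.array([0, 0, ref["LacI_low"], ref["TetR_high"], 0, 0], dtype=float)
        assert not classify_phenotype(a, ref)
        assert classify_phenotype(b, ref)

    def test_exact_tie_keeps_previous_label(self):
        ref = reference_states()
        tie = np.array([[0, 0, ref["LacI_high"], ref["TetR_high"], 0, 0]], dtype=float)
        assert classify_phenotype(tie, ref, previous=np.array([True]))[0]
        assert not classify_phenotype(tie, ref, previous=np.array([False]))[0]


class TestActuation:
    CON_TJ = ActuationConstraints(U_aTc=60.0, U_IPTG=0.5, mode="t_junction")
    CON_DW = ActuationConstraints(U_aTc=100.0, U_IPTG=1.0, mode="dial_a_wave")

    @pytest.mark.parametrize(
        "u,expected", [(5.0, (0.0, 0.5)), (-5.0, (60.0, 0.0)), (0.0, (0.0, 0.0))]
    )
    def test_t_junction_levels(self, u, expected):
        assert actuate_t_junction(u, self.CON_TJ) == expected

    def test_t_junction_holds_during_dwell(self):
        prev = (0.0, 0.5)
        held = actuate_t_junction(-5.0, self.CON_TJ, prev=prev, elapsed=5.0)
        assert held == prev
        released = actuate_t_junction(-5.0, self.CON_TJ, prev=prev, elapsed=20.0)
        assert released == (60.0, 0.0)

    @given(u=st.floats(-5, 5, allow_nan=False))
    def test_t_junction_mutual_exclusivity(self, u):
        a, i = actuate_t_junction(u, self.CON_TJ)
        assert a * i == 0.0

    @pytest.mark.parametrize(
        "u,expected", [(0.0, (50.0, 0.5)), (5.0, (0.0, 1.0)), (-5.0, (100.0, 0.0))]
    )
    def test_dial_a_wave_levels(self, u, expected):
        out = actuate_dial_a_wave(u, 5.0, self.CON_DW)
        assert out == pytest.approx(expected)

    @given(u=st.floats(-5, 5, allow_nan=False))
    def test_dial_a_wave_convexity(self, u):
        a, i = actuate_dial_a_wave(u, 5.0, self.CON_DW)
        assert a / self.CON_DW.U_aTc + i / self.CON_DW.U_IPTG == pytest.approx(1.0)

    def test_constraint_validation(self):
        with pytest.raises(ValueError):
            ActuationConstraints(min_dwell=-1.0)
        with pytest.raises(ValueError):
            ActuationConstraints(mode="peristaltic")


class TestChamberPopulation:
    def test_flush_restores_capacity(self, rng):
        ch = Chamber(capacity=50, seed=rng).seed_cells(n=60)
        assert ch.n == 60
        step_chamber(ch, (0.0, 0.0), 0.5)
        assert ch.n == 50

    def test_no_divisions_in_short_step_keeps_count(self, rng):
        ch = Chamber(capacity=50, seed=rng).seed_cells(n=30)
        ch.length_fraction[:] = 0.0
        ch.step(0.0, 0.0, 0.5)
        assert ch.n == 30

    def test_growth_penalty_halves_division_rate(self):
        counts = {}
        for label, (ra, rb) in {"A": (0.5 / 42, 1 / 42), "B": (1 / 42, 1 / 42)}.items():
            ch = Chamber(capacity=4000, div_rate_A=ra, div_rate_B=rb,
                         noise_sigma=0.0, seed=7).seed_cells(n=400, frac_b=0.0)
            n0 = ch.n
            for _ in range(int(84 / 0.5)):
                ch.step(0.0, 0.0, 0.5)
            counts[label] = ch.n / n0
        # one doubling time at half rate vs two at full rate
        assert counts["A"] == pytest.approx(2.0, rel=0.1)
        assert counts["B"] == pytest.approx(4.0, rel=0.1)

    def test_extinct_chamber_aborts(self):
        ch = Chamber(capacity=10, seed=0)
        with pytest.raises(RuntimeError, match="extinct"):
            ch.step(0.0, 0.0, 0.5)

    def test_capacity_held_constant_once_reached(self, rng):
        ch = Chamber(capacity=40, seed=rng).seed_cells()
        con = ActuationConstraints(U_aTc=60.0, U_IPTG=0.5)
        traj = run_closed_loop(ch, con, r_d=0.5, t_end=300.0)
        assert (traj.samples["N"] == 40).all()

    def test_snapshot_and_cells_views(self, rng):
        ch = Chamber(capacity=20, seed=rng).seed_cells()
        snap = ch.snapshot()
        assert len(snap) == 20 and set(snap["label"]) <= {"A", "B"}
        assert len(ch.cells) == 20


class TestClosedLoopChamber:
    def test_relay_t_junction_regulates_near_target(self):
        ch = Chamber(capacity=100, seed=42).seed_cells()
        con = ActuationConstraints(U_aTc=60.0, U_IPTG=0.5, mode="t_junction")
        traj = run_closed_loop(ch, con, r_d=0.5, t_end=1200.0)
        e = traj.samples["e"].to_numpy()
        tail = e[len(e) // 2:]
        assert abs(tail.mean()) < 0.2
        # T-junction exclusivity holds along the whole run
        assert (traj.samples["u_aTc"] * traj.samples["u_IPTG"] == 0.0).all()

    def test_pi_dial_a_wave_runs_and_stays_convex(self):
        ch = Chamber(capacity=100, seed=43).seed_cells()
        con = ActuationConstraints(U_aTc=100.0, U_IPTG=1.0, mode="dial_a_wave")
        traj = run_closed_loop(ch, con, r_d=0.5, t_end=600.0, controller="pi")
        s = traj.samples.iloc[1:]  # inputs reach the cells after the first delay
        conv = s["u_aTc"] / 100.0 + s["u_IPTG"] / 1.0
        assert np.allclose(conv[conv > 0], 1.0)

    def test_open_loop_final_ratio_depends_on_initial_conditions(self):
        con = ActuationConstraints(U_aTc=60.0, U_IPTG=0.5)
        finals = []
        for frac_b in (0.2, 0.8):
            ch = Chamber(capacity=100, seed=5).seed_cells(frac_b=frac_b)
            traj = run_closed_loop(ch, con, r_d=0.5, t_end=600.0, dead_zone=1.0)
            finals.append(traj.samples["r_B"].iloc[-1])
        assert abs(finals[0] - finals[1]) > 0.15

    def test_cell_variability_does_not_break_regulation(self):
        ch = Chamber(capacity=100, param_cv=0.2, seed=44).seed_cells()
        con = ActuationConstraints(U_aTc=60.0, U_IPTG=0.5)
        traj = run_closed_loop(ch, con, r_d=0.5, t_end=1200.0)
        e = traj.samples["e"].to_numpy()
        assert abs(e[len(e) // 2:].mean()) < 0.2
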