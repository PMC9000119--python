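"""Euler steppers, stability bound, accuracy norms, resume semantics."""

import math

import numpy as np
import pytest

from pacesim import (get_preset, simulate_cell, stability_check, error_norms,
                     step_forward_euler, step_backward_euler)
from pacesim.integrators import (IntegratorSpec, StateField, TissueModel,
                                 Trace, run_tissue)
from pacesim.models import PassiveParams, CT_DEFAULT
from pacesim.topology import build_single


def passive_node():
    op = build_single()
    model = TissueModel.from_regions(op, {0: PassiveParams()})
    return op, model


class TestForwardEuler:
    def test_zero_field_stays_zero(self):
        op, model = passive_node()
        state = StateField(np.zeros(1), np.zeros(1))
        step_forward_euler(state, model, op, dt=0.1)
        assert state.u[0] == 0.0

    def test_passive_step_hand_value(self):
        op, model = passive_node()
        state = StateField(np.ones(1), np.zeros(1))
        step_forward_euler(state, model, op, dt=0.1)
        assert state.u[0] == pytest.approx(1.0 - 0.1 * 26.0 / 12.9, rel=1e-14)

    def test_halving_dt_halves_local_error(self):
        # linear decay du/dt = -c*u: one-step error vs exp(-c*dt) is O(dt^2),
        # so the per-time local error rate halves with dt
        c = 26.0 / 12.9

        def end_error(dt):
            op, model = passive_node()
            state = StateField(np.ones(1), np.zeros(1))
            steps = int(round(1.0 / dt))
            for _ in range(steps):
                step_forward_euler(state, model, op, dt=dt)
            return abs(state.u[0] - math.exp(-c * 1.0))

        r = end_error(0.1) / end_error(0.05)
        assert 1.8 < r < 2.2

    def test_time_advances_by_counter(self):
        op, model = passive_node()
        state = StateField(np.ones(1), np.zeros(1))
        run_tissue(model, op, state, duration=10.0, dt=0.1, scheme="fe")
        assert state.time == pytest.approx(10.0, abs=1e-12)


class TestBackwardEuler:
    def test_linear_node_closed_form(self):
        op, model = passive_node()
        state = StateField(np.ones(1), np.zeros(1))
        spec = IntegratorSpec(scheme="be", dt=0.1)
        step_backward_euler(state, model, op, spec)
        assert state.u[0] == pytest.approx(
            1.0 / (1.0 + 0.1 * 26.0 * CT_DEFAULT), rel=1e-12)

    def test_agrees_with_fe_to_second_order(self):
        p = get_preset("pAP-0D")
        errs = []
        for dt in (0.1, 0.05):
            tf, _ = simulate_cell(p, 10 * dt, dt=dt, scheme="fe",
                                  state0=(0.3, 0.5), record_dt=10 * dt)
            tb, _ = simulate_cell(p, 10 * dt, dt=dt, scheme="be",
                                  state0=(0.3, 0.5), record_dt=10 * dt)
            errs.append(abs(tf.u[-1] - tb.u[-1]))
        # FE-BE gap shrinks ~ linearly in dt over a fixed horizon fraction
        assert errs[1] < 0.75 * errs[0]

    def test_stable_far_beyond_fe_bound(self):
        # stiff passive node: FE is stable only for dt < 2/(S*ct) ~ 1 ms;
        # BE at 100x that bound must decay monotonically
        op, model = passive_node()
        state = StateField(np.ones(1), np.zeros(1))
        spec = IntegratorSpec(scheme="be", dt=100.0)
        vals = [1.0]
        for _ in range(5):
            step_backward_euler(state, model, op, spec)
            vals.append(state.u[0])
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert vals[-1] >= 0.0

    def test_fe_and_be_frequencies_agree(self):
        p = get_preset("pAP-0D", b=0.05)
        tf, _ = simulate_cell(p, 30_000.0, dt=0.01, scheme="fe", record_dt=0.1)
        tb, _ = simulate_cell(p, 30_000.0, dt=0.01, scheme="be", record_dt=0.1)
        rep = error_norms(tb, tf, mode="frequency")
        assert rep.freq_err < 0.5


class TestStabilityCheck:
    def test_san_operating_point_passes(self):
        ok, margin = stability_check(0.160, 0.05, 0.002, N=2)
        assert ok
        assert margin == pytest.approx(0.128)

    def test_boundary_is_strict(self):
        # d*dt exactly 1/(2N) fails
        ok, margin = stability_check(1.0, 1.0, 0.25, N=2)
        assert margin == pytest.approx(0.25)
        assert not ok

    def test_dimension_scaling(self):
        # N = 1 admits exactly twice the dt of N = 2 at fixed d
        ok1, _ = stability_check(1.0, 1.0, 0.49, N=1)
        ok2, _ = stability_check(1.0, 1.0, 0.49, N=2)
        assert ok1 and not ok2


class TestErrorNorms:
    def _osc_trace(self, scale=1.0):
        t = np.arange(0, 5000.0, 1.0)
        return Trace(t, scale * (0.5 + 0.5 * np.sin(2 * np.pi * t / 700.0)))

    def test_identical_traces_zero(self):
        tr = self._osc_trace()
        rep = error_norms(tr, tr)
        assert rep.L2 == 0.0 and rep.Linf == 0.0 and rep.freq_err == 0.0

    def test_doubled_trace_is_100_percent(self):
        rep = error_norms(self._osc_trace(), self._osc_trace(2.0))
        assert rep.L2 == pytest.approx(100.0, rel=1e-3)

    def test_no_cycle_raises(self):
        t = np.arange(0, 100.0, 1.0)
        flat = Trace(t, np.full_like(t, 0.3))
        with pytest.raises(ValueError, match="cycle"):
            error_norms(flat, flat, mode="single-cycle")


class TestResume:
    def test_two_segment_fe_run_is_bit_exact(self):
        from pacesim.topology import StarSpec, build_star
        spec = StarSpec(n=1, cells_per_strand=5, d=0.3)
        op = build_star(spec)
        params = {0: get_preset("pAP-1D", b=0.1), 1: get_preset("AP-1D")}
        model = TissueModel.from_regions(op, params)

        s_once = model.initial_state()
        run_tissue(model, op, s_once, 2000.0, dt=0.02, scheme="fe")

        s_split = model.initial_state()
        run_tissue(model, op, s_split, 800.0, dt=0.02, scheme="fe")
        run_tissue(model, op, s_split, 1200.0, dt=0.02, scheme="fe")

        np.testing.assert_array_equal(s_once.u, s_split.u)
        np.testing.assert_array_equal(s_once.w, s_split.w)

    def test_mixed_family_rejected(self):
        from pacesim.topology import StarSpec, build_star
        op = build_star(StarSpec(n=1, cells_per_strand=3, d=0.1))
        with pytest.raises(ValueError, match="one model family"):
            TissueModel.from_regions(op, {0: get_preset("pAP-0D"),
                                          1: get_preset("CN-1D")})
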