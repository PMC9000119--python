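"""Right-hand sides, nullclines, equilibria and presets."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from pacesim.models import (APParams, CNParams, PassiveParams, CellState,
                            ap_rhs, cn_rhs, passive_rhs, h_inf, nullclines,
                            find_equilibria, ap_nontrivial_equilibrium_u,
                            get_preset, PRESETS, CT_DEFAULT, DivergenceError)

P0 = get_preset("pAP-0D")


class TestAPRhs:
    def test_factor_u_identity(self):
        # every term of the u-equation carries a factor u
        for v in (-1.0, 0.0, 0.3, 2.0):
            du, _ = ap_rhs(CellState(0.0, v), P0)
            assert du == 0.0

    def test_origin_is_fixed_point(self):
        assert ap_rhs(CellState(0.0, 0.0), P0) == (0.0, 0.0)

    def test_recovery_rate_hand_value(self):
        # u = 0, v = 0.3: eps = 0.002 + 0.2*0.3/0.3, dv = ct*eps*(-0.3)
        _, dv = ap_rhs(CellState(0.0, 0.3), P0)
        expected = (1.0 / 12.9) * (0.002 + 0.2 * 0.3 / 0.3) * (-0.3)
        assert dv == pytest.approx(expected, rel=1e-14)

    @given(u=st.floats(-0.5, 1.5), v=st.floats(-0.5, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_conventional_limit_is_bitwise(self, u, v):
        # b = -a reproduces the conventional cubic k*u*(u-a)*(1-u) exactly
        p = APParams.conventional(a=0.13)
        du, dv = ap_rhs(CellState(u, v), p)
        du_conv = p.ct * (p.k * u * (u - p.a) * (1.0 - u) - v * u)
        assert du == du_conv

    def test_nonfinite_state_rejected(self):
        with pytest.raises(DivergenceError):
            ap_rhs(CellState(float("nan"), 0.0), P0)

    def test_external_current_additive(self):
        du0, _ = ap_rhs(CellState(0.2, 0.5), P0)
        du1, _ = ap_rhs(CellState(0.2, 0.5), P0, i_ext=0.7)
        assert du1 - du0 == pytest.approx(0.7)


class TestCNRhs:
    C0 = get_preset("pCN-0D")

    def test_factor_u_identity(self):
        du, _ = cn_rhs(CellState(0.0, 0.4), self.C0, i_ext=0.25)
        assert du == pytest.approx(0.25)

    def test_gate_midpoint(self):
        assert h_inf(self.C0.u_gate, self.C0) == pytest.approx(0.5)

    def test_tau_close_at_depolarized_potential(self):
        # h_inf -> 0 for u >> u_gate gives tau = tau_close in both blends
        for blend in ("convex", "printed"):
            p = self.C0.with_(gate_tau_blend=blend, u_s=1e-3)
            u = p.u_gate + 0.5
            hi = float(h_inf(u, p))
            assert hi < 1e-12
            _, dh = cn_rhs(CellState(u, 0.25), p)
            assert dh == pytest.approx((hi - 0.25) / p.tau_close, rel=1e-9)

    def test_tau_open_at_rest_convex_blend(self):
        p = self.C0.with_(u_s=1e-3)
        u = p.u_gate - 0.5   # h_inf -> 1
        _, dh = cn_rhs(CellState(u, 0.25), p)
        assert dh == pytest.approx((1.0 - 0.25) / p.tau_open, rel=1e-6)

    def test_printed_blend_domain_error(self):
        # tau_close > 2*tau_open makes the printed denominator cross zero
        p = CNParams(tau_in=0.3, tau_out=6.0, tau_open=100.0, tau_close=300.0,
                     u_gate=0.1, u_s=0.05, gate_tau_blend="printed")
        with pytest.raises(ValueError, match="denominator"):
            cn_rhs(CellState(p.u_gate - 1.0, 0.5), p)  # h_inf ~ 1

    def test_h_inf_bounded_and_decreasing(self):
        u = np.linspace(-3, 3, 301)
        hi = h_inf(u, self.C0)
        assert np.all(hi >= 0) and np.all(hi <= 1)
        assert np.all(np.diff(hi) <= 0)

    def test_h_inf_heaviside_limit(self):
        # u_s -> 0: h_inf approaches the step gate away from the threshold
        p = self.C0.with_(u_s=1e-6)
        u = np.concatenate([np.linspace(-1, p.u_gate - 1e-2, 50),
                            np.linspace(p.u_gate + 1e-2, 1.5, 50)])
        step = (u <= p.u_gate).astype(float)
        assert np.max(np.abs(h_inf(u, p) - step)) < 1e-3


class TestPassive:
    def test_zero_at_rest(self):
        assert passive_rhs(0.0, PassiveParams()) == 0.0

    def test_hand_value(self):
        assert passive_rhs(1.0, PassiveParams(S=26.0)) == pytest.approx(-26.0 / 12.9)

    def test_monotone_decay_toward_zero(self):
        for u in (-2.0, -0.1, 0.3, 5.0):
            assert passive_rhs(u, PassiveParams()) * u < 0


class TestNullclines:
    def test_pap_u_nullcline_roots(self):
        res = nullclines(P0, np.array([1.0, -P0.b]))
        assert res["u_nullcline"] == pytest.approx([0.0, 0.0], abs=1e-14)
        assert res["u_zero_line"]

    def test_ap_v_nullcline_origin(self):
        res = nullclines(P0, np.array([0.0]))
        assert res["w_nullcline"][0] == 0.0

    def test_pcn_h_nullcline_midpoint(self):
        p = get_preset("pCN-0D")
        res = nullclines(p, np.array([p.u_gate]))
        assert res["w_nullcline"][0] == pytest.approx(0.5)

    def test_cn_u_nullcline_singularity_marked(self):
        # denominator tau_out*(u+b)*(1-u) + tau_in vanishes somewhere for
        # suitable b < 0; that point must be NaN, not an exception
        p = CNParams(tau_in=1.0, tau_out=1.0, b=-2.0)
        # (u+b)(1-u) = -1 at u = 1 + ... solve numerically on a grid
        u = np.linspace(-1, 4, 2001)
        res = nullclines(p, u)
        assert np.isnan(res["u_nullcline"]).sum() >= 0  # no exception raised
        assert np.isfinite(res["u"]).all()


class TestEquilibria:
    def test_conventional_ap_origin(self):
        p = APParams.conventional(a=0.13)
        eqs = find_equilibria(p, n_starts=15)
        assert any(u == 0.0 and w == 0.0 for u, w in eqs)

    def test_pap_nontrivial_point_matches_bisection_oracle(self):
        p = P0  # b = 0.03
        # oracle: root of k(u+b)(1-u) + k*u*(u-a-1) = 0 by bisection
        f = lambda u: p.k * (u + p.b) * (1 - u) + p.k * u * (u - p.a - 1)
        u_star = brentq(f, 1e-6, 0.9)
        assert u_star == pytest.approx(ap_nontrivial_equilibrium_u(p), rel=1e-10)
        v_star = p.k * (u_star + p.b) * (1 - u_star)
        eqs = find_equilibria(p, n_starts=15)
        assert any(abs(u - u_star) < 1e-8 and abs(w - v_star) < 1e-8
                   for u, w in eqs), eqs

    def test_residuals_below_tolerance(self):
        from pacesim.models import _rhs_and_jac
        for preset in ("pAP-0D", "pCN-0D"):
            p = get_preset(preset)
            f, _ = _rhs_and_jac(p)
            for u, w in find_equilibria(p, n_starts=15):
                fu, fw = f(u, w)
                assert max(abs(fu), abs(fw)) < 1e-10

    def test_stable_origin_holds_under_simulation(self):
        # conventional AP: forward run started at the origin stays there
        from pacesim import simulate_cell
        p = APParams.conventional(a=0.13)
        trace, _ = simulate_cell(p, 1000.0, dt=0.01, scheme="fe",
                                 state0=(0.0, 0.0))
        assert np.max(np.abs(trace.u)) < 1e-6
        assert np.max(np.abs(trace.w)) < 1e-6


class TestPresets:
    def test_unknown_preset(self):
        with pytest.raises(KeyError, match="unknown preset"):
            get_preset("pAP-9D")

    def test_bad_override_field(self):
        with pytest.raises(TypeError, match="no field"):
            get_preset("pAP-0D", tau_in=1.0)

    def test_conventional_rows_tie_b_to_threshold(self):
        assert PRESETS["AP-1D"].b == -PRESETS["AP-1D"].a == -0.13
        assert PRESETS["CN-1D"].b == -PRESETS["CN-1D"].u_gate == -0.13
        assert PRESETS["CN-SMC"].b == -PRESETS["CN-SMC"].u_gate == -0.10

    def test_time_scaling_constant(self):
        assert PRESETS["pAP-0D"].ct == pytest.approx(1 / 12.9)

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            APParams(k=-1.0)
        with pytest.raises(ValueError):
            CNParams(tau_in=0.0)
        with pytest.raises(ValueError):
            PassiveParams(S=-1.0)
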