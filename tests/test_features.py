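"""Cycle-feature extraction, orbit orientation, synchronization measures."""

import numpy as np
import pytest

from pacesim import get_preset
from pacesim.events import cycle_crossings, upward_crossings
from pacesim.features import (extract_features, orbit_orientation,
                              measure_sync, run_star_system, sweep_parameter)
from pacesim.integrators import Trace
from pacesim.models import ap_nontrivial_equilibrium_u
from pacesim.topology import StarSpec, star_probe_nodes


def sine_trace(freq_hz=1.0, duration=10_000.0, dt=1.0, lo=0.0, hi=1.0):
    t = np.arange(0.0, duration, dt)
    mid, amp = 0.5 * (lo + hi), 0.5 * (hi - lo)
    return Trace(t, mid + amp * np.sin(2 * np.pi * freq_hz * t / 1000.0))


class TestExtractFeatures:
    def test_sine_closed_form(self):
        f = extract_features(sine_trace(), settle_time=2_000.0)
        assert f is not None
        assert f.frequency == pytest.approx(1.0, rel=1e-3)
        assert f.CL == pytest.approx(1000.0, rel=1e-3)
        assert f.POP == pytest.approx(1.0, abs=1e-4)
        assert f.MDP == pytest.approx(0.0, abs=1e-4)
        assert f.frequency == pytest.approx(1000.0 / f.CL, rel=1e-12)

    def test_constant_trace_quiescent(self):
        t = np.arange(0.0, 10_000.0, 1.0)
        assert extract_features(Trace(t, np.full_like(t, 0.2)), 1000.0) is None

    def test_too_few_cycles_quiescent(self):
        assert extract_features(sine_trace(duration=3_500.0), 1_000.0) is None

    def test_apd_plus_di_equals_cycle_length(self, pap_trace):
        f = extract_features(pap_trace, settle_time=20_000.0)
        assert f is not None
        assert f.APD90 + f.DI == pytest.approx(f.CL, abs=1e-9)
        assert f.POP > f.MDP

    def test_frequency_matches_fft_oracle(self, pap_trace):
        # independent estimate: FFT peak of the settled, mean-removed trace
        f = extract_features(pap_trace, settle_time=20_000.0)
        sel = pap_trace.t >= 20_000.0
        u = pap_trace.u[sel] - pap_trace.u[sel].mean()
        dt_s = (pap_trace.t[1] - pap_trace.t[0]) / 1000.0
        spec = np.abs(np.fft.rfft(u, n=4 * len(u)))
        freqs = np.fft.rfftfreq(4 * len(u), dt_s)
        f_fft = freqs[np.argmax(spec)]
        assert abs(f.frequency - f_fft) / f_fft < 0.01

    def test_pcn_frequency_matches_fft_oracle(self, pcn_trace):
        f = extract_features(pcn_trace, settle_time=20_000.0)
        sel = pcn_trace.t >= 20_000.0
        u = pcn_trace.u[sel] - pcn_trace.u[sel].mean()
        dt_s = (pcn_trace.t[1] - pcn_trace.t[0]) / 1000.0
        spec = np.abs(np.fft.rfft(u, n=4 * len(u)))
        freqs = np.fft.rfftfreq(4 * len(u), dt_s)
        assert abs(f.frequency - freqs[np.argmax(spec)]) / f.frequency < 0.01


class TestOrbitOrientation:
    def test_unit_circle_counterclockwise(self):
        t = np.linspace(0, 2 * np.pi, 200)
        assert orbit_orientation(np.cos(t), np.sin(t)) == "counterclockwise"

    def test_pap_counterclockwise(self, pap_trace):
        sel = pap_trace.t >= 20_000.0
        assert orbit_orientation(pap_trace.u[sel], pap_trace.w[sel]) == \
            "counterclockwise"

    def test_pcn_clockwise(self, pcn_trace):
        sel = pcn_trace.t >= 20_000.0
        assert orbit_orientation(pcn_trace.u[sel], pcn_trace.w[sel]) == \
            "clockwise"

    def test_quiescent_orbit_rejected(self):
        with pytest.raises(ValueError):
            orbit_orientation(np.full(100, 0.1), np.full(100, 0.2))


class TestSweep:
    def test_hopf_onset_and_cycle_encloses_equilibrium(self):
        res = sweep_parameter("pAP-0D", "b", [-0.01, 0.03], dt=0.01,
                              scheme="fe", settle_time=8_000.0,
                              measure_time=12_000.0, eq_starts=12)
        quiet, osc = res.points
        assert quiet.features is None          # b < 0: excitable, no cycle
        assert osc.features is not None        # b = 0.03: pacemaking
        # the limit cycle encloses the unstable equilibrium
        u_eq = ap_nontrivial_equilibrium_u(get_preset("pAP-0D", b=0.03))
        assert osc.features.MDP < u_eq < osc.features.POP
        assert any(abs(u - u_eq) < 1e-6 for u, _ in osc.equilibria)

    def test_monotone_grid_required(self):
        with pytest.raises(ValueError, match="monotone"):
            sweep_parameter("pAP-0D", "b", [0.01, 0.03, 0.02])

    def test_unknown_parameter(self):
        with pytest.raises(AttributeError):
            sweep_parameter("pAP-0D", "tau_in", [0.1, 0.2])


class TestMeasureSync:
    # (d = 0.1, b = 0.1) is a verified interior point of the pAP-AP 1:1
    # region for a single 20-cell strand; an isolated pAP oscillates only
    # for b below ~0.067, so the uncoupled check uses b = 0.05.
    def run_star(self, d, b=0.1, duration=30_000.0):
        spec = StarSpec(n=1, cells_per_strand=20, d=d)
        run = run_star_system(spec, get_preset("pAP-1D", b=b),
                              get_preset("AP-1D"), duration, dt=0.02)
        return run, star_probe_nodes(spec)[0]

    def test_uncoupled_strand_has_zero_followers(self):
        run, probe = self.run_star(d=0.0, b=0.05)
        m = measure_sync(run, 0, probe, settle_time=10_000.0)
        assert m.ratio == 0.0
        assert not m.is_one_to_one

    def test_one_to_one_at_interior_point(self):
        run, probe = self.run_star(d=0.1)
        m = measure_sync(run, 0, probe, settle_time=10_000.0)
        assert m.is_one_to_one
        assert m.ratio == pytest.approx(1.0, abs=1e-9)

    def test_verdict_stable_under_longer_window(self):
        # stationarity: doubling the observation window keeps the verdict
        r1, probe = self.run_star(d=0.1, duration=30_000.0)
        r2, _ = self.run_star(d=0.1, duration=60_000.0)
        m1 = measure_sync(r1, 0, probe, settle_time=10_000.0)
        m2 = measure_sync(r2, 0, probe, settle_time=10_000.0)
        assert m1.is_one_to_one == m2.is_one_to_one

    def test_quiescent_pacemaker_raises(self):
        run, probe = self.run_star(d=0.1, b=-0.13)  # excitable, never fires
        with pytest.raises(ValueError, match="quiescent"):
            measure_sync(run, 0, probe, settle_time=1_000.0)
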