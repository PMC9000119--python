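"""Dual-layer intestine: excitability gradient, pair frequencies, entrainment
plateaus and the conduction block.

Tissue runs use the scaled geometry (lengths and gradient decay divided by a
common factor), which preserves the intrinsic-frequency range while keeping
runtimes small.
"""

import numpy as np
import pytest

from pacesim.intestine3d import (bcn_gradient, pair_intrinsic_frequency,
                                 BlockSpec, IntestineExperiment,
                                 apply_conduction_block, run_intestine,
                                 segment_plateaus)
from pacesim.integrators import StateField
from pacesim.topology import CylinderSpec


class TestGradient:
    def test_duodenal_end(self):
        assert bcn_gradient(0) == pytest.approx(1.70)

    def test_distal_end_two_decimals(self):
        assert round(bcn_gradient(4800, dx=0.25), 2) == 0.62

    def test_asymptote(self):
        assert bcn_gradient(1e9) == pytest.approx(0.4)

    def test_scaled_gradient_preserves_range(self):
        # dividing length and decay scale together leaves the endpoints fixed
        assert bcn_gradient(0, y_scale=68.0) == pytest.approx(bcn_gradient(0))
        assert bcn_gradient(120, dx=1.0, y_scale=68.0) == \
            pytest.approx(bcn_gradient(1200, dx=1.0, y_scale=680.0))


class TestConductionBlock:
    SPEC = CylinderSpec(nx=8, ny=40, dx=0.25)

    def _state(self):
        n = 2 * self.SPEC.nx * self.SPEC.ny
        return StateField(np.full(n, 0.7), np.full(n, 0.9))

    def test_zero_area_block_is_identity(self):
        st = self._state()
        before = st.copy()
        apply_conduction_block(st, self.SPEC,
                               BlockSpec(ly_mm=0.0, lx_mm=0.0))
        np.testing.assert_array_equal(st.u, before.u)

    def test_full_domain_block_resets_everything(self):
        st = self._state()
        apply_conduction_block(st, self.SPEC,
                               BlockSpec(y0_mm=0, ly_mm=1e6, x0_mm=0, lx_mm=1e6))
        assert np.all(st.u == 0.001)
        assert np.all(st.w == 0.5)

    def test_block_touches_only_its_rectangle(self):
        st = self._state()
        blk = BlockSpec(y0_mm=2.0, ly_mm=1.0, x0_mm=0.0, lx_mm=0.5)
        apply_conduction_block(st, self.SPEC, blk)
        nx, ny, dx = self.SPEC.nx, self.SPEC.ny, self.SPEC.dx
        changed = np.nonzero(st.u != 0.7)[0]
        assert changed.size > 0
        for idx in changed:
            layer, rest = divmod(idx, nx * ny)
            iy, ix = divmod(rest, nx)
            assert 2.0 <= iy * dx < 3.0
            assert 0.0 <= ix * dx < 0.5


class TestPairFrequency:
    def test_monotone_decreasing_along_length(self):
        f = [pair_intrinsic_frequency(y, duration=900_000.0,
                                      prime_duration=400_000.0)
             for y in (0.0, 400.0, 1200.0)]
        assert all(v is not None for v in f)
        assert f[0] > f[1] > f[2]

    def test_quiescent_below_oscillatory_range(self):
        # the gradient bottoms out at b = 0.4 (still oscillating); forcing
        # b far below that must report quiescence, not an error
        f = pair_intrinsic_frequency(0.0, b=0.05, duration=600_000.0,
                                     prime_duration=300_000.0)
        assert f is None


@pytest.fixture(scope="module")
def scaled_run():
    """Primed, coupled, block-free scaled run used by several tests."""
    exp = IntestineExperiment.scaled(factor=80.0, nx=4, ny=60,
                                     duration=600_000.0)
    exp.block = None
    exp.prime_duration = 300_000.0
    return exp, run_intestine(exp, freq_window=(300_000.0, 600_000.0))


class TestEntrainment:
    def test_profile_is_monotone_plateau_staircase(self, scaled_run):
        _, res = scaled_run
        f = res.freq_cpm
        assert np.isfinite(f).all()
        # non-increasing within measurement resolution
        assert np.all(np.diff(f) <= 0.2)
        assert len(res.plateaus) >= 2
        widths = [hi - lo for lo, hi, _ in res.plateaus]
        assert max(widths) > 2.0  # at least one extended plateau

    def test_plateaus_ride_above_local_intrinsic_frequency(self, scaled_run):
        exp, res = scaled_run
        for lo, hi, cpm in res.plateaus:
            if hi - lo < 1.0:
                continue
            intrinsic = pair_intrinsic_frequency(hi, y_scale=exp.y_scale,
                                                 duration=700_000.0,
                                                 prime_duration=300_000.0)
            if intrinsic is not None:
                assert cpm >= intrinsic - 0.3

    def test_smc_follows_icc_cycle_for_cycle(self, scaled_run):
        _, res = scaled_run
        window = (300_000.0, 600_000.0)
        for row in (10, 30, 50):
            ti = res.cross_times_icc[row]
            tm = res.cross_times_smc[row]
            ni = ((ti >= window[0]) & (ti <= window[1])).sum()
            nm = ((tm >= window[0]) & (tm <= window[1])).sum()
            assert abs(ni - nm) <= 1

    def test_conduction_block_perturbs_downstream_waves(self):
        exp = IntestineExperiment.scaled(factor=80.0, nx=4, ny=60,
                                         duration=500_000.0)
        exp.prime_duration = 200_000.0
        exp.block = BlockSpec(t_ms=250_000.0, y0_mm=580.0 / 80, ly_mm=40.0 / 80,
                              x0_mm=0.0, lx_mm=22.0 / 80)
        res = run_intestine(exp, freq_window=(300_000.0, 500_000.0))
        # the run completes and the blocked rows resume activity afterwards
        row = int(round((580.0 / 80) / exp.cylinder.dx))
        post = res.cross_times_icc[row]
        post = post[np.isfinite(post)]
        assert (post > 260_000.0).any()


class TestPlateauSegmentation:
    def test_staircase_is_segmented_exactly(self):
        y = np.arange(10.0)
        f = np.array([5, 5, 5, 4, 4, np.nan, 3, 3, 3, 3], dtype=float)
        ps = segment_plateaus(y, f, tol_cpm=0.5)
        assert [(lo, hi) for lo, hi, _ in ps] == [(0, 2), (3, 4), (6, 9)]
        assert ps[2][2] == pytest.approx(3.0)
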