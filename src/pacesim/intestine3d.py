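"""Dual-layer intestine model: a pacemaking ICC (interstitial cells of Cajal)
sheet electrotonically coupled to an excitable SMC (smooth muscle) sheet.

The tube is cut along its axis and unrolled into two stacked planes.  The ICC
layer carries a proximal-to-distal gradient of the excitability parameter

    b_CN(i) = b_inf + b_amp * exp(-i*dx / y_scale)

(defaults 0.4 + 1.3*exp(-y/680), y in mm), which makes isolated ICC-SMC pairs
oscillate faster near the duodenum (~17.5 counts per minute) than at the
distal end of the simulated half (~10.5 cpm at y = 1200 mm).  With intra-layer
coupling on, faster proximal oscillators entrain their slower neighbours and
the frequency profile organizes into constant-frequency plateaus; a transient
conduction block then triggers a persistent dysrhythmia.

Near the proximal end the pair is bistable: a stable limit cycle coexists
with a stable equilibrium, and the standard initial conditions (u = 0.01,
h = 0.5) lie in the equilibrium's basin.  Protocols that measure intrinsic
pair frequencies therefore include a priming stage at a mid-range b_CN where
the cycle is globally attracting, before moving to the target value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .events import upward_crossings
from .integrators import StateField, TissueModel, Trace, run_tissue
from .models import CNParams, get_preset
from .topology import CouplingOperator, CylinderSpec, build_cylinder, LAYER_INNER, LAYER_OUTER

__all__ = [
    "bcn_gradient",
    "pair_intrinsic_frequency",
    "BlockSpec",
    "IntestineExperiment",
    "apply_conduction_block",
    "run_intestine",
    "IntestineResult",
    "segment_plateaus",
]


def bcn_gradient(i, dx: float = 0.25, b_inf: float = 0.4, b_amp: float = 1.3,
                 y_scale: float = 680.0):
    """ICC excitability parameter at cell index ``i`` along the tube length.

    ``b = b_inf + b_amp * exp(-i*dx/y_scale)``; defaults give 1.70 at the
    duodenal end and 0.62 (2 d.p.) at y = 1200 mm.  Accepts scalars or arrays.
    """
    i = np.asarray(i, dtype=float)
    out = b_inf + b_amp * np.exp(-i * dx / y_scale)
    return float(out) if out.ndim == 0 else out


def _pair_operator(d_between: float) -> CouplingOperator:
    import scipy.sparse as sp
    m = sp.csr_matrix(np.array([[-d_between, d_between],
                                [d_between, -d_between]]))
    return CouplingOperator(2, m, region=np.array([0, 1], dtype=np.int32),
                            region_names={0: "ICC", 1: "SMC"})


def pair_intrinsic_frequency(
    y_mm: float,
    icc: Optional[CNParams] = None,
    smc: Optional[CNParams] = None,
    d_between: float = 6e-3,
    y_scale: float = 680.0,
    dt: float = 2.5,
    duration: float = 1_200_000.0,
    settle: float = 300_000.0,
    prime_b: float = 1.0,
    prime_duration: float = 600_000.0,
    scheme: str = "fe",
    b: Optional[float] = None,
) -> Optional[float]:
    """Intrinsic oscillation frequency (counts per minute) of one decoupled
    ICC-SMC pair at longitudinal position ``y_mm``.

    Simulates the two cells with zero intra-layer diffusion and inter-layer
    coupling ``d_between``, with the ICC ``b`` set by the longitudinal
    gradient.  A priming stage (``prime_duration`` ms at ``b = prime_b``)
    places the pair on its limit cycle before the target ``b`` is applied;
    cycles are counted after ``settle`` ms of the measurement stage.  Returns
    None when the pair is quiescent at the target ``b``.
    """
    icc = get_preset("pCN-ICC") if icc is None else icc
    smc = get_preset("CN-SMC") if smc is None else smc
    if b is None:
        b = bcn_gradient(y_mm, dx=1.0, y_scale=y_scale, b_inf=0.4, b_amp=1.3)
    op = _pair_operator(d_between)
    state = None
    if prime_duration > 0:
        model_p = TissueModel.from_regions(op, {0: replace(icc, b=prime_b), 1: smc})
        state = model_p.initial_state()
        run_tissue(model_p, op, state, prime_duration, dt, scheme=scheme,
                   record_nodes=np.array([0], dtype=np.int64), record_dt=1e6)
        state.time = 0.0
    model = TissueModel.from_regions(op, {0: replace(icc, b=float(b)), 1: smc})
    if state is None:
        state = model.initial_state()
    run = run_tissue(model, op, state, duration, dt, scheme=scheme,
                     record_nodes=np.array([0], dtype=np.int64),
                     record_dt=1000.0, cross_capacity=4096)
    tc = run.cross_times[0]
    tc = tc[np.isfinite(tc)]
    tc = tc[tc >= settle]
    if tc.size < 3:
        return None
    return 60_000.0 * (tc.size - 1) / (tc[-1] - tc[0])


@dataclass(frozen=True)
class BlockSpec:
    """Transient conduction block: inside the rectangle both layers are reset
    to u = 0.001, h = 0.5 for exactly one time step."""

    t_ms: float = 8_100_000.0    # block instant (ms)
    y0_mm: float = 580.0         # longitudinal origin
    ly_mm: float = 40.0          # longitudinal extent
    x0_mm: float = 0.0           # circumferential origin
    lx_mm: float = 22.0          # circumferential extent
    u_reset: float = 0.001
    h_reset: float = 0.5


def apply_conduction_block(state: StateField, spec: CylinderSpec,
                           block: BlockSpec) -> StateField:
    """Reset both layers inside the block rectangle (in place).

    Nodes with ``y in [y0, y0+ly)`` and ``x in [x0, x0+lx)`` (node centers at
    ``ix*dx``, ``iy*dx``) are set to the reset values in both layers.
    """
    nx, ny, dx = spec.nx, spec.ny, spec.dx
    ix = np.arange(nx) * dx
    iy = np.arange(ny) * dx
    in_x = (ix >= block.x0_mm) & (ix < block.x0_mm + block.lx_mm)
    in_y = (iy >= block.y0_mm) & (iy < block.y0_mm + block.ly_mm)
    mask2d = np.outer(in_y, in_x).ravel()
    npl = nx * ny
    full = np.concatenate([mask2d, mask2d])
    state.u[full] = block.u_reset
    state.w[full] = block.h_reset
    return state


@dataclass
class IntestineExperiment:
    """Configuration of a dual-layer intestine run.

    ``y_scale`` is the decay length of the excitability gradient; scaling the
    geometry and ``y_scale`` together (e.g. by 1/10) preserves the range of
    intrinsic frequencies while shrinking the domain.  ``prime_duration > 0``
    runs a warm-up with spatially uniform ``b_CN = prime_b`` before the
    gradient is applied (used for decoupled-profile measurements where the
    proximal pairs are bistable).
    """

    cylinder: CylinderSpec = field(default_factory=CylinderSpec)
    icc: CNParams = field(default_factory=lambda: get_preset("pCN-ICC"))
    smc: CNParams = field(default_factory=lambda: get_preset("CN-SMC"))
    y_scale: float = 680.0
    dt: float = 2.5
    duration: float = 11_600_000.0
    scheme: str = "fe"
    block: Optional[BlockSpec] = field(default_factory=BlockSpec)
    prime_b: float = 1.0
    prime_duration: float = 0.0
    cross_capacity: int = 4096

    @classmethod
    def scaled(cls, factor: float = 10.0, **kw) -> "IntestineExperiment":
        """Geometry (and gradient decay length) divided by ``factor``; the
        default full-size protocol is desk-scale only when reduced."""
        cyl = CylinderSpec(nx=kw.pop("nx", 16),
                           ny=kw.pop("ny", int(round(4800 / factor))),
                           dx=0.25)
        block = BlockSpec(t_ms=kw.pop("block_t_ms", 810_000.0),
                          y0_mm=580.0 / factor, ly_mm=40.0 / factor,
                          x0_mm=0.0, lx_mm=22.0 / factor)
        return cls(cylinder=cyl, y_scale=680.0 / factor, block=block,
                   duration=kw.pop("duration", 1_160_000.0), **kw)


@dataclass
class IntestineResult:
    """Frequency profile and probe traces of an intestine run."""

    y_mm: np.ndarray             # longitudinal node positions
    freq_cpm: np.ndarray         # per-y frequency at mid-circumference (ICC)
    plateaus: list               # list of (y_lo, y_hi, mean_cpm)
    trace: Trace                 # probe-node traces (ICC and SMC pairs)
    probe_y_mm: np.ndarray
    cross_times_icc: np.ndarray  # (ny, capacity) at mid-circumference
    cross_times_smc: np.ndarray
    state: StateField


def segment_plateaus(y: np.ndarray, freq: np.ndarray,
                     tol_cpm: float = 0.1) -> list:
    """Maximal y-intervals over which the frequency varies less than
    ``tol_cpm`` (quiescent/NaN nodes break segments)."""
    plateaus = []
    i = 0
    n = len(y)
    while i < n:
        if not np.isfinite(freq[i]):
            i += 1
            continue
        j = i
        lo = hi = freq[i]
        while j + 1 < n and np.isfinite(freq[j + 1]):
            lo2, hi2 = min(lo, freq[j + 1]), max(hi, freq[j + 1])
            if hi2 - lo2 >= tol_cpm:
                break
            lo, hi = lo2, hi2
            j += 1
        plateaus.append((float(y[i]), float(y[j]),
                         float(np.mean(freq[i:j + 1]))))
        i = j + 1
    return plateaus


def run_intestine(exp: IntestineExperiment,
                  freq_window: tuple[float, float] | None = None,
                  probe_y_mm=(170.0, 1200.0)) -> IntestineResult:
    """Simulate the dual-layer intestine and measure the per-y frequency
    profile at mid-circumference.

    The run is segmented around the conduction block (state reset applied
    between segments).  ``freq_window`` is the (t_lo, t_hi) ms interval over
    which cycles are counted for the profile; by default the last third of
    the run before the block (or of the whole run if no block).
    """
    spec = exp.cylinder
    nx, ny, dx = spec.nx, spec.ny, spec.dx
    npl = nx * ny
    op = build_cylinder(spec)
    iy = np.arange(ny)
    b_profile = bcn_gradient(iy, dx=dx, y_scale=exp.y_scale)

    # per-node parameter table: ICC layer row-by-row b, uniform SMC layer
    def build_model(b_values: np.ndarray) -> TissueModel:
        base = TissueModel.from_regions(op, {LAYER_INNER: exp.icc,
                                             LAYER_OUTER: exp.smc})
        P = base.P
        P[:npl, 6] = np.repeat(b_values, nx)
        return base

    mid = nx // 2
    icc_idx = iy * nx + mid              # mid-circumference column, ICC layer
    smc_idx = npl + icc_idx
    probe_rows = [min(ny - 1, int(round(y / dx))) for y in probe_y_mm]
    rec = np.array([r * nx + mid for r in probe_rows] +
                   [npl + r * nx + mid for r in probe_rows], dtype=np.int64)

    state = None
    if exp.prime_duration > 0:
        model_p = build_model(np.full(ny, exp.prime_b))
        state = model_p.initial_state()
        run_tissue(model_p, op, state, exp.prime_duration, exp.dt,
                   scheme=exp.scheme, record_nodes=rec[:1], record_dt=1e9)
        state.time = 0.0

    model = build_model(b_profile)
    if state is None:
        state = model.initial_state()

    cross_times = np.full((op.n_nodes, exp.cross_capacity), np.nan)
    cross_count = np.zeros(op.n_nodes, dtype=np.int64)
    segments = []
    block_t = exp.block.t_ms if exp.block is not None else None
    if block_t is not None and 0 < block_t < exp.duration:
        segments = [(0.0, block_t), (block_t, exp.duration)]
    else:
        segments = [(0.0, exp.duration)]

    traces_t, traces_u, traces_w = [], [], []
    for si, (t0, t1) in enumerate(segments):
        if si == 1:
            apply_conduction_block(state, spec, exp.block)
        run = run_tissue(model, op, state, t1 - t0, exp.dt, scheme=exp.scheme,
                         record_nodes=rec, record_dt=max(exp.dt, 500.0),
                         cross_times=cross_times, cross_count=cross_count)
        traces_t.append(run.trace.t)
        traces_u.append(run.trace.u)
        traces_w.append(run.trace.w)

    trace = Trace(np.concatenate(traces_t), np.vstack(traces_u),
                  np.vstack(traces_w))

    if freq_window is None:
        t_end = block_t if block_t is not None else exp.duration
        freq_window = (2.0 * t_end / 3.0, t_end)
    lo, hi = freq_window
    freq = np.full(ny, np.nan)
    for r in range(ny):
        tc = cross_times[icc_idx[r]]
        tc = tc[np.isfinite(tc)]
        tc = tc[(tc >= lo) & (tc <= hi)]
        if tc.size >= 3:
            freq[r] = 60_000.0 * (tc.size - 1) / (tc[-1] - tc[0])
    y_mm = iy * dx
    plateaus = segment_plateaus(y_mm, freq)
    return IntestineResult(
        y_mm=y_mm, freq_cpm=freq, plateaus=plateaus, trace=trace,
        probe_y_mm=np.asarray(probe_y_mm, dtype=float),
        cross_times_icc=cross_times[icc_idx],
        cross_times_smc=cross_times[smc_idx],
        state=state,
    )
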