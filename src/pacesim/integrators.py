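"""Time stepping (forward/backward Euler), stability checking and accuracy
norms.

The forward Euler (FE) scheme is explicit and subject to the diffusion
stability bound ``D*dt/dx^2 < 1/(2N)``; the backward Euler (BE) scheme is
implicit and unconditionally stable.  BE on tissue uses operator splitting:
the reaction term is solved implicitly per node (damped Newton with analytic
2x2 Jacobian), then the diffusion term implicitly via a pre-factorized sparse
linear solve.  Time is tracked as ``step_count * dt`` with a 64-bit counter,
never by accumulated addition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _kernels as K
from .events import cycle_crossings
from .models import APParams, CNParams, PassiveParams, DivergenceError
from .topology import CouplingOperator

__all__ = [
    "IntegratorSpec",
    "NormReport",
    "Trace",
    "StateField",
    "TissueModel",
    "simulate_cell",
    "run_tissue",
    "step_forward_euler",
    "step_backward_euler",
    "stability_check",
    "error_norms",
    "accuracy_report",
]


@dataclass(frozen=True)
class IntegratorSpec:
    """Scheme selection and implicit-solver controls."""

    scheme: str = "be"          # "fe" | "be"
    dt: float = 0.01            # ms
    abs_tol: float = 1e-7       # inner Newton tolerance (max-norm)
    max_inner: int = 20

    def __post_init__(self):
        if self.scheme not in ("fe", "be"):
            raise ValueError("scheme must be 'fe' or 'be'")
        if not (self.dt > 0 and self.abs_tol > 0 and self.max_inner >= 1):
            raise ValueError("invalid integrator spec")


@dataclass
class NormReport:
    """Relative accuracy of a test trace against a reference, in percent."""

    L2: float
    Linf: float
    freq_err: float


@dataclass
class Trace:
    """Uniformly sampled time series: ``t`` in ms, ``u``/``w`` with time as
    the leading axis (1D for a single node)."""

    t: np.ndarray
    u: np.ndarray
    w: Optional[np.ndarray] = None

    def node(self, q: int) -> "Trace":
        return Trace(self.t, self.u[:, q], None if self.w is None else self.w[:, q])


@dataclass
class StateField:
    """Per-node state over a topology: potential ``u``, slow variable ``w``
    (recovery or gate), and simulated time in ms."""

    u: np.ndarray
    w: np.ndarray
    time: float = 0.0

    def copy(self) -> "StateField":
        return StateField(self.u.copy(), self.w.copy(), self.time)


class ConvergenceError(RuntimeError):
    """Backward-Euler inner iteration failed to reach tolerance."""


# ---------------------------------------------------------------------------
# tissue model packing
# ---------------------------------------------------------------------------

_AP_COLS = ("k", "a", "b", "eps0", "mu1", "mu2", "ct")
_CN_COLS = ("tau_in", "tau_out", "tau_open", "tau_close", "u_gate", "u_s", "b")


@dataclass
class TissueModel:
    """Per-node reaction model over a topology.

    ``family`` is "cardiac" (Aliev-Panfilov-type + passive nodes) or "gut"
    (Corrado-type).  ``kind`` distinguishes active (0) from passive (1) nodes
    in the cardiac family.  ``P`` packs per-node parameters column-wise as in
    :mod:`pacesim._kernels`.
    """

    family: str
    kind: np.ndarray
    P: np.ndarray

    @classmethod
    def from_regions(cls, op: CouplingOperator, region_params: dict) -> "TissueModel":
        """Build from a mapping of region code -> parameter dataclass."""
        n = op.n_nodes
        region = op.region if op.region is not None else np.zeros(n, dtype=np.int32)
        families = set()
        for p in region_params.values():
            if isinstance(p, APParams) or isinstance(p, PassiveParams):
                families.add("cardiac")
            elif isinstance(p, CNParams):
                families.add("gut")
            else:
                raise TypeError(f"unsupported parameter type {type(p)!r}")
        if len(families) != 1:
            raise ValueError("all regions must belong to one model family")
        family = families.pop()
        kind = np.zeros(n, dtype=np.int32)
        P = np.zeros((n, 8))
        for code, p in region_params.items():
            sel = region == code
            if not sel.any():
                raise ValueError(f"region code {code} not present in topology")
            if isinstance(p, PassiveParams):
                kind[sel] = K.KIND_PASSIVE
                P[sel, 0] = p.S
                P[sel, 6] = p.ct
            elif isinstance(p, APParams):
                for j, name in enumerate(_AP_COLS):
                    P[sel, j] = getattr(p, "ct" if name == "ct" else name)
            else:
                for j, name in enumerate(_CN_COLS):
                    P[sel, j] = getattr(p, name)
                P[sel, 7] = 1.0 if p.gate_tau_blend == "convex" else -1.0
        covered = np.isin(region, list(region_params))
        if not covered.all():
            missing = sorted(set(region[~covered].tolist()))
            raise ValueError(f"no parameters for region code(s) {missing}")
        return cls(family, kind, P)

    def initial_state(self, n: Optional[int] = None) -> StateField:
        """Standard initial conditions: u = 0.01 with v = 0.01 (cardiac) or
        h = 0.5 (gut)."""
        n = self.P.shape[0] if n is None else n
        u = np.full(n, 0.01)
        w = np.full(n, 0.01 if self.family == "cardiac" else 0.5)
        return StateField(u, w, 0.0)


# ---------------------------------------------------------------------------
# single-cell driver
# ---------------------------------------------------------------------------

def _default_state(params) -> tuple[float, float]:
    if isinstance(params, CNParams):
        return 0.01, 0.5
    return 0.01, 0.01


def simulate_cell(
    params,
    duration: float,
    dt: float = 0.01,
    scheme: str = "fe",
    i_ext: float = 0.0,
    record_dt: Optional[float] = None,
    state0: Optional[tuple[float, float]] = None,
    abs_tol: float = 1e-7,
    max_inner: int = 20,
) -> tuple[Trace, StateField]:
    """Integrate one isolated cell for ``duration`` ms.

    Records every ``record_dt`` ms (default: every step, but never more than
    ~2e6 samples).  Returns the trace and the final state.
    """
    n_steps = int(round(duration / dt))
    if record_dt is None:
        rec_every = max(1, int(math.ceil(n_steps / 2_000_000)))
    else:
        rec_every = max(1, int(round(record_dt / dt)))
    n_rec = n_steps // rec_every + 1
    out_u = np.empty(n_rec)
    out_w = np.empty(n_rec)
    u0, w0 = _default_state(params) if state0 is None else state0

    if isinstance(params, APParams):
        args = (u0, w0, params.k, params.a, params.b, params.eps0,
                params.mu1, params.mu2, params.ct, i_ext, dt, n_steps)
        if scheme == "fe":
            u, w, status = K.ap_cell_fe(*args, rec_every, out_u, out_w)
        else:
            u, w, status, worst = K.ap_cell_be(*args, abs_tol, max_inner,
                                               rec_every, out_u, out_w)
    elif isinstance(params, CNParams):
        tsgn = 1.0 if params.gate_tau_blend == "convex" else -1.0
        args = (u0, w0, params.tau_in, params.tau_out, params.tau_open,
                params.tau_close, params.u_gate, params.u_s, params.b,
                tsgn, i_ext, dt, n_steps)
        if scheme == "fe":
            u, w, status = K.cn_cell_fe(*args, rec_every, out_u, out_w)
        else:
            u, w, status, worst = K.cn_cell_be(*args, abs_tol, max_inner,
                                               rec_every, out_u, out_w)
    else:
        raise TypeError(f"unsupported parameter type {type(params)!r}")

    if status == K.DIVERGED:
        raise DivergenceError(
            f"single-cell integration diverged (scheme={scheme}, dt={dt})")
    if status == K.NO_CONVERGENCE:
        raise ConvergenceError(
            f"backward-Euler inner loop exceeded {max_inner} iterations at dt={dt}")
    t = np.arange(n_rec) * (rec_every * dt)
    return Trace(t, out_u, out_w), StateField(np.array([u]), np.array([w]), n_steps * dt)


# ---------------------------------------------------------------------------
# tissue drivers
# ---------------------------------------------------------------------------

@dataclass
class TissueRun:
    """Output of :func:`run_tissue`."""

    trace: Trace                 # recorded nodes
    record_nodes: np.ndarray
    cross_times: np.ndarray      # (n_nodes, capacity), ms; NaN-padded
    cross_count: np.ndarray      # (n_nodes,), total upward crossings of level
    cross_level: float
    state: StateField            # final state
    max_inner_used: int = 0


def run_tissue(
    model: TissueModel,
    op: CouplingOperator,
    state: StateField,
    duration: float,
    dt: float,
    scheme: str = "fe",
    record_nodes: Optional[np.ndarray] = None,
    record_dt: Optional[float] = None,
    cross_level: float = 0.5,
    cross_capacity: int = 64,
    abs_tol: float = 1e-7,
    max_inner: int = 20,
    cross_times: Optional[np.ndarray] = None,
    cross_count: Optional[np.ndarray] = None,
) -> TissueRun:
    """Integrate a tissue in place for ``duration`` ms.

    ``state`` is advanced in place and also returned inside the result.
    Existing ``cross_times``/``cross_count`` buffers may be passed to continue
    event collection across segmented runs (e.g. around a conduction block).
    """
    n = op.n_nodes
    n_steps = int(round(duration / dt))
    if record_nodes is None:
        record_nodes = np.arange(min(n, 4), dtype=np.int64)
    record_nodes = np.asarray(record_nodes, dtype=np.int64)
    if record_dt is None:
        rec_every = max(1, int(math.ceil(n_steps / 200_000)))
    else:
        rec_every = max(1, int(round(record_dt / dt)))
    n_rec = n_steps // rec_every + 1
    out_u = np.empty((n_rec, record_nodes.size))
    out_w = np.empty((n_rec, record_nodes.size))
    if cross_times is None:
        cross_times = np.full((n, cross_capacity), np.nan)
        cross_count = np.zeros(n, dtype=np.int64)
    indptr, indices, data = op.csr_arrays()
    t0 = state.time
    worst = 0

    if scheme == "fe":
        if model.family == "cardiac":
            status, bad, step = K.cardiac_tissue_fe(
                state.u, state.w, model.kind, model.P, indptr, indices, data,
                dt, n_steps, t0, record_nodes, rec_every, out_u, out_w,
                cross_level, cross_times, cross_count)
        else:
            status, bad, step = K.gut_tissue_fe(
                state.u, state.w, model.P, indptr, indices, data,
                dt, n_steps, t0, record_nodes, rec_every, out_u, out_w,
                cross_level, cross_times, cross_count)
        if status == K.DIVERGED:
            raise DivergenceError(
                f"tissue FE diverged at node {bad}, t = {t0 + step * dt:.3f} ms")
    elif scheme == "be" and n <= 2048:
        # small systems: the whole split step runs compiled, with a dense
        # inverse of (I - dt*L) for the implicit diffusion stage
        Minv = np.linalg.inv(np.eye(n) - dt * op.matrix.toarray())
        if model.family == "cardiac":
            status, bad, step, worst = K.cardiac_tissue_be(
                state.u, state.w, model.kind, model.P, indptr, indices, data,
                Minv, dt, n_steps, t0, record_nodes, rec_every, out_u, out_w,
                cross_level, cross_times, cross_count, abs_tol, max_inner)
        else:
            status, bad, step, worst = K.gut_tissue_be(
                state.u, state.w, model.P, indptr, indices, data,
                Minv, dt, n_steps, t0, record_nodes, rec_every, out_u, out_w,
                cross_level, cross_times, cross_count, abs_tol, max_inner)
        if status == K.DIVERGED:
            raise DivergenceError(
                f"tissue BE diverged at node {bad}, t = {t0 + step * dt:.3f} ms")
        if status == K.NO_CONVERGENCE:
            raise ConvergenceError(
                f"BE inner loop exceeded {max_inner} iterations at node {bad}, "
                f"t = {t0 + step * dt:.3f} ms")
    elif scheme == "be":
        # operator splitting: implicit reaction per node with the coupling
        # current frozen at the step start, then implicit diffusion solve
        solver = spla.factorized(
            (sp.identity(n, format="csc") - dt * op.matrix.tocsc()))
        react = K.cardiac_react_be if model.family == "cardiac" else K.gut_react_be
        j = 1
        out_u[0] = state.u[record_nodes]
        out_w[0] = state.w[record_nodes]
        cap = cross_times.shape[1]
        for s in range(n_steps):
            u_prev = state.u.copy()
            i_ext = op.matrix @ state.u
            if model.family == "cardiac":
                status, bad, it = react(state.u, state.w, model.kind, model.P,
                                        i_ext, dt, abs_tol, max_inner)
            else:
                status, bad, it = react(state.u, state.w, model.P,
                                        i_ext, dt, abs_tol, max_inner)
            if status == K.NO_CONVERGENCE:
                raise ConvergenceError(
                    f"BE inner loop exceeded {max_inner} iterations at node {bad}, "
                    f"t = {t0 + s * dt:.3f} ms")
            if status == K.DIVERGED:
                raise DivergenceError(
                    f"BE reaction diverged at node {bad}, t = {t0 + s * dt:.3f} ms")
            worst = max(worst, it)
            # implicit diffusion around the already-applied explicit coupling
            state.u[:] = solver(state.u - dt * i_ext)
            if not np.all(np.isfinite(state.u)):
                bad = int(np.argmax(~np.isfinite(state.u)))
                raise DivergenceError(
                    f"BE diffusion produced non-finite u at node {bad}")
            up = (u_prev < cross_level) & (state.u >= cross_level)
            for i in np.nonzero(up)[0]:
                c = cross_count[i]
                if c < cap:
                    frac = (cross_level - u_prev[i]) / (state.u[i] - u_prev[i])
                    cross_times[i, c] = t0 + (s + frac) * dt
                cross_count[i] = c + 1
            if (s + 1) % rec_every == 0 and j < n_rec:
                out_u[j] = state.u[record_nodes]
                out_w[j] = state.w[record_nodes]
                j += 1
    else:
        raise ValueError("scheme must be 'fe' or 'be'")

    state.time = t0 + n_steps * dt
    t = t0 + np.arange(n_rec) * (rec_every * dt)
    return TissueRun(Trace(t, out_u, out_w), record_nodes, cross_times,
                     cross_count, cross_level, state, worst)


def step_forward_euler(state: StateField, model: TissueModel,
                       op: CouplingOperator, dt: float) -> StateField:
    """Advance a tissue state by one explicit Euler step (in place)."""
    run_tissue(model, op, state, duration=dt, dt=dt, scheme="fe",
               record_nodes=np.empty(0, dtype=np.int64))
    return state


def step_backward_euler(state: StateField, model: TissueModel,
                        op: CouplingOperator, spec: IntegratorSpec) -> StateField:
    """Advance a tissue state by one implicit Euler step (in place)."""
    run_tissue(model, op, state, duration=spec.dt, dt=spec.dt, scheme="be",
               record_nodes=np.empty(0, dtype=np.int64),
               abs_tol=spec.abs_tol, max_inner=spec.max_inner)
    return state


# ---------------------------------------------------------------------------
# stability and accuracy
# ---------------------------------------------------------------------------

def stability_check(D_max: float, dx: float, dt: float, N: int) -> tuple[bool, float]:
    """Explicit-Euler diffusion stability: D*dt/dx^2 < 1/(2N), strict.

    Returns (passes, margin) where margin = d*dt = D*dt/dx^2.
    """
    if min(D_max, dx, dt) < 0 or N < 1:
        raise ValueError("arguments must be positive")
    margin = D_max * dt / dx ** 2
    return margin < 1.0 / (2 * N), margin


def _last_complete_cycle(t, u):
    cross = cycle_crossings(t, u)
    if cross.size < 2:
        raise ValueError("reference trace contains no complete cycle")
    return cross[-2], cross[-1]


def error_norms(trace_ref: Trace, trace_test: Trace, mode: str = "both") -> NormReport:
    """Relative error norms of a test trace against a reference, in percent.

    Single-cycle L2/Linf norms compare the last complete cycle of each trace,
    aligned at the cycle-start crossing (the two integrations drift in phase
    over long runs; the norm measures waveform error, not accumulated phase).
    The frequency error compares mean cycle lengths over the full traces.
    ``mode``: "single-cycle", "frequency", or "both".
    """
    if mode not in ("single-cycle", "frequency", "both"):
        raise ValueError("mode must be 'single-cycle', 'frequency' or 'both'")
    L2 = Linf = freq = float("nan")

    if mode in ("single-cycle", "both"):
        r0, r1 = _last_complete_cycle(trace_ref.t, trace_ref.u)
        s0, s1 = _last_complete_cycle(trace_test.t, trace_test.u)
        span = min(r1 - r0, s1 - s0)
        sel = (trace_ref.t >= r0) & (trace_ref.t <= r0 + span)
        tr = trace_ref.t[sel]
        ur = trace_ref.u[sel]
        ut = np.interp(s0 + (tr - r0), trace_test.t, trace_test.u)
        diff = ur - ut
        L2 = 100.0 * np.linalg.norm(diff) / np.linalg.norm(ur)
        Linf = 100.0 * np.max(np.abs(diff)) / np.max(np.abs(ur))

    if mode in ("frequency", "both"):
        cr = cycle_crossings(trace_ref.t, trace_ref.u)
        ct = cycle_crossings(trace_test.t, trace_test.u)
        if cr.size < 2 or ct.size < 2:
            raise ValueError("need at least one complete cycle in both traces")
        fr = (cr.size - 1) / (cr[-1] - cr[0])
        ft = (ct.size - 1) / (ct[-1] - ct[0])
        freq = 100.0 * abs(ft - fr) / fr

    return NormReport(L2=L2, Linf=Linf, freq_err=freq)


def accuracy_report(
    params,
    fe_dts=(0.1, 0.01),
    be_dt: float = 1e-4,
    duration: float = 60_000.0,
    record_dt: float = 0.01,
) -> list[dict]:
    """FE-vs-BE accuracy table for one cell: single-cycle L2/Linf norms and
    the relative frequency error at each FE time step, against a BE reference
    at ``be_dt``.

    The reference protocol uses 60-s runs; shorter windows give the same
    single-cycle norms and a slightly coarser frequency estimate.
    """
    ref, _ = simulate_cell(params, duration, dt=be_dt, scheme="be",
                           record_dt=record_dt)
    rows = []
    for dt in fe_dts:
        test, _ = simulate_cell(params, duration, dt=dt, scheme="fe",
                                record_dt=max(record_dt, dt))
        rep = error_norms(ref, test, mode="both")
        rows.append({"dt": dt, "L2_pct": rep.L2, "Linf_pct": rep.Linf,
                     "freq_err_pct": rep.freq_err})
    return rows
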