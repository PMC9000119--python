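"""Action-potential cycle features, bifurcation-parameter sweeps, and
pacemaker-strand synchronization measures.

Feature definitions (per oscillation cycle, averaged over cycles):

* POP — peak overshoot potential (per-cycle maximum of u);
* MDP — maximum diastolic potential (per-cycle minimum of u);
* APD90 — time per cycle spent above the 90%-repolarization level
  ``POP - 0.9*(POP - MDP)``;
* DI — diastolic interval, ``CL - APD90``;
* CL — cycle length (ms) between consecutive upward mid-level crossings;
* frequency — 1000/CL in Hz.

A trace with fewer than three complete cycles after the settling window is
reported as quiescent, which is an outcome, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .events import cycle_crossings, upward_crossings, QUIESCENT_AMPLITUDE
from .integrators import Trace, TissueRun, run_tissue, simulate_cell, TissueModel
from .models import (APParams, CNParams, find_equilibria, get_preset,
                     DivergenceError)
from .topology import (StarSpec, build_star, star_probe_nodes,
                       REGION_PACEMAKER, REGION_STRAND)

__all__ = [
    "FeatureSet",
    "QUIESCENT",
    "extract_features",
    "orbit_orientation",
    "SweepResult",
    "sweep_parameter",
    "SyncResult",
    "measure_sync",
    "run_star_system",
    "scan_sync_limits",
]


@dataclass(frozen=True)
class FeatureSet:
    """Per-trace oscillation cycle features (see module docstring)."""

    POP: float
    MDP: float
    APD90: float
    DI: float
    CL: float
    frequency: float
    n_cycles: int

    @property
    def di_apd_ratio(self) -> float:
        return self.DI / self.APD90


#: sentinel for traces without sustained oscillation
QUIESCENT = None


def _time_above(t: np.ndarray, u: np.ndarray, level: float) -> float:
    """Total time u(t) > level over the sampled window, with linear
    interpolation at the threshold crossings."""
    above = u > level
    if not above.any():
        return 0.0
    total = 0.0
    start = None
    for i in range(len(t)):
        if above[i] and start is None:
            if i == 0:
                start = t[0]
            else:
                frac = (level - u[i - 1]) / (u[i] - u[i - 1])
                start = t[i - 1] + frac * (t[i] - t[i - 1])
        elif not above[i] and start is not None:
            frac = (level - u[i - 1]) / (u[i] - u[i - 1])
            total += t[i - 1] + frac * (t[i] - t[i - 1]) - start
            start = None
    if start is not None:
        total += t[-1] - start
    return total


def extract_features(trace: Trace, settle_time: float = 30_000.0) -> Optional[FeatureSet]:
    """Extract cycle features from the part of a trace after ``settle_time``
    ms.  Returns ``None`` (quiescent) when fewer than three complete cycles
    remain, or when the trace is (nearly) constant."""
    sel = trace.t >= settle_time
    t = np.asarray(trace.t[sel], dtype=float)
    u = np.asarray(trace.u[sel], dtype=float)
    if t.size < 4 or (u.max() - u.min()) < QUIESCENT_AMPLITUDE:
        return QUIESCENT
    cross = cycle_crossings(t, u)
    if cross.size < 4:  # need >= 3 complete cycles
        return QUIESCENT
    pops, mdps, apds, cls_ = [], [], [], []
    for a, b in zip(cross[:-1], cross[1:]):
        seg = (t >= a) & (t <= b)
        if seg.sum() < 3:
            continue
        ts, us = t[seg], u[seg]
        pop, mdp = float(us.max()), float(us.min())
        level = pop - 0.9 * (pop - mdp)
        apds.append(_time_above(ts, us, level))
        pops.append(pop)
        mdps.append(mdp)
        cls_.append(b - a)
    if len(cls_) < 3:
        return QUIESCENT
    cl = float(np.mean(cls_))
    apd = float(np.mean(apds))
    return FeatureSet(
        POP=float(np.mean(pops)), MDP=float(np.mean(mdps)),
        APD90=apd, DI=cl - apd, CL=cl, frequency=1000.0 / cl,
        n_cycles=len(cls_),
    )


def orbit_orientation(u: np.ndarray, w: np.ndarray) -> str:
    """Traversal direction of a (u, w) phase-plane orbit covering at least one
    cycle: "clockwise" or "counterclockwise" by the sign of the signed (shoelace)
    area.  Raises for an open or degenerate orbit."""
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    if u.size < 4 or (u.max() - u.min()) < QUIESCENT_AMPLITUDE:
        raise ValueError("orbit is quiescent or too short")
    area = 0.5 * float(np.sum(u * np.roll(w, -1) - np.roll(u, -1) * w))
    if area == 0.0:
        raise ValueError("degenerate orbit (zero enclosed area)")
    return "counterclockwise" if area > 0 else "clockwise"


# ---------------------------------------------------------------------------
# parameter sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepPoint:
    value: float
    features: Optional[FeatureSet]
    equilibria: list
    failed: bool = False


@dataclass
class SweepResult:
    """One row per grid value: features (or quiescent) plus equilibria."""

    parameter: str
    grid: np.ndarray
    points: list

    def frequencies(self) -> np.ndarray:
        return np.array([p.features.frequency if p.features else np.nan
                         for p in self.points])

    def oscillating(self) -> np.ndarray:
        return np.array([p.features is not None for p in self.points])


def sweep_parameter(
    preset,
    parameter: str,
    grid: Sequence[float],
    dt: float = 0.01,
    scheme: str = "be",
    settle_time: float = 30_000.0,
    measure_time: float = 20_000.0,
    record_dt: float = 0.1,
    eq_box=(-0.5, 1.5, -0.5, 3.0),
    eq_starts: int = 25,
) -> SweepResult:
    """Simulate one isolated cell per grid value of ``parameter`` and extract
    cycle features and equilibrium points.

    ``preset`` is a parameter dataclass or preset name.  Grid values must be
    strictly monotone.  Divergent points are recorded as failed and the sweep
    continues.
    """
    base = get_preset(preset) if isinstance(preset, str) else preset
    grid = np.asarray(grid, dtype=float)
    if grid.size > 1 and not (np.all(np.diff(grid) > 0) or np.all(np.diff(grid) < 0)):
        raise ValueError("grid must be strictly monotone")
    if not hasattr(base, parameter):
        raise AttributeError(f"{type(base).__name__} has no parameter {parameter!r}")
    points = []
    for val in grid:
        p = replace(base, **{parameter: float(val)})
        try:
            trace, _ = simulate_cell(p, settle_time + measure_time, dt=dt,
                                     scheme=scheme, record_dt=record_dt)
            feats = extract_features(trace, settle_time)
            eqs = find_equilibria(p, box=eq_box, n_starts=eq_starts)
            points.append(SweepPoint(float(val), feats, eqs))
        except (DivergenceError, ValueError):
            points.append(SweepPoint(float(val), None, [], failed=True))
    return SweepResult(parameter, grid, points)


# ---------------------------------------------------------------------------
# 1D pacemaker-strand synchronization
# ---------------------------------------------------------------------------

@dataclass
class SyncMeasure:
    """Frequency ratio between a pacemaker and a strand probe cell."""

    ratio: float                 # probe cycles / pacemaker cycles
    pacemaker_freq: float        # Hz
    probe_freq: float            # Hz
    n_pacemaker_cycles: int
    is_one_to_one: bool


def measure_sync(run: TissueRun, pacemaker_node: int, probe_node: int,
                 settle_time: float = 0.0) -> SyncMeasure:
    """Frequency ratio between two nodes from upward level-crossing counts
    after ``settle_time``.  1:1 synchronization is declared when
    ``|ratio - 1| < 1/n_pacemaker_cycles``.  Raises if the pacemaker is
    quiescent."""
    tp = run.cross_times[pacemaker_node]
    tq = run.cross_times[probe_node]
    tp = tp[np.isfinite(tp)]
    tq = tq[np.isfinite(tq)]
    tp = tp[tp >= settle_time]
    if tp.size < 2:
        raise ValueError("pacemaker is quiescent (fewer than 2 cycles)")
    n_p = tp.size - 1
    # probe events counted inside the pacemaker's cycle window, so a locked
    # pair gives exactly equal counts regardless of phase offset
    tq = tq[(tq >= tp[0]) & (tq < tp[-1])]
    n_q = tq.size
    ratio = n_q / n_p
    fp = 1000.0 * n_p / (tp[-1] - tp[0])
    fq = 1000.0 * (n_q - 1) / (tq[-1] - tq[0]) if tq.size >= 2 else 0.0
    return SyncMeasure(ratio=ratio, pacemaker_freq=fp, probe_freq=fq,
                       n_pacemaker_cycles=n_p,
                       is_one_to_one=abs(ratio - 1.0) < 1.0 / n_p)


def run_star_system(
    spec: StarSpec,
    pacemaker_params,
    strand_params,
    duration: float,
    dt: float = 0.01,
    scheme: str = "fe",
    state0=None,
    cross_capacity: int = 512,
) -> TissueRun:
    """Simulate a pacemaker + strand(s) system, collecting level-crossing
    events for synchronization measurements."""
    op = build_star(spec)
    model = TissueModel.from_regions(op, {REGION_PACEMAKER: pacemaker_params,
                                          REGION_STRAND: strand_params})
    state = model.initial_state() if state0 is None else state0
    probe = star_probe_nodes(spec)[0]
    return run_tissue(model, op, state, duration, dt, scheme=scheme,
                      record_nodes=np.array([0, probe], dtype=np.int64),
                      record_dt=max(dt, 1.0), cross_capacity=cross_capacity)


def star_sync_at(spec: StarSpec, pacemaker_params, strand_params, b: float,
                 duration: float = 30_000.0, dt: float = 0.02,
                 settle_time: float = 10_000.0) -> Optional[SyncMeasure]:
    """Synchronization measure at one value of the pacemaker control parameter
    ``b``; None when the pacemaker does not oscillate."""
    pm = replace(pacemaker_params, b=float(b))
    try:
        run = run_star_system(spec, pm, strand_params, duration, dt=dt)
        probe = star_probe_nodes(spec)[0]
        return measure_sync(run, 0, probe, settle_time=settle_time)
    except (ValueError, DivergenceError):
        return None


@dataclass
class SyncInterval:
    """A maximal 1:1-synchronized interval of the control parameter b."""

    b_lo: float
    b_hi: float
    freq_lo: float   # system frequency (Hz) at b_lo
    freq_hi: float   # system frequency (Hz) at b_hi


@dataclass
class SyncResult:
    """Per coupling value d: the 1:1-synchronized interval(s) of b, their
    boundary frequencies, and the overall min/max synchronized frequency."""

    d_grid: np.ndarray
    intervals: list           # list (per d) of lists of SyncInterval
    min_freq: np.ndarray      # Hz, NaN where no 1:1 value was found
    max_freq: np.ndarray
    min_b: np.ndarray
    max_b: np.ndarray


def scan_sync_limits(
    pacemaker_params,
    strand_params,
    d_grid: Sequence[float],
    b_range: tuple[float, float],
    n: float = 1.0,
    cells_per_strand: int = 20,
    n_b: int = 17,
    b_tol: float = 1e-3,
    duration: float = 30_000.0,
    dt: float = 0.02,
    settle_time: float = 10_000.0,
) -> SyncResult:
    """Locate the 1:1 synchronization region(s) in the control parameter b for
    each coupling coefficient d.

    A coarse scan over ``n_b`` values of b marks 1:1 points; each maximal run
    of 1:1 points becomes an interval whose boundaries are refined by
    bisection down to ``b_tol``.  Regions may be disjoint.  An empty entry
    (no 1:1 value at a given d) is a result, not an error.
    """
    d_grid = np.asarray(d_grid, dtype=float)
    bs = np.linspace(b_range[0], b_range[1], n_b)
    all_intervals = []
    min_f = np.full(d_grid.size, np.nan)
    max_f = np.full(d_grid.size, np.nan)
    min_b = np.full(d_grid.size, np.nan)
    max_b = np.full(d_grid.size, np.nan)

    for di, d in enumerate(d_grid):
        spec = StarSpec(n=n, cells_per_strand=cells_per_strand, d=float(d))

        def sync_ok(b):
            m = star_sync_at(spec, pacemaker_params, strand_params, b,
                             duration=duration, dt=dt, settle_time=settle_time)
            return m is not None and m.is_one_to_one, m

        flags = []
        measures = []
        for b in bs:
            ok, m = sync_ok(b)
            flags.append(ok)
            measures.append(m)
        intervals = []
        i = 0
        while i < len(bs):
            if not flags[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(bs) and flags[j + 1]:
                j += 1
            # refine the outer boundaries by bisection
            b_lo = bs[i]
            if i > 0:
                lo, hi = bs[i - 1], bs[i]
                while hi - lo > b_tol:
                    mid = 0.5 * (lo + hi)
                    ok, _ = sync_ok(mid)
                    if ok:
                        hi = mid
                    else:
                        lo = mid
                b_lo = hi
            b_hi = bs[j]
            if j + 1 < len(bs):
                lo, hi = bs[j], bs[j + 1]
                while hi - lo > b_tol:
                    mid = 0.5 * (lo + hi)
                    ok, _ = sync_ok(mid)
                    if ok:
                        lo = mid
                    else:
                        hi = mid
                b_hi = lo
            _, m_lo = sync_ok(b_lo)
            _, m_hi = sync_ok(b_hi)
            f_lo = m_lo.pacemaker_freq if m_lo else np.nan
            f_hi = m_hi.pacemaker_freq if m_hi else np.nan
            intervals.append(SyncInterval(float(b_lo), float(b_hi), f_lo, f_hi))
            i = j + 1
        all_intervals.append(intervals)
        if intervals:
            freqs = [f for iv in intervals for f in (iv.freq_lo, iv.freq_hi)
                     if math.isfinite(f)]
            if freqs:
                min_f[di] = min(freqs)
                max_f[di] = max(freqs)
            min_b[di] = intervals[0].b_lo
            max_b[di] = intervals[-1].b_hi
    return SyncResult(d_grid, all_intervals, min_f, max_f, min_b, max_b)
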