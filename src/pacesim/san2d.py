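"""2D sinoatrial-node (SAN) tissue: an elliptical patch of pacemaking cells
embedded in excitable atrial tissue on a square grid.

Two structure types are supported:

* type 1 — no insulating border; the whole tissue is anisotropic with
  Dy:Dx = 1:0.208 (fibers along y) and the SAN ellipse (half-axes 3 and 1 mm,
  long axis 30 degrees off the fiber direction) differs from the atrium only
  in its cell parameters.  Strong coupling (Dy = 0.090 mm^2/ms) entrains the
  atrium 1:1 at about 120 cycles per minute; weak coupling (Dy = 0.048)
  produces partial exit block with a 2:5 atrial:SAN cycle ratio.
* type 2 — isotropic tissue; the ellipse is surrounded by a thin ring of
  passive (linearly decaying) tissue pierced by four 1-mm exit pathways
  centered on the ellipse axes.  The atrium keeps D_A = 0.160 mm^2/ms while
  the SAN/pathway diffusion D_S controls exit block (1:1 at 0.060, 1:2 at
  0.052).

The "central line" diagnostics run along the ellipse's long axis extended to
the domain boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .integrators import StateField, TissueModel, Trace, run_tissue, stability_check
from .models import APParams, PassiveParams, get_preset
from .topology import CouplingOperator, Grid2DSpec, build_grid2d

__all__ = [
    "REGION_SAN",
    "REGION_ATRIUM",
    "REGION_PASSIVE",
    "REGION_PATHWAY",
    "SANExperiment",
    "san_geometry",
    "run_san",
    "SANResult",
    "activation_sequence",
    "line_cycle_counts",
]

REGION_SAN = 0
REGION_ATRIUM = 1
REGION_PASSIVE = 2
REGION_PATHWAY = 3

_REGION_NAMES = {REGION_SAN: "SAN", REGION_ATRIUM: "atrium",
                 REGION_PASSIVE: "passive", REGION_PATHWAY: "pathway"}


def _ellipse_coords(nx, ny, dx, rotation_deg, cx=None, cy=None):
    """Coordinates along (c1) and across (c2) the ellipse long axis for every
    node; the long axis is rotated ``rotation_deg`` off the y (fiber) axis."""
    x = np.arange(nx) * dx
    y = np.arange(ny) * dx
    cx = 0.5 * (nx - 1) * dx if cx is None else cx
    cy = 0.5 * (ny - 1) * dx if cy is None else cy
    X, Y = np.meshgrid(x - cx, y - cy)
    th = math.radians(rotation_deg)
    e1 = (math.sin(th), math.cos(th))     # long-axis direction
    e2 = (math.cos(th), -math.sin(th))    # short-axis direction
    c1 = X * e1[0] + Y * e1[1]
    c2 = X * e2[0] + Y * e2[1]
    return c1, c2


@dataclass
class SANExperiment:
    """A ready-to-run SAN tissue experiment (see :func:`san_geometry`)."""

    structure_type: int
    grid: Grid2DSpec
    region_params: dict
    dt: float
    duration: float
    scheme: str = "fe"
    line_nodes: np.ndarray = None
    meta: dict = field(default_factory=dict)


def san_geometry(
    structure_type: int = 1,
    D: float = 0.090,
    D_S: float = 0.060,
    D_A: float = 0.160,
    nx: int = 200,
    ny: int = 200,
    dx: float = 0.05,
    dt: float = 0.002,
    duration: float = 4_000.0,
    semi_major: float = 3.0,
    semi_minor: float = 1.0,
    rotation_deg: float = 30.0,
    border_mm: float = 0.25,
    pathway_mm: float = 1.0,
    anisotropy: float = 0.208,
    san_params: Optional[APParams] = None,
    atrium_params: Optional[APParams] = None,
    passive_params: Optional[PassiveParams] = None,
    scheme: str = "fe",
) -> SANExperiment:
    """Build the mask, per-region diffusion fields and parameters for a SAN
    experiment.

    Type 1 uses ``D`` as the fiber-direction coefficient Dy with
    Dx = ``anisotropy``*Dy everywhere.  Type 2 is isotropic: ``D_A`` in the
    atrium and ``D_S`` in the SAN ellipse, its passive border ring (thickness
    ``border_mm``) and the four exit pathways (width ``pathway_mm``) centered
    on the ellipse axes.
    """
    if structure_type not in (1, 2):
        raise ValueError("structure_type must be 1 or 2")
    c1, c2 = _ellipse_coords(nx, ny, dx, rotation_deg)
    inside = (c1 / semi_major) ** 2 + (c2 / semi_minor) ** 2 <= 1.0
    mask = np.full((ny, nx), REGION_ATRIUM, dtype=np.int32)
    mask[inside] = REGION_SAN

    if structure_type == 1:
        san = get_preset("pAP-SAN1") if san_params is None else san_params
        Dy = np.full((ny, nx), D)
        Dx = anisotropy * Dy
        region_params = {
            REGION_SAN: san,
            REGION_ATRIUM: get_preset("AP-atrium") if atrium_params is None else atrium_params,
        }
    else:
        san = get_preset("pAP-SAN2") if san_params is None else san_params
        ring = ~inside & ((c1 / (semi_major + border_mm)) ** 2 +
                          (c2 / (semi_minor + border_mm)) ** 2 <= 1.0)
        half_w = 0.5 * pathway_mm
        pathway = ring & ((np.abs(c2) <= half_w) | (np.abs(c1) <= half_w))
        mask[ring] = REGION_PASSIVE
        mask[pathway] = REGION_PATHWAY
        Dv = np.full((ny, nx), D_A)
        Dv[mask != REGION_ATRIUM] = D_S
        Dx = Dv
        Dy = Dv.copy()
        region_params = {
            REGION_SAN: san,
            REGION_PATHWAY: san,
            REGION_ATRIUM: get_preset("AP-atrium") if atrium_params is None else atrium_params,
            REGION_PASSIVE: PassiveParams() if passive_params is None else passive_params,
        }

    grid = Grid2DSpec(nx=nx, ny=ny, dx=dx, Dx=Dx, Dy=Dy, mask=mask,
                      region_names=dict(_REGION_NAMES))

    # nodes along the ellipse long axis, extended to the domain boundary
    th = math.radians(rotation_deg)
    cxy = (0.5 * (nx - 1) * dx, 0.5 * (ny - 1) * dx)
    smax = math.hypot(nx * dx, ny * dx)
    line = []
    for s in np.arange(-smax, smax, dx / 2):
        px = cxy[0] + s * math.sin(th)
        py = cxy[1] + s * math.cos(th)
        ix, iy = int(round(px / dx)), int(round(py / dx))
        if 0 <= ix < nx and 0 <= iy < ny:
            node = iy * nx + ix
            if not line or line[-1] != node:
                line.append(node)
    return SANExperiment(structure_type, grid, region_params, dt, duration,
                         scheme=scheme, line_nodes=np.array(line, dtype=np.int64),
                         meta={"D": D, "D_S": D_S, "D_A": D_A})


@dataclass
class SANResult:
    """Output of :func:`run_san`."""

    exp: SANExperiment
    op: CouplingOperator
    line_trace: Trace            # u along the central line
    cross_times: np.ndarray      # (n_nodes, capacity)
    cross_count: np.ndarray
    state: StateField


def run_san(exp: SANExperiment, record_dt: float = 2.0,
            cross_capacity: int = 64, force: bool = False) -> SANResult:
    """Run a SAN experiment from the standard initial conditions
    (u = v = 0.01), recording the central-line trace and per-node upward
    crossings of u = 0.5 (cycle counts / activation times).

    Under forward Euler the diffusion stability bound is checked first and a
    violation raises unless ``force``.
    """
    spec = exp.grid
    if exp.scheme == "fe" and not force:
        D_max = float(max(spec.Dx.max(), spec.Dy.max()))
        ok, margin = stability_check(D_max, spec.dx, exp.dt, N=2)
        if not ok:
            raise ValueError(
                f"forward Euler unstable: d*dt = {margin:.3f} >= 0.25 "
                f"(D={D_max}, dx={spec.dx}, dt={exp.dt}); reduce dt or use BE")
    op = build_grid2d(spec)
    model = TissueModel.from_regions(op, exp.region_params)
    state = model.initial_state()
    run = run_tissue(model, op, state, exp.duration, exp.dt,
                     scheme=exp.scheme, record_nodes=exp.line_nodes,
                     record_dt=record_dt, cross_capacity=cross_capacity)
    return SANResult(exp, op, run.trace, run.cross_times, run.cross_count,
                     state)


def _window_rate_cpm(times: np.ndarray, lo: float, hi: float) -> Optional[float]:
    tc = times[np.isfinite(times)]
    tc = tc[(tc >= lo) & (tc <= hi)]
    if tc.size < 2:
        return None
    return 60_000.0 * (tc.size - 1) / (tc[-1] - tc[0])


def line_cycle_counts(res: SANResult, window: tuple[float, float]):
    """Per-region diagnostics over a time window: (SAN rate cpm, atrial rate
    cpm, SAN cycle count, atrial cycle count) measured at the SAN-center node
    and at an atrial node on the central line three quarters of the way out."""
    lo, hi = window
    region = res.op.region
    line = res.exp.line_nodes
    san_line = line[region[line] == REGION_SAN]
    atr_line = line[region[line] == REGION_ATRIUM]
    san_node = san_line[len(san_line) // 2]
    atr_node = atr_line[int(len(atr_line) * 0.9)]

    def count(node):
        tc = res.cross_times[node]
        tc = tc[np.isfinite(tc)]
        return int(((tc >= lo) & (tc <= hi)).sum())

    return {
        "san_rate_cpm": _window_rate_cpm(res.cross_times[san_node], lo, hi),
        "atrial_rate_cpm": _window_rate_cpm(res.cross_times[atr_node], lo, hi),
        "san_cycles": count(san_node),
        "atrial_cycles": count(atr_node),
        "san_node": int(san_node),
        "atrial_node": int(atr_node),
    }


def activation_sequence(res: SANResult, cycle_index: int = -2) -> np.ndarray:
    """Per-node activation-time map (ms, relative to the earliest activation)
    for one propagated beat.

    The beat window is delimited by consecutive crossings of the SAN-center
    node (``cycle_index`` selects which; negative indexes count from the last
    complete beat).  Nodes that never activate within the window are NaN.
    Raises if no node activates.
    """
    region = res.op.region
    line = res.exp.line_nodes
    san_line = line[region[line] == REGION_SAN]
    center = san_line[len(san_line) // 2]
    tc = res.cross_times[center]
    tc = tc[np.isfinite(tc)]
    if tc.size < 2:
        raise ValueError("SAN center never activated twice; no beat to map")
    starts = tc[:-1]
    t0 = starts[cycle_index]
    t1 = tc[list(tc).index(t0) + 1]
    n = res.op.n_nodes
    act = np.full(n, np.nan)
    for i in range(n):
        ti = res.cross_times[i]
        ti = ti[np.isfinite(ti)]
        ti = ti[(ti >= t0) & (ti < t1)]
        if ti.size:
            act[i] = ti[0]
    if not np.isfinite(act).any():
        raise ValueError("no node activated in the selected beat")
    act -= np.nanmin(act)
    ny, nx = res.exp.grid.ny, res.exp.grid.nx
    return act.reshape(ny, nx)
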