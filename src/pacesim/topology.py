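"""Coupling (electrotonic diffusion) operators over cell networks.

An operator is a sparse matrix ``L`` of weights in ms^-1 applied to the
potential field: the coupling current at node ``i`` is ``(L u)_i``.  Diffusive
rows sum to zero (discrete flux conservation) under both no-flux and periodic
boundary conditions; off-diagonal weights are non-negative.

Supported geometries:

* 0D — a single uncoupled cell (empty operator);
* 1D star — one pacemaker driving ``n`` identical strands of excitable cells,
  with non-integer ``n`` representing a fractional load;
* 2D grid — 5-point stencil with per-region, per-axis diffusion coefficients
  (anisotropy) and no-flux edges;
* dual-layer cylinder — two stacked 2D sheets (inner pacemaker layer, outer
  muscular layer), periodic around the circumference, no-flux at the tube
  ends, with pointwise inter-layer coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

__all__ = [
    "CouplingOperator",
    "StarSpec",
    "Grid2DSpec",
    "CylinderSpec",
    "build_single",
    "build_star",
    "build_grid2d",
    "build_cylinder",
]


@dataclass
class CouplingOperator:
    """Sparse coupling structure over ``n_nodes`` cells.

    ``matrix`` holds weights in ms^-1 (CSR).  ``region`` labels each node with
    an integer code interpreted through ``region_names``.  ``shape`` is the
    logical grid shape for grid-based operators (None for graphs).
    """

    n_nodes: int
    matrix: sp.csr_matrix
    boundary: str = "no-flux"
    region: Optional[np.ndarray] = None
    region_names: dict = field(default_factory=dict)
    shape: Optional[tuple] = None
    dx: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def apply(self, u: np.ndarray) -> np.ndarray:
        """Coupling current L @ u (per ms)."""
        return self.matrix @ u

    def csr_arrays(self):
        m = self.matrix
        return m.indptr, m.indices, m.data

    def max_offdiag(self) -> float:
        """Largest off-diagonal weight (ms^-1), i.e. the stiffest d = D/dx^2."""
        m = self.matrix.tocoo()
        off = m.data[m.row != m.col]
        return float(off.max()) if off.size else 0.0


def _to_csr(n: int, rows, cols, vals) -> sp.csr_matrix:
    return sp.coo_matrix(
        (np.asarray(vals, dtype=float),
         (np.asarray(rows, dtype=np.int64), np.asarray(cols, dtype=np.int64))),
        shape=(n, n),
    ).tocsr()


def build_single() -> CouplingOperator:
    """Operator for an isolated cell (no coupling)."""
    return CouplingOperator(1, sp.csr_matrix((1, 1)), region=np.zeros(1, dtype=np.int32),
                            region_names={0: "cell"})


# ---------------------------------------------------------------------------
# 1D star (pacemaker + n strands)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StarSpec:
    """One pacemaker cell loaded by ``n`` strands of ``cells_per_strand``
    excitable cells with nearest-neighbour coupling ``d`` (ms^-1).

    ``n`` may be fractional: a value like 0.5 means half the load of one
    strand.  Integer ``n`` builds explicit strands; fractional ``n`` builds a
    single strand whose current into the pacemaker is scaled by ``n`` —
    exactly equivalent for synchronized identical strands and continuous in
    ``n``.
    """

    n: float = 1.0
    cells_per_strand: int = 20
    d: float = 1.0

    def __post_init__(self):
        if not (self.n > 0):
            raise ValueError("strand multiplicity n must be positive")
        if self.d < 0:
            raise ValueError("coupling d must be non-negative")
        if self.cells_per_strand < 1:
            raise ValueError("cells_per_strand must be >= 1")


REGION_PACEMAKER = 0
REGION_STRAND = 1


def build_star(spec: StarSpec) -> CouplingOperator:
    """Build the star coupling operator.  Node 0 is the pacemaker; strand
    ``s`` occupies nodes ``1 + s*m .. (s+1)*m`` (``m = cells_per_strand``),
    ordered from the pacemaker outward.  The far end of each strand is
    no-flux."""
    m = spec.cells_per_strand
    d = spec.d
    integer_n = abs(spec.n - round(spec.n)) < 1e-12
    n_strands = int(round(spec.n)) if integer_n else 1
    pm_scale = 1.0 if integer_n else spec.n

    n_nodes = 1 + n_strands * m
    rows, cols, vals = [], [], []

    def add(i, j, w):
        rows.append(i)
        cols.append(j)
        vals.append(w)

    for s in range(n_strands):
        first = 1 + s * m
        # pacemaker <- first cell of this strand (scaled for fractional load)
        add(0, first, pm_scale * d)
        add(0, 0, -pm_scale * d)
        # first cell <- pacemaker
        add(first, 0, d)
        add(first, first, -d)
        for j in range(m):
            node = first + j
            if j + 1 < m:
                add(node, node + 1, d)
                add(node, node, -d)
                add(node + 1, node, d)
                add(node + 1, node + 1, -d)
    region = np.full(n_nodes, REGION_STRAND, dtype=np.int32)
    region[0] = REGION_PACEMAKER
    op = CouplingOperator(
        n_nodes, _to_csr(n_nodes, rows, cols, vals),
        region=region,
        region_names={REGION_PACEMAKER: "pacemaker", REGION_STRAND: "strand"},
        meta={"n": spec.n, "cells_per_strand": m, "d": d, "n_strands": n_strands},
    )
    return op


def star_probe_nodes(spec: StarSpec, cell: Optional[int] = None) -> list[int]:
    """Node indices of the ``cell``-th cell (1-based from the pacemaker) in
    each strand; used for synchronization measurements.

    Defaults to cell 16 of a 20-cell strand (away from the sealed end, to
    avoid boundary effects) or the equivalent 80% position of shorter strands.
    """
    m = spec.cells_per_strand
    integer_n = abs(spec.n - round(spec.n)) < 1e-12
    n_strands = int(round(spec.n)) if integer_n else 1
    if cell is None:
        cell = min(16, max(1, int(round(0.8 * m))))
    if not (1 <= cell <= m):
        raise ValueError("probe cell outside strand")
    return [1 + s * m + (cell - 1) for s in range(n_strands)]


# ---------------------------------------------------------------------------
# 2D grid
# ---------------------------------------------------------------------------

@dataclass
class Grid2DSpec:
    """Rectangular grid with per-node diffusion coefficients.

    ``Dx``/``Dy`` are (ny, nx) arrays in mm^2/ms; ``mask`` is an integer
    region-label array of the same shape.  Node (iy, ix) sits at
    ``x = ix*dx, y = iy*dx``; arrays are row-major with y as the leading axis.
    """

    nx: int
    ny: int
    dx: float
    Dx: np.ndarray
    Dy: np.ndarray
    mask: np.ndarray
    region_names: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("Dx", "Dy", "mask"):
            arr = getattr(self, name)
            if arr.shape != (self.ny, self.nx):
                raise ValueError(f"{name} must have shape (ny, nx)")
        if (self.Dx < 0).any() or (self.Dy < 0).any():
            raise ValueError("diffusion coefficients must be non-negative")


def build_grid2d(spec: Grid2DSpec) -> CouplingOperator:
    """5-point stencil with face coefficients equal to the arithmetic mean of
    the two adjacent nodes' D over dx^2 (heterogeneous interfaces), no-flux
    outer boundary."""
    nx, ny, dx2 = spec.nx, spec.ny, spec.dx ** 2
    idx = np.arange(nx * ny).reshape(ny, nx)
    rows, cols, vals = [], [], []

    # horizontal faces (x direction) use Dx
    wx = 0.5 * (spec.Dx[:, :-1] + spec.Dx[:, 1:]) / dx2
    left, right = idx[:, :-1].ravel(), idx[:, 1:].ravel()
    w = wx.ravel()
    rows += [left, right, left, right]
    cols += [right, left, left, right]
    vals += [w, w, -w, -w]

    # vertical faces (y direction) use Dy
    wy = 0.5 * (spec.Dy[:-1, :] + spec.Dy[1:, :]) / dx2
    lo, hi = idx[:-1, :].ravel(), idx[1:, :].ravel()
    w = wy.ravel()
    rows += [lo, hi, lo, hi]
    cols += [hi, lo, lo, hi]
    vals += [w, w, -w, -w]

    mat = _to_csr(nx * ny, np.concatenate(rows), np.concatenate(cols), np.concatenate(vals))
    return CouplingOperator(
        nx * ny, mat,
        region=spec.mask.ravel().astype(np.int32),
        region_names=dict(spec.region_names),
        shape=(ny, nx), dx=spec.dx,
    )


# ---------------------------------------------------------------------------
# dual-layer cylinder
# ---------------------------------------------------------------------------

@dataclass
class CylinderSpec:
    """Dual-layer tube cut open along its axis: two (ny, nx) sheets.

    ``nx`` spans the circumference (periodic by default), ``ny`` the tube
    length (no-flux ends).  ``D_inner``/``D_outer`` are the intra-layer
    isotropic diffusion coefficients (mm^2/ms) and ``d_between`` the pointwise
    inter-layer coupling (ms^-1).  The physical tube of the reference
    experiment is 44 mm around (nx=176) and 1200 mm long (ny=4800) at
    dx = 0.25 mm.
    """

    nx: int = 176
    ny: int = 4800
    dx: float = 0.25
    D_inner: float = 5e-5
    D_outer: float = 8e-4
    d_between: float = 6e-3
    periodic_axis: str = "x"  # circumference; "y" reproduces the printed text

    def __post_init__(self):
        if self.periodic_axis not in ("x", "y"):
            raise ValueError("periodic_axis must be 'x' or 'y'")
        if min(self.D_inner, self.D_outer) < 0 or self.d_between < 0:
            raise ValueError("coupling coefficients must be non-negative")


LAYER_INNER = 0   # pacemaker (ICC) layer
LAYER_OUTER = 1   # muscular (SMC) layer


def build_cylinder(spec: CylinderSpec) -> CouplingOperator:
    """Two stacked sheets with per-layer 5-point stencils (one axis periodic,
    the other no-flux) plus antisymmetric pointwise inter-layer coupling
    ``d_between * (u_other - u_self)``.

    Node layout: ``index = layer*(nx*ny) + iy*nx + ix``; layer 0 is the inner
    (pacemaker) layer.
    """
    nx, ny, dx2 = spec.nx, spec.ny, spec.dx ** 2
    npl = nx * ny  # nodes per layer
    rows, cols, vals = [], [], []

    for layer, D in ((LAYER_INNER, spec.D_inner), (LAYER_OUTER, spec.D_outer)):
        base = layer * npl
        idx = base + np.arange(npl).reshape(ny, nx)
        d = D / dx2
        if d > 0:
            # x-neighbours
            a, b = idx[:, :-1].ravel(), idx[:, 1:].ravel()
            if spec.periodic_axis == "x" and nx > 2:
                a = np.concatenate([a, idx[:, -1]])
                b = np.concatenate([b, idx[:, 0]])
            w = np.full(a.shape, d)
            rows += [a, b, a, b]
            cols += [b, a, a, b]
            vals += [w, w, -w, -w]
            # y-neighbours
            a, b = idx[:-1, :].ravel(), idx[1:, :].ravel()
            if spec.periodic_axis == "y" and ny > 2:
                a = np.concatenate([a, idx[-1, :]])
                b = np.concatenate([b, idx[0, :]])
            w = np.full(a.shape, d)
            rows += [a, b, a, b]
            cols += [b, a, a, b]
            vals += [w, w, -w, -w]

    if spec.d_between > 0:
        inner = np.arange(npl)
        outer = npl + inner
        w = np.full(npl, spec.d_between)
        rows += [inner, outer, inner, outer]
        cols += [outer, inner, inner, outer]
        vals += [w, w, -w, -w]

    n = 2 * npl
    mat = _to_csr(n,
                  np.concatenate([np.asarray(r) for r in rows]) if rows else [],
                  np.concatenate([np.asarray(c) for c in cols]) if cols else [],
                  np.concatenate([np.asarray(v) for v in vals]) if vals else [])
    region = np.concatenate([np.full(npl, LAYER_INNER, dtype=np.int32),
                             np.full(npl, LAYER_OUTER, dtype=np.int32)])
    return CouplingOperator(
        n, mat, boundary=f"periodic-{spec.periodic_axis}",
        region=region,
        region_names={LAYER_INNER: "inner", LAYER_OUTER: "outer"},
        shape=(2, ny, nx), dx=spec.dx,
        meta={"d_between": spec.d_between},
    )
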