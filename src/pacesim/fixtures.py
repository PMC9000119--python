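"""Tiny reproducible fixtures: scaled-down versions of each tissue experiment
with stored reference traces and checksums, for regression testing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .config import write_table
from .features import measure_sync
from .integrators import TissueModel, run_tissue, stability_check
from .models import get_preset
from .san2d import san_geometry, run_san
from .topology import StarSpec, build_star, star_probe_nodes
from .intestine3d import IntestineExperiment, run_intestine


def _checksum(arr: np.ndarray) -> str:
    # single-precision quantization so the checksum tolerates last-bit
    # differences from FMA/reassociation across builds
    a = np.asarray(arr, dtype=np.float32)
    return hashlib.sha256(a.tobytes()).hexdigest()[:16]


def make_fixtures(out_dir: str | Path, scale: float = 1.0) -> dict:
    """Generate the bundled tiny fixtures under ``out_dir``.

    * 5-cell strand (pCN pacemaker + CN cells, d = 1.0, b = 1.0; at this
      coupling strength lower b leaves the loaded pacemaker quiescent) —
      verified 1:1 synchronized at creation; backward-Euler reference trace.
    * 8x8 SAN grid (type 1) — verified against the explicit stability bound
      at its stored dt.
    * 16x60 dual-layer intestine — short forward-Euler reference.

    ``scale`` multiplies the reference-trace durations.  Returns the manifest
    (also written as ``manifest.json``); regeneration is idempotent.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}

    # --- 5-cell strand ----------------------------------------------------
    spec = StarSpec(n=1, cells_per_strand=5, d=1.0)
    op = build_star(spec)
    model = TissueModel.from_regions(op, {0: get_preset("pCN-1D", b=1.0),
                                          1: get_preset("CN-1D")})
    state = model.initial_state()
    dur = 8000.0 * scale
    run = run_tissue(model, op, state, dur, dt=0.001, scheme="be",
                     record_nodes=np.array([0, 3], dtype=np.int64),
                     record_dt=1.0, cross_capacity=256)
    sync = measure_sync(run, 0, 3, settle_time=dur * 0.25)
    if not sync.is_one_to_one:
        raise RuntimeError("strand fixture failed its 1:1 sync check")
    write_table(out / "strand_trace.tsv",
                {"t": run.trace.t, "u_pacemaker": run.trace.u[:, 0],
                 "u_cell3": run.trace.u[:, 1]},
                units={"t": "ms"})
    manifest["strand"] = {
        "spec": {"n": 1, "cells_per_strand": 5, "d": 1.0, "b": 1.0},
        "sync_ratio": sync.ratio,
        "checksum_u": _checksum(run.trace.u),
    }

    # --- 8x8 SAN grid ------------------------------------------------------
    exp = san_geometry(structure_type=1, D=0.090, nx=8, ny=8, dx=0.5,
                       dt=0.1, duration=2000.0 * scale,
                       semi_major=1.5, semi_minor=0.5)
    ok, margin = stability_check(0.090, 0.5, 0.1, N=2)
    if not ok:
        raise RuntimeError("SAN fixture violates its own stability bound")
    res = run_san(exp, record_dt=5.0)
    write_table(out / "san_line_trace.tsv",
                {"t": res.line_trace.t,
                 **{f"u{j}": res.line_trace.u[:, j]
                    for j in range(res.line_trace.u.shape[1])}},
                units={"t": "ms"})
    manifest["san8x8"] = {
        "dt": 0.1, "dx": 0.5, "stability_margin": margin,
        "checksum_u": _checksum(res.line_trace.u),
    }

    # --- 16x60 intestine ---------------------------------------------------
    iexp = IntestineExperiment.scaled(factor=80.0, nx=16, ny=60,
                                      duration=300_000.0 * scale)
    iexp.block = None
    ires = run_intestine(iexp, freq_window=(100_000.0 * scale, 300_000.0 * scale),
                         probe_y_mm=(2.0, 14.0))
    write_table(out / "intestine_profile.tsv",
                {"y_mm": ires.y_mm, "freq_cpm": ires.freq_cpm},
                units={"y_mm": "mm", "freq_cpm": "cpm"})
    manifest["intestine16x60"] = {
        "checksum_freq": _checksum(np.nan_to_num(ires.freq_cpm)),
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
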