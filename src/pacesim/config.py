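"""Run configuration: YAML/dict parsing, preset lookup with type-checked
overrides, and deterministic serialization of results to delimited text."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from .models import PRESETS, get_preset

__all__ = ["RunConfig", "load_config", "write_table", "write_snapshots"]


@dataclasses.dataclass
class RunConfig:
    """Parsed configuration of one CLI run.

    ``kind`` selects the experiment; ``preset``/``overrides`` name the cell
    parameters; integrator fields mirror the CLI flags.  ``seed`` only feeds
    the jitter of multi-start equilibrium searches — the simulations
    themselves are deterministic.
    """

    kind: str
    preset: Optional[str] = None
    overrides: dict = dataclasses.field(default_factory=dict)
    scheme: str = "fe"
    dt: float = 0.01
    duration: float = 40_000.0
    out: Optional[str] = None
    seed: int = 0
    extra: dict = dataclasses.field(default_factory=dict)

    KINDS = ("cell", "sweep", "strand", "sync-scan", "san", "intestine",
             "verify", "fixtures")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}")
        if self.preset is not None and self.preset not in PRESETS:
            raise KeyError(f"unknown preset {self.preset!r}")

    def params(self):
        """Resolve preset + overrides into a parameter dataclass (overrides
        are type-checked against the preset's fields)."""
        if self.preset is None:
            raise ValueError("no preset named in configuration")
        return get_preset(self.preset, **self.overrides)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config file into a :class:`RunConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig) if f.name != "extra"}
    kw = {k: v for k, v in raw.items() if k in known}
    extra = {k: v for k, v in raw.items() if k not in known}
    return RunConfig(extra=extra, **kw)


def write_table(path: str | Path, columns: dict, units: Optional[dict] = None) -> None:
    """Write named columns as tab-delimited text with a ``# name (unit)``
    header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = list(columns)
    arrays = [np.asarray(columns[k]) for k in names]
    n = max(a.shape[0] for a in arrays)
    header = "\t".join(
        f"{k} ({units[k]})" if units and k in units else k for k in names)
    with open(path, "w") as fh:
        fh.write("# " + header + "\n")
        for i in range(n):
            row = []
            for a in arrays:
                v = a[i] if i < a.shape[0] else np.nan
                row.append(f"{v:.10g}" if isinstance(v, (float, np.floating)) else str(v))
            fh.write("\t".join(row) + "\n")


def write_snapshots(path: str | Path, datasets: dict, attrs: Optional[dict] = None) -> None:
    """Write arrays to an HDF5 container (datasets keyed by name); falls back
    to ``.npz`` when h5py is unavailable."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        import h5py
    except ImportError:
        np.savez_compressed(path.with_suffix(".npz"), **datasets)
        return
    with h5py.File(path, "w") as fh:
        for k, v in datasets.items():
            fh.create_dataset(k, data=np.asarray(v))
        for k, v in (attrs or {}).items():
            fh.attrs[k] = v
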