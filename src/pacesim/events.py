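"""Cycle detection on sampled potential traces.

Cycles are delimited by upward crossings of a mid-amplitude level.  The level
is found iteratively: a first pass uses the global min/max of the trace, a
second pass recomputes the level from per-cycle extrema, which makes the
detection robust to settling transients and baseline drift.
"""

from __future__ import annotations

import numpy as np

__all__ = ["upward_crossings", "cycle_crossings", "QUIESCENT_AMPLITUDE"]

#: traces whose peak-to-peak amplitude is below this are treated as quiescent
QUIESCENT_AMPLITUDE = 1e-3


def upward_crossings(t: np.ndarray, u: np.ndarray, level: float) -> np.ndarray:
    """Times of upward crossings of ``level``, linearly interpolated."""
    t = np.asarray(t, dtype=float)
    u = np.asarray(u, dtype=float)
    below = u[:-1] < level
    above = u[1:] >= level
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return np.empty(0)
    frac = (level - u[idx]) / (u[idx + 1] - u[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def cycle_crossings(t: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Cycle-start times: upward crossings of the iterated mid-level.

    Returns an empty array when the trace is (nearly) constant or never
    crosses its mid level.
    """
    u = np.asarray(u, dtype=float)
    lo, hi = float(np.min(u)), float(np.max(u))
    if hi - lo < QUIESCENT_AMPLITUDE:
        return np.empty(0)
    level = 0.5 * (lo + hi)
    cross = upward_crossings(t, u, level)
    if cross.size < 3:
        return cross
    # second pass: per-cycle extrema give a drift-robust mid level
    pops, mdps = [], []
    for a, b in zip(cross[:-1], cross[1:]):
        seg = u[(t >= a) & (t < b)]
        if seg.size:
            pops.append(seg.max())
            mdps.append(seg.min())
    if pops:
        level2 = 0.5 * (float(np.mean(mdps)) + float(np.mean(pops)))
        cross2 = upward_crossings(t, u, level2)
        if cross2.size >= 2:
            return cross2
    return cross
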