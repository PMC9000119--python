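"""Two-variable cell models: Aliev-Panfilov (AP) family, Corrado (CN) family,
and passive (non-excitable) tissue.

Both excitable models describe a normalized transmembrane potential ``u`` and a
single slow variable (recovery ``v`` for the AP family, inactivation gate ``h``
for the CN family).  The pacemaking variants (pAP, pCN) are obtained by
replacing the excitation-threshold parameter inside the cubic source term of
the ``u``-equation with a sign-flipped control parameter ``b``: for ``b > 0``
the resting state loses stability through a Hopf bifurcation and the cell
oscillates spontaneously; ``b = -a`` (AP) or ``b = -u_gate`` (CN) recovers the
conventional excitable model exactly.

Time is in milliseconds throughout.  The AP family carries an explicit time
scaling coefficient ``c_t = 1/12.9`` per ms; the CN family's time constants are
already in ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CT_DEFAULT",
    "APParams",
    "CNParams",
    "PassiveParams",
    "CellState",
    "ap_rhs",
    "cn_rhs",
    "passive_rhs",
    "h_inf",
    "nullclines",
    "find_equilibria",
    "ap_nontrivial_equilibrium_u",
    "get_preset",
    "PRESETS",
    "PRESET_RANGES",
]

#: time scaling coefficient converting the dimensionless AP system to ms
CT_DEFAULT = 1.0 / 12.9


@dataclass(frozen=True)
class APParams:
    """Parameters of the (pacemaking) Aliev-Panfilov cell.

    ``a`` is the recovery-equation threshold and remains an independent
    parameter; ``b`` replaces ``-a`` only in the cubic of the potential
    equation.  ``b > 0`` gives a pacemaker, ``b = -a`` the conventional
    excitable cell.
    """

    k: float = 8.0
    a: float = 0.13
    b: float = 0.03
    eps0: float = 0.002
    mu1: float = 0.2
    mu2: float = 0.3
    ct: float = CT_DEFAULT

    def __post_init__(self) -> None:
        if not (self.k > 0):
            raise ValueError("k must be positive")
        if not (self.mu2 > 0):
            raise ValueError("mu2 must be positive")
        if not (self.eps0 > 0):
            raise ValueError("eps0 must be positive")

    @classmethod
    def conventional(cls, a: float = 0.13, **kw) -> "APParams":
        """Conventional excitable AP cell: the cubic uses ``b = -a``."""
        return cls(a=a, b=-a, **kw)

    def with_(self, **kw) -> "APParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class CNParams:
    """Parameters of the (pacemaking) Corrado cell.

    The gate steady state is a Boltzmann sigmoid
    ``h_inf(u) = (1 - tanh((u - u_gate)/u_s))/2``; ``u_s -> 0`` recovers the
    Heaviside gate of the conventional model.  ``b`` replaces ``-u_gate`` in
    the cubic of the potential equation only; ``u_gate`` keeps its role in
    the gate dynamics.

    ``gate_tau_blend`` selects how the gate time constant interpolates
    between ``tau_close`` (h_inf = 0) and ``tau_open`` (h_inf = 1):

    * "convex" (default): ``tau = tau_open*tau_close /
      [tau_open + h_inf*(tau_close - tau_open)]``, the harmonic blend whose
      endpoints are exactly tau_close and tau_open, consistent with the
      Heaviside-gate limit of the conventional model;
    * "printed": the same expression with a minus sign in the denominator,
      as it appears in print.  Its h_inf = 1 endpoint is not tau_open, and
      with it the pacemaker layer of the intestine model loses its limit
      cycle well inside the documented excitability range — we treat the
      minus sign as a typographical error but keep the form available.
    """

    tau_in: float = 0.3
    tau_out: float = 6.0
    tau_open: float = 120.0
    tau_close: float = 150.0
    u_gate: float = -0.05
    u_s: float = 0.2
    b: float = 0.3
    gate_tau_blend: str = "convex"

    def __post_init__(self) -> None:
        for name in ("tau_in", "tau_out", "tau_open", "tau_close"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if not (self.u_s > 0):
            raise ValueError("u_s must be positive")
        if self.gate_tau_blend not in ("convex", "printed"):
            raise ValueError("gate_tau_blend must be 'convex' or 'printed'")

    @classmethod
    def conventional(cls, u_gate: float = 0.13, **kw) -> "CNParams":
        """Conventional excitable CN cell: cubic threshold ``b = -u_gate``."""
        return cls(u_gate=u_gate, b=-u_gate, **kw)

    def with_(self, **kw) -> "CNParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class PassiveParams:
    """Passive (non-excitable) tissue: linear decay du/dt = -ct*S*u + I_ext."""

    S: float = 26.0
    ct: float = CT_DEFAULT

    def __post_init__(self) -> None:
        if not (self.S > 0):
            raise ValueError("S must be positive")

    def with_(self, **kw) -> "PassiveParams":
        return replace(self, **kw)


@dataclass
class CellState:
    """State of a single cell: potential ``u`` and slow variable ``w``
    (recovery ``v`` for the AP family, gate ``h`` for the CN family)."""

    u: float
    w: float


class DivergenceError(RuntimeError):
    """Raised when a state becomes non-finite (numerical instability)."""


def _check_finite(u: float, w: float) -> None:
    if not (math.isfinite(u) and math.isfinite(w)):
        raise DivergenceError(f"non-finite state (u={u}, w={w})")


def ap_rhs(state: CellState, p: APParams, i_ext: float = 0.0) -> tuple[float, float]:
    """Time derivatives (du/dt, dv/dt) of the (p)AP cell, per ms.

    du/dt = ct*[k*u*(u + b)*(1 - u) - v*u] + i_ext
    dv/dt = ct*eps(u, v)*[-v - k*u*(u - a - 1)],  eps = eps0 + mu1*v/(u + mu2)
    """
    u, v = state.u, state.w
    _check_finite(u, v)
    du = p.ct * (p.k * u * (u + p.b) * (1.0 - u) - v * u) + i_ext
    eps = p.eps0 + p.mu1 * v / (u + p.mu2)
    dv = p.ct * eps * (-v - p.k * u * (u - p.a - 1.0))
    return du, dv


def h_inf(u, p: CNParams):
    """Gate steady state: Boltzmann sigmoid, 0.5 at u = u_gate, decreasing."""
    return 0.5 * (1.0 - np.tanh((u - p.u_gate) / p.u_s))


def _cn_tau(hinf: float, p: CNParams) -> float:
    if p.gate_tau_blend == "convex":
        denom = p.tau_open + hinf * (p.tau_close - p.tau_open)
    else:
        denom = p.tau_open - hinf * (p.tau_close - p.tau_open)
    if np.any(np.asarray(denom) <= 0.0):
        raise ValueError(
            f"gate time-constant denominator <= 0 at h_inf={hinf!r}; "
            "tau_open/tau_close ratio outside the valid range"
        )
    return p.tau_open * p.tau_close / denom


def cn_rhs(state: CellState, p: CNParams, i_ext: float = 0.0) -> tuple[float, float]:
    """Time derivatives (du/dt, dh/dt) of the (p)CN cell, per ms.

    du/dt = h*u*(u + b)*(1 - u)/tau_in - (1 - h)*u/tau_out + i_ext
    dh/dt = (h_inf - h)/tau,  tau = tau_open*tau_close /
            [tau_open - h_inf*(tau_close - tau_open)]
    """
    u, h = state.u, state.w
    _check_finite(u, h)
    du = h * u * (u + p.b) * (1.0 - u) / p.tau_in - (1.0 - h) * u / p.tau_out + i_ext
    hi = float(h_inf(u, p))
    tau = _cn_tau(hi, p)
    dh = (hi - h) / tau
    return du, dh


def passive_rhs(u: float, p: PassiveParams, i_ext: float = 0.0) -> float:
    """Time derivative of passive tissue potential: -ct*S*u + i_ext."""
    return -p.ct * p.S * u + i_ext


# ---------------------------------------------------------------------------
# nullclines
# ---------------------------------------------------------------------------

def nullclines(params, u_grid) -> dict:
    """Evaluate the phase-plane nullclines on ``u_grid``.

    For AP-family parameters returns the cubic ``u``-nullcline
    ``v = k*(u + b)*(1 - u)`` and the ``v``-nullcline
    ``v = -k*u*(u - a - 1)``.  For CN-family parameters returns the
    ``u``-nullcline ``h = tau_in / [tau_out*(u + b)*(1 - u) + tau_in]``
    (NaN where the denominator vanishes) and the ``h``-nullcline
    ``h = h_inf(u)``.  The trivial nullcline ``u = 0`` common to both models
    is reported by the ``"u_zero_line"`` flag rather than as a curve.
    """
    u = np.asarray(u_grid, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("u_grid must be finite")
    if isinstance(params, APParams):
        return {
            "kind": "AP",
            "u": u,
            "u_nullcline": params.k * (u + params.b) * (1.0 - u),
            "w_nullcline": -params.k * u * (u - params.a - 1.0),
            "u_zero_line": True,
        }
    if isinstance(params, CNParams):
        denom = params.tau_out * (u + params.b) * (1.0 - u) + params.tau_in
        with np.errstate(divide="ignore", invalid="ignore"):
            ucurve = np.where(denom != 0.0, params.tau_in / denom, np.nan)
        return {
            "kind": "CN",
            "u": u,
            "u_nullcline": ucurve,
            "w_nullcline": h_inf(u, params),
            "u_zero_line": True,
        }
    raise TypeError(f"unsupported parameter type {type(params)!r}")


# ---------------------------------------------------------------------------
# equilibrium points
# ---------------------------------------------------------------------------

def _rhs_and_jac(params):
    """Return f(u, w) -> (2,) rates and its analytic 2x2 Jacobian."""
    if isinstance(params, APParams):
        p = params

        def f(u, w):
            du = p.ct * (p.k * u * (u + p.b) * (1.0 - u) - w * u)
            eps = p.eps0 + p.mu1 * w / (u + p.mu2)
            dw = p.ct * eps * (-w - p.k * u * (u - p.a - 1.0))
            return du, dw

        def jac(u, w):
            duu = p.ct * (p.k * ((u + p.b) * (1.0 - u) + u * (1.0 - u) - u * (u + p.b)) - w)
            duw = -p.ct * u
            eps = p.eps0 + p.mu1 * w / (u + p.mu2)
            deps_du = -p.mu1 * w / (u + p.mu2) ** 2
            deps_dw = p.mu1 / (u + p.mu2)
            g = -w - p.k * u * (u - p.a - 1.0)
            dg_du = -p.k * (2.0 * u - p.a - 1.0)
            dwu = p.ct * (deps_du * g + eps * dg_du)
            dww = p.ct * (deps_dw * g - eps)
            return duu, duw, dwu, dww

        return f, jac
    if isinstance(params, CNParams):
        p = params

        sgn = 1.0 if p.gate_tau_blend == "convex" else -1.0

        def f(u, h):
            du = h * u * (u + p.b) * (1.0 - u) / p.tau_in - (1.0 - h) * u / p.tau_out
            hi = 0.5 * (1.0 - math.tanh((u - p.u_gate) / p.u_s))
            tau = p.tau_open * p.tau_close / (p.tau_open + sgn * hi * (p.tau_close - p.tau_open))
            return du, (hi - h) / tau

        def jac(u, h):
            duu = h * ((u + p.b) * (1.0 - u) + u * (1.0 - u) - u * (u + p.b)) / p.tau_in \
                - (1.0 - h) / p.tau_out
            duh = u * (u + p.b) * (1.0 - u) / p.tau_in + u / p.tau_out
            th = math.tanh((u - p.u_gate) / p.u_s)
            hi = 0.5 * (1.0 - th)
            dhi = -0.5 * (1.0 - th * th) / p.u_s
            denom = p.tau_open + sgn * hi * (p.tau_close - p.tau_open)
            tau = p.tau_open * p.tau_close / denom
            dtau = -sgn * p.tau_open * p.tau_close * (p.tau_close - p.tau_open) * dhi / denom ** 2
            dhu = dhi / tau - (hi - h) * dtau / tau ** 2
            return duu, duh, dhu, -1.0 / tau

        return f, jac
    raise TypeError(f"unsupported parameter type {type(params)!r}")


def find_equilibria(
    params,
    box: tuple[float, float, float, float] = (-0.5, 1.5, -0.5, 3.0),
    n_starts: int = 50,
    tol: float = 1e-10,
    merge_tol: float = 1e-6,
    max_iter: int = 80,
) -> list[tuple[float, float]]:
    """Find equilibrium points of a single cell inside a phase-plane box.

    Dense multi-start damped Newton iteration from an ``n_starts x n_starts``
    grid over ``box = (u_lo, u_hi, w_lo, w_hi)``.  Points are accepted when
    the RHS max-norm falls below ``tol``; duplicates closer than ``merge_tol``
    are merged.  Returns a list of (u, w) pairs sorted by u.
    """
    u_lo, u_hi, w_lo, w_hi = box
    if not all(map(math.isfinite, box)):
        raise ValueError("search box must be finite")
    f, jac = _rhs_and_jac(params)
    roots: list[tuple[float, float]] = []

    def try_add(u, w):
        if not (math.isfinite(u) and math.isfinite(w)):
            return
        if not (u_lo - 1e-9 <= u <= u_hi + 1e-9 and w_lo - 1e-9 <= w <= w_hi + 1e-9):
            return
        fu, fw = f(u, w)
        if max(abs(fu), abs(fw)) >= tol:
            return
        for (ru, rw) in roots:
            if abs(ru - u) < merge_tol and abs(rw - w) < merge_tol:
                return
        roots.append((u, w))

    for u0 in np.linspace(u_lo, u_hi, n_starts):
        for w0 in np.linspace(w_lo, w_hi, n_starts):
            u, w = float(u0), float(w0)
            ok = True
            for _ in range(max_iter):
                try:
                    fu, fw = f(u, w)
                    juu, juw, jwu, jww = jac(u, w)
                except (ZeroDivisionError, OverflowError, ValueError):
                    ok = False
                    break
                r = max(abs(fu), abs(fw))
                if r < tol:
                    break
                det = juu * jww - juw * jwu
                if det == 0.0 or not math.isfinite(det):
                    ok = False
                    break
                # solve J s = -f for the Newton step
                su = (fw * juw - fu * jww) / det
                sw = (fu * jwu - fw * juu) / det
                # damped step: halve until residual does not grow badly
                lam = 1.0
                for _ in range(8):
                    un, wn = u + lam * su, w + lam * sw
                    try:
                        fun, fwn = f(un, wn)
                    except (ZeroDivisionError, OverflowError, ValueError):
                        lam *= 0.5
                        continue
                    if math.isfinite(fun) and math.isfinite(fwn) and \
                            max(abs(fun), abs(fwn)) <= r * (1.0 - 0.25 * lam) + tol:
                        break
                    lam *= 0.5
                u, w = u + lam * su, w + lam * sw
                if not (math.isfinite(u) and math.isfinite(w)):
                    ok = False
                    break
            if ok:
                try_add(u, w)

    # the resting state is an exact root for the AP family; report it exactly,
    # replacing any tolerance-level near-duplicate found by Newton
    try:
        fu, fw = f(0.0, 0.0)
        if max(abs(fu), abs(fw)) < tol and \
                u_lo <= 0.0 <= u_hi and w_lo <= 0.0 <= w_hi:
            roots = [(ru, rw) for (ru, rw) in roots
                     if not (abs(ru) < merge_tol and abs(rw) < merge_tol)]
            roots.append((0.0, 0.0))
    except (ZeroDivisionError, ValueError):
        pass

    roots.sort(key=lambda r: (r[0], r[1]))
    return roots


def ap_nontrivial_equilibrium_u(p: APParams) -> float:
    """Closed-form u-coordinate of the nontrivial AP-family equilibrium.

    Intersecting ``v = k*(u + b)*(1 - u)`` with ``v = -k*u*(u - a - 1)``
    collapses to the linear equation ``b = u*(a + b)``, so ``u* = b/(a + b)``
    (defined for a + b != 0).
    """
    if p.a + p.b == 0.0:
        raise ZeroDivisionError("a + b = 0: nullclines are parallel")
    return p.b / (p.a + p.b)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

# Named parameter sets for each experiment family.  Where a table row prints a
# range (sweep parameters), the preset stores a representative default and the
# range is kept in PRESET_RANGES for sweep/scan drivers.
PRESETS: dict[str, object] = {
    # isolated-cell / 1D Aliev-Panfilov family
    "pAP-0D": APParams(k=8, a=0.13, b=0.03, eps0=0.002, mu1=0.2, mu2=0.3),
    "pAP-1D": APParams(k=8, a=0.13, b=0.1, eps0=0.002, mu1=0.2, mu2=0.3),
    "AP-1D": APParams(k=8, a=0.13, b=-0.13, eps0=0.002, mu1=0.2, mu2=0.3),
    # 2D sinoatrial-node family
    "pAP-SAN1": APParams(k=8, a=0.13, b=0.120, eps0=0.002, mu1=0.2, mu2=0.5),
    "pAP-SAN2": APParams(k=12, a=0.13, b=0.133, eps0=0.002, mu1=0.2, mu2=0.5),
    "AP-atrium": APParams(k=8, a=0.045, b=-0.13, eps0=0.002, mu1=0.2, mu2=0.3),
    # isolated-cell / 1D Corrado family
    "pCN-0D": CNParams(tau_in=0.3, tau_out=6.0, tau_open=120, tau_close=150,
                       u_s=0.2, u_gate=-0.05, b=0.3),
    "pCN-1D": CNParams(tau_in=0.3, tau_out=6.0, tau_open=120, tau_close=150,
                       u_s=0.15, u_gate=-0.05, b=0.3),
    "CN-1D": CNParams(tau_in=0.3, tau_out=6.0, tau_open=120, tau_close=150,
                      u_s=0.01, u_gate=0.13, b=-0.13),
    # dual-layer intestine family
    "pCN-ICC": CNParams(tau_in=16, tau_out=200, tau_open=1500, tau_close=1800,
                        u_s=0.20, u_gate=-0.05, b=1.70),
    "CN-SMC": CNParams(tau_in=11, tau_out=200, tau_open=1500, tau_close=1800,
                       u_s=0.01, u_gate=0.10, b=-0.10),
    "passive": PassiveParams(S=26.0),
}

#: sweep ranges printed alongside the presets (inclusive bounds)
PRESET_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "pAP-0D": {"b": (0.0, 0.08)},
    "pAP-1D": {"b": (0.0, 0.5)},
    "pCN-0D": {"u_s": (0.05, 0.55), "u_gate": (-0.1, 0.35), "b": (0.05, 0.6)},
    "pCN-1D": {"b": (0.1, 12.0)},
    "pCN-ICC": {"b": (0.62, 1.70)},
}


def get_preset(name: str, **overrides):
    """Look up a named preset, optionally overriding individual fields.

    Raises ``KeyError`` for an unknown preset and ``TypeError`` for an
    override field the preset does not have.
    """
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
    if not overrides:
        return base
    valid = {f.name for f in fields(base)}
    bad = set(overrides) - valid
    if bad:
        raise TypeError(f"preset {name!r} has no field(s) {sorted(bad)}")
    return replace(base, **overrides)
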