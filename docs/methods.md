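# Methods

## Models

Two two-variable excitable cell models are implemented together with their
pacemaking variants, in a uniform formulation where a single control
parameter `b` moves the cell between excitable and self-oscillatory
behaviour.

**Aliev–Panfilov family.** The potential equation's cubic source is
`k·u·(u + b)(1 − u)`; the recovery equation keeps its own threshold `a`
(`a` and `b` are independent fields — the conventional excitable cell is
recovered by the constructor `APParams.conventional`, which sets
`b = −a`, changing only the potential equation). The recovery rate
`ε = ε0 + μ1 v/(u + μ2)` is evaluated at the current state, without lagging
or clamping. Time enters through `c_t = 1/12.9` per ms.

**Corrado family.** The gate's steady state is the Boltzmann sigmoid
`h∞(u) = [1 − tanh((u − u_gate)/u_s)]/2`; as `u_s → 0` it converges to the
Heaviside gate of the conventional model (verified to 1e-3 away from the
threshold). `b` replaces `−u_gate` in the potential cubic only; `u_gate`
keeps its role in the gate.

**Gate time constant.** The gate relaxes with a state-dependent time
constant interpolating between `τ_close` (depolarized, `h∞ = 0`) and
`τ_open` (recovered, `h∞ = 1`). We use the harmonic (convex) blend

    τ(u) = τ_open τ_close / [τ_open + h∞(u)·(τ_close − τ_open)],

whose endpoints are exactly `τ_close` and `τ_open`, consistent with the
Heaviside-gate limit of the conventional model. A variant with the opposite
sign in the denominator circulates in print; it yields `τ = τ_close` at
`h∞ = 0` but not `τ_open` at `h∞ = 1`, and under it the intestinal
pacemaker pair loses its limit cycle well inside the documented
excitability range (the proximal intrinsic frequency of ~17.5 cpm becomes
unreachable). We therefore treat that sign as a typographical artefact;
the variant remains available as `CNParams(gate_tau_blend="printed")`.
For parameter sets where the printed denominator can cross zero
(`τ_close > 2 τ_open`) the evaluation raises a parameter-domain error
naming the offending `h∞`.

**Presets.** Parameter tables are exposed as named presets. Three rows of
the source tables print only a subset of their columns; the presets adopt
the inherit-from-row-above reading (SAN type-2: `k = 12`, `b = 0.133`;
atrium: `k = 8`, `a = 0.045`, `μ2 = 0.3`, `b = −0.13`; smooth-muscle:
`τ_in = 11`, `u_s = 0.01`, `u_gate = 0.10`, `b = −0.10`). All presets are
field-by-field overridable. For the smooth-muscle row the alternative
placements of the lone `τ` value were simulated and destroy the ICC–SMC
pair oscillation throughout the documented range, which corroborates the
leftmost-column reading.

## Oscillation windows and bistability

Linear stability of the nontrivial equilibrium (u* = b/(a + b) for the AP
family, in closed form) shows the pacemaking windows are *intervals* in
`b`: the pAP cell with the isolated-cell parameter set oscillates for
`0 < b ≲ 0.067` (upper Hopf; the maximum frequency just below it, ~7.2 Hz,
is the model's frequency ceiling); printed sweep ranges extending to 0.08
or 0.5 cover quiescent territory, which the sweep drivers report as
quiescent points rather than errors.

The ICC–SMC pair of the intestine model is more subtle: the *isolated*
pacemaking cell with intestinal time constants has a stable equilibrium
throughout `b ∈ [0.62, 1.70]`; the oscillation is a property of the
*coupled pair*, and near the proximal end (`b ≳ 1.4`) the pair is
bistable — a stable limit cycle coexists with the stable equilibrium, and
the standard initial condition `(u, h) = (0.01, 0.5)` lies in the
equilibrium's basin. Protocols that measure intrinsic pair frequencies
therefore run a **priming stage**: 600 s at `b = 1.0` (where the cycle is
reached from the standard initial conditions) before switching to the
target `b`. With it the pair frequency at the duodenal end is 17.53 cpm
and at `y = 1200 mm` 10.35 cpm, matching the documented 17.5–10.5 cpm
span. Priming is off by default for full coupled-tissue runs (waves from
the self-starting region recruit dormant neighbours) and on for
decoupled-profile measurements, which would otherwise compare against
basin-dependent outcomes.

## Numerics

* **Forward Euler** is fully explicit; tissue runs check the diffusion
  stability bound `D·Δt/Δx² < 1/(2N)` (strict) before starting and refuse
  to run unless forced.
* **Backward Euler** uses operator splitting: the 2×2 reaction system is
  solved implicitly per node by damped Newton with the analytic Jacobian
  (absolute tolerance 1e-7 in max-norm, at least one update per step, at
  most 20; exceeding the cap raises rather than clamps), then the
  diffusion term is solved implicitly — a dense pre-inverted
  `(I − Δt L)⁻¹` for systems up to 2048 nodes (the whole step then runs
  compiled), a pre-factorized sparse LU above that.
* Simulated time is `step_count × Δt` with a 64-bit counter, never
  accumulated addition (60-s runs at Δt = 1e-4 ms are exercised routinely).
* Upward level crossings (activation times, cycle counts) are detected
  inside the stepping kernels with linear interpolation of the crossing
  instant, so rate measurements do not depend on the trace-recording
  stride.

**Accuracy norms.** The FE-vs-BE verification compares the last complete
cycle of each trace, aligned at its own cycle-start crossing (mid-amplitude
upward crossing, two-pass level estimate). Alignment is essential: over a
60-s run the schemes accumulate a phase drift that would otherwise dominate
the single-cycle norm. The relative frequency error uses the mean cycle
length over the whole window. A 10-s window is used in the test suite; the
single-cycle norms are window-independent.

**Cycle features.** POP/MDP are per-cycle extrema averaged over cycles;
APD90 is the time per cycle above `POP − 0.9(POP − MDP)` with interpolated
threshold crossings; DI = CL − APD90; traces with fewer than three complete
cycles after the settling window (default 30 s, configurable) are reported
as quiescent — an outcome, not an error. Amplitudes below 1e-3 count as
quiescent, so numerical ripple is never mistaken for pacemaking.

**Synchronization.** The 1:1 verdict compares the pacemaker's cycle count
with the number of probe-cell crossings *inside the pacemaker's
first-to-last crossing window* (a locked pair then gives exactly equal
counts regardless of phase lag); 1:1 is declared when
`|ratio − 1| < 1/cycles`. The probe sits at cell 16 of a 20-cell strand
(80 % of shorter strands) to avoid the sealed end. Region boundaries in
`b` are refined by bisection from a coarse grid, so disjoint 1:1 regions
are representable. Scans over the light-load case `n = 0.5` at weak
coupling sit in a hysteresis regime; boundary values there depend on
initial conditions by design of the system, not of the scanner.

## Topologies

* **Star strands:** integer `n` builds explicit strands (kept bitwise
  identical by symmetry, which is asserted in tests); fractional `n` uses
  one strand with the pacemaker-bound current scaled by `n` — exactly
  equivalent for synchronized identical strands and continuous in `n`.
* **2D grids:** 5-point stencil; heterogeneous interfaces take the
  arithmetic mean of the two nodes' `D` per face; anisotropy is grid-
  aligned (`Dy:Dx = 1:0.208` for the type-1 SAN) while the SAN ellipse
  (half-axes 3 and 1 mm) is rotated 30° off the fiber axis. The type-2
  passive border is a 0.25-mm elliptical ring pierced by four 1-mm exit
  pathways centered on the ellipse axes; pathways carry SAN tissue
  parameters and the SAN diffusion coefficient. All geometry parameters
  are arguments, not constants.
* **Dual-layer cylinder:** the tube is cut and unrolled; periodicity is
  applied along the 44-mm circumference (176 nodes) with no-flux tube
  ends. (A literal reading of the source text would make the long axis
  periodic; the cut-tube geometry dictates circumferential periodicity,
  and `CylinderSpec(periodic_axis="y")` restores the literal variant.)
  Layers couple pointwise and antisymmetrically with `d_IM = 6e-3` per ms.

## Scaled experiment variants

The full intestine protocol (176×4800 nodes per layer, 11 600 s) is not a
desk-scale computation; the package ships a scaled variant
(`IntestineExperiment.scaled`) that divides lengths *and* the gradient
decay length by a common factor, preserving the intrinsic-frequency range
(1.70 → 0.62 in `b`, ~17.5 → ~10.5 cpm) while shrinking domain and
transient times. Scaled runs reproduce the qualitative surface: a
non-increasing staircase of constant-frequency plateaus, smooth-muscle
waves following the pacemaker layer cycle for cycle, and a transient
conduction block (state reset `u = 0.001`, `h = 0.5` for one step in a
rectangle of both layers) that perturbs and re-establishes downstream
activity. The conduction-block instant defaults to the later of the two
times quoted in the source (8100 s, with 5100 s reachable via
configuration). SAN acceptance runs use the full 10×10 mm domain and
full-size ellipse coarsened to Δx = 0.1 mm with Δt = 0.01 ms; between
Δx = 0.1 and 0.05 mm the measured pacing rate moves by ~2 %, so the
coarse rate stands in for the fine one well inside the tolerance used.
The measured type-1 rate at strong coupling is ~100–102 cpm against the
source's "about 120 cpm" — reproduced as computed, not tuned.

## What the synthetic protocols do not show

All inputs are generated by the models themselves; there is no measured
electrophysiology anywhere. Passing tests demonstrate internal consistency
(conservation, convergence, entrainment structure) and agreement with the
published numbers of the same models — not fidelity to real SAN or
intestinal tissue, which would require heterogeneous cell populations,
realistic geometry and fitted parameters, all documented non-goals here
(as are electromechanical/thermodynamic coupling and formal continuation
analysis; equilibria come from dense multi-start damped Newton searches,
cycle extremes from simulation).

## Known limitations

* Forward-Euler tissue kernels are serial (numba, single thread); the full
  200×200 SAN at Δt = 0.002 ms runs in tens of minutes, not seconds.
* The backward-Euler splitting is first-order (Lie) and freezes the
  coupling current during the reaction solve; it is a verification tool
  here, not the production path for large tissues.
* The sync-limit scanner brackets region boundaries monotonically from a
  coarse grid; regions narrower than the grid spacing are missed.
* Near fold/Hopf boundaries (pAP `b ≈ 0.067`, ICC pair `b ≈ 1.5` without
  priming) outcomes are sensitive to initial conditions; protocols pin
  them down explicitly rather than hiding the sensitivity.
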