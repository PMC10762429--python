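# Methods

`finwake` reconstructs the mechanical story of a swimming fish from
time-resolved 2D PIV: velocity fields → pressure fields → surface forces →
tail thrust and hydrodynamic efficiency, alongside wake-vortex analysis and
fin-gait classification. This note records the models, the numerical
choices, and what the synthetic validation does and does not demonstrate.

## Coordinate and sign conventions

All quantities are SI. The grid is node-centred, uniform Cartesian, with
physical coordinates in metres and the index origin at (min x, min y) — the
layout of typical PIV vendor exports. The swimming axis `swim_axis` is a
unit vector pointing **rostrally** (the direction the fish faces); in a
flume the free stream therefore has a negative projection on it. "Axial"
always means the projection on `swim_axis`, and positive axial force is
thrust. Lateral is the 90°-counter-clockwise rotation of the axis. Jet
angles are measured from the caudal (downstream-drift) direction and are
**negative when the jet points medially**, toward the body midline — the
convention in which a pectoral-fin jet aimed at the tail is negative.

Gauge pressure is relative to ambient: zero at the domain boundary.

## Velocity fields and derived quantities

`VelocityFrameSeries` holds (u, v) on an (nt, ny, nx) grid with a per-frame
boolean body mask. Spatial derivatives use central differences in the
interior and first-order one-sided stencils on boundary rows/columns;
boundary nodes are excluded from all validation metrics. Any
derivative-based field is invalidated within one node of the mask
(8-connected dilation), because stencils straddling the fish–fluid
interface are meaningless.

Free-stream subtraction removes the time-average mean velocity vector over
a user-chosen upstream window (the window geometry is a parameter; there is
no single canonical choice). The operation is idempotent to machine
precision. Note the fundamental limitation for wake work: an isolated 2D
vortex has a Γ/(2πr) far field, so the window mean always contains a small
bias of order Γ/(2πd) for a structure at distance d — negligible for
zero-net-circulation (paired) wakes, but a percent-level effect for single
strong cores near the window.

Material acceleration is Du/Dt = ∂u/∂t + (u·∇)u with a central time
difference; the first and last frames fall back to one-sided differences
when explicitly allowed, and results there carry lower confidence.

## Pressure from velocity

The pressure gradient comes from the 2D Navier–Stokes momentum balance,
∇p = −ρ Du/Dt + μ∇²u, with the viscous term from a 5-point Laplacian
(negligible for the validation flows, kept for fidelity). Defaults
ρ = 998 kg m⁻³ and μ = 1.0 × 10⁻³ Pa·s are fresh water at ~21 °C.

Pressure is recovered by **multi-directional ray integration with median
polling** rather than a Poisson solve: for every fluid node, ∇p·dl is
integrated (trapezoid rule) along straight rays from boundary seed points —
where gauge pressure is zero — in up to eight compass directions of the
grid; rays crossing the dilated body mask are discarded and the node takes
the **median** of the surviving integrals. The median makes the estimate
robust to a corrupted ray: perturbing any single ray changes the result by
less than the inter-ray spread. Nodes shadowed in all eight directions
(concave mask pockets) are filled by relaxation consistent with the local
gradient, iterating neighbour predictions p_i = p_j + ½(g_i + g_j)·(x_i −
x_j) to convergence. The solver refuses geometries where more than 20% of
fluid nodes are fully shadowed. Each of the eight directions is implemented
as a vectorised cumulative sweep, so a 128 × 128 frame solves in tens of
milliseconds.

Validation: against steady potential flow past a cylinder (16-cell
diameter, 128² grid) the solved pressure coefficient at surface-adjacent
nodes agrees with the closed form Cp(r, θ) = 2(R/r)²cos 2θ − (R/r)⁴ — the
surface limit of 1 − 4 sin²θ — to |ΔCp| < 0.02. Against a Lamb–Oseen
vortex the radial profile matches the quadrature oracle
p(r) = −ρ∫ᵣ^∞ v_θ²/s ds within ~3% of the core deficit for r ≤ 3 r_c on a
domain spanning ±5 r_c, and the error falls monotonically with grid
refinement. Because the solver anchors its gauge at the finite boundary
while the oracle decays to zero at infinity, a fixed offset of a few
percent of the core deficit is inherent at finite domain size; the
convergence study therefore compares profiles re-referenced to the
2.5–3 r_c annulus.

## Body surface, forces, efficiency

Outlines are extracted by marching squares at the 0.5 level of a
Gaussian-smoothed (σ = 1 cell) mask, then fitted with a periodic smoothing
spline allowing ~0.2 cell RMS deviation — the raw binary contour is a
staircase whose normals and perimeter are badly biased. The result is
resampled to uniform arc spacing ≤ Δx and oriented counter-clockwise, so
outward normals are the tangents rotated by −90°. Anatomical landmarks
(snout, caudal peduncle, superior caudal-lobe tip) cannot be inferred
robustly from a silhouette and are supplied per sequence (the synthetic
generator emits them).

Surface pressure is sampled per segment at midpoint + offset·n̂ by bilinear
interpolation, flagged invalid when any support node is invalid. The
default offset of 1.5 grid spacings just clears the 1-node invalid band
around the mask; for very thin structures (the scripted tail plate is
~3.5 cells thick) 2.5 spacings keeps the bilinear support clear, and the
pipeline uses that value for the virtual swimmer.

The **tail region** is defined from the landmark pair (peduncle, tip): the
arc interval centred on the tip with half-width equal to the peduncle→tip
arc distance, i.e. the peduncle-side flank plus its mirror image across the
tip, so both faces of the tail contribute. Segment forces are
f_i = −p̄_i L_i n̂_i (N/m, per unit depth — the fields are 2D). On a closed
outline the net force is gauge-invariant by construction.

Surface velocities pair outline segments across frames by **normalized arc
length anchored at the snout** (closest-point matching is unstable under
lateral tail excursions) and difference corresponding midpoints; the
pipeline uses centred differences over adjacent frames.

Power decomposition, per unit depth, over the tail region:
P_ax(t) = max(F_ax(t), 0) · U (thrust times swimming speed, the useful rate
for a station-holding swimmer) and P_lat(t) = Σ|f_lat,i · v_lat,i| (the
pressure work rate of lateral surface motion, taken as an unsigned cost).
Hydrodynamic efficiency is η = ⟨P_ax⟩/(⟨P_ax⟩ + ⟨P_lat⟩) over an integer
number of tail-beat cycles; clipping negative instantaneous thrust keeps
η ∈ [0, 1], with drag phases expressed through a reduced ⟨P_ax⟩. Whether
lateral work should be signed or unsigned, and whether axial power should
use swimming speed or surface axial velocity, are genuine modelling
choices; the ones above are fixed, documented, and tested against their
own closed forms.

## Wake analysis

Vortex cores are connected components of |ω| ≥ f·max|ω| (default f = 0.2)
outside the dilated body mask — wall shear produces a vorticity sheet along
the body at any speed that must not be read as shed vortices. Components
smaller than 4 cells are dropped; each core carries an |ω|-weighted
centroid, Γ = Σω ΔxΔy, and area. Note that thresholding truncates the
Gaussian vorticity tail: for a Lamb–Oseen core thresholded at fraction f
the recovered circulation is Γ(1 − f), which the tests account for.

Counter-rotating cores within a separation bound are paired greedily,
nearest first, into vortex-ring cross-sections. The **central jet region**
is operationalized as the disk of radius separation/2 about the ring
midpoint, gated to nodes with ≥50% of the regional maximum speed; the jet
angle is the circular mean (wrap-safe) of the velocity angles there,
measured from the caudal axis with the medial-negative sign convention.
Cores are tracked frame-to-frame by nearest-neighbour linking under a
same-sign constraint and a maximum step; given per-frame tail positions, a
shed-to-interception interval is reported the first time a tracked core
approaches the tail within a stated radius (a proxy for what is, in
experiments, a visual call).

## Gait kinematics

Fin-tip traces (lateral displacement vs time) are conditioned by a
1.5-beat-period moving-average detrend (drift robustness) and a 1/8-period
moving-average low-pass, with the dominant frequency estimated from the
amplitude spectrum. Peaks need a prominence of 25% of the half-range; peak
times are refined to sub-sample precision by parabolic interpolation.
Amplitude is the mean peak-to-peak excursion over the last three full
cycles, corrected for the known filter gain at the beat frequency and
normalized to body length; frequency is the reciprocal mean inter-peak
interval over the same window. Phase differences are circular means of
per-cycle peak-time offsets (both maxima and minima), in degrees of the
shared period — spectral phase is avoided because real traces are short
and nonstationary.

Gait labels per tail-beat cycle: **PCF** requires anti-phase pectorals
(within ±45° of 180°, enclosing about two standard deviations of the
observed spread), pectoral/caudal frequency match within 15%, an active
caudal fin (peak-to-peak ≥ 0.02 BL), and the pattern sustained over **at
least three consecutive tail beats** — shorter candidate runs are labelled
"other", never PCF. MPF is active pectorals with a quiet caudal fin; BCF
the reverse. The PCF time budget is the summed PCF bout duration over the
observation window, with flagged repositioning/wall intervals excluded
from the numerator only. All thresholds are configurable; the defaults are
this package's operational choices, not values published with the original
observations.

## Statistics

Two-sample t-tests are pooled-variance by default (Welch via a flag),
with statistics computed from the standard formulas and p-values from the
t/F distributions; one-way ANOVA uses the between/within decomposition
(identical constant groups return F = 0, p = 1; distinct constants with
zero within-variance return F = ∞, p = 0); Tukey HSD delegates to the
studentized-range implementation in scipy. α = 0.05 throughout. The
two-group identity F = t² and a simulated type-I error rate within
[0.03, 0.07] are enforced in the acceptance suite.

## Synthetic data: what it emulates, and what it does not

The generators emulate the study geometry — 128 × 128 vectors per frame,
1000 frames/s for flow clips, a ~9 cm fish at 0.3–2.0 BL/s — and every
scenario carries analytic truth:

* **Lamb–Oseen vortices** (closed-form swirl, vorticity, partial
  circulation, quadrature pressure), optionally advected and superposed on
  a free stream;
* **potential flow past a cylinder** with the full Cp field and the
  d'Alembert zero-drag identity;
* **counter-rotating dipoles** with a prescribed central-jet direction,
  seeded centre jitter and 2% velocity noise;
* **fin-trace triples** with prescribed frequencies, amplitudes, phases and
  additive tracker noise;
* the **virtual swimmer**: a rigid elliptical body with a thin tail plate
  pitching about the peduncle, θ(t) = θ₀ sin ωt, and face pressures
  prescribed as ±P₀ cos(ωt − ψ) sin²(πξ) extruded constantly along the
  plate normal over a band wider than the sampling offset. Net thrust,
  positive-thrust mean and lateral power are computed by fine quadrature
  over the analytic plate faces, and the swimming speed U is then solved so
  the quadrature efficiency equals a prescribed η* — giving an exact
  end-to-end truth that is independent of the gridded pipeline under test.
  Swimmer clips cover one full beat cycle at 64 frames/cycle (a 3 Hz beat
  at 1000 fps would need 333 frames to close a cycle; efficiency is a
  cycle-average, so the clip length follows the beat, not the camera).

The swimmer deliberately **prescribes** surface pressure rather than
solving the flow around a deforming body: that yields exact force and power
truths at desk scale, while the pressure solver is validated separately on
analytic flows. Consequently, a passing suite shows that each stage meets
its oracle and that the stages compose deterministically — it does not
show that a real fish's pressure field is recovered to the same accuracy,
which depends on PIV resolution, masking quality and out-of-plane flow
that no 2D method captures.

## Known limitations

Skin-friction (shear) forces, added-mass bookkeeping and 3D effects are out
of scope; forces are pressure-only and per unit depth. The pressure solver
assumes the boundary is far enough from the body for the zero-gauge
reference to hold. Landmark placement is user input. The jet-region rule
and the interception radius are stated proxies for visual judgements.
Generator defaults (noise levels, parameter ranges) are fixed choices meant
to be realistic for high-speed PIV fin tracking; they are not fitted to any
dataset.
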