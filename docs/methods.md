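# Methods

This note records the models, the provenance of every default parameter,
the numerical choices, and the limitations of `patellasim`.  Constants
with a literature source live in `src/patellasim/defaults/literature_defaults.yaml`;
every stand-in value this package calibrated itself lives in
`src/patellasim/defaults/calibrated_defaults.yaml`.  The two files are
never mixed.

## Shared geometry

The embryonic knee is idealized as a tendon strip of uniform thickness
t = 1.75 mm wrapped around a rigid circular femoral condyle of radius
r = 4 mm (both literature values).  The centerline consists of a straight
quadriceps segment (6 mm), a circular arc subtending exactly the flexion
angle θ, and a straight patellar segment (6 mm).  The segment lengths are
free parameters — no source states them — chosen so the muscle and tibial
molecule sources are well separated from the contact arc.  Mapping the
flexion angle one-to-one onto the wrap angle realizes the key mechanism
all three theories rely on: the tendon/condyle coincident area grows with
flexion.  Coordinates are millimetres with the origin at the condyle
centre; flexion is measured between the two straight segments.

The structured mesh has `n_through_thickness` × `n_along_length`
(default 8 × 120) bilinear quadrilaterals; the along-count is split over
the three segments in proportion to centerline length.  Because every
flexion angle uses the same subdivision counts, element correspondence
across angles is the identity permutation on structured indices, which is
how fields from different angles are projected onto the 90° reference
mesh.  For the biochemical model an annular femoral-cartilage sector
(depth 2 mm, 4 radial layers) sits inside the contact arc and shares the
interface nodes with the tendon; the interface line is simultaneously the
TGF-β/BMP femoral source and the GDF-5 (joint-marker) source.

## Theory I — biochemical model

State: nodal concentrations of TGF-β, BMP, FGF and GDF-5; nodal Scx-cell
density b; one tissue label per element (mesenchyme, Scx domain, tendon,
patellar/tibial cartilage, interzone, femoral cartilage).

Equations.  Each molecule obeys ∂s/∂t = D∇²s with no-flux exterior
boundaries and fixed-value (Dirichlet) source node sets: TGF-β at the
muscle end, the femoral interface and the tibial end; BMP at the femoral
interface and tibial end; GDF-5 at the femoral interface; FGF at the
muscle end, switching on permanently once the mean Scx density in the two
element columns nearest the muscle exceeds `b_sense`.  The cells obey
∂b/∂t = ∇·(μ∇b − χ b ∇s_TGF) + r b (1 − b/b_max).  Diffusion of TGF-β,
BMP and FGF is slowed ×0.1 inside cartilaginous tissue; the joint marker
GDF-5 is not slowed (the molecule/tissue role table assigns it no low-
diffusion entry).  Cell transport coefficients are zero inside the
femoral cartilage (progenitors do not invade the anlage).

Differentiation is a cellular-automaton rule on element-averaged nodal
values, evaluated every step, with irreversible transitions and the
ordering: cartilage + GDF-5 → interzone first, then Scx + BMP → cartilage,
then Scx + FGF → tendon (an element meeting both molecular gates in the
same step becomes cartilage, which is what lets the eminence form where
BMP reaches the cell stream).  New cartilage is labelled tibial when the
element lies nearer the tibial end than the femoral arc along the
centerline; the label affects reporting only.

The predicted patella is the largest connected component of patellar
cartilage with no edge-adjacency to femoral cartilage; it counts as
detached when it additionally borders interzone.

### Parameter provenance and calibration

No molecular parameter of this system has a measured value; the original
coefficients were themselves set by trial and error.  The shipped
defaults were calibrated the same way, once, against the qualitative
developmental sequence — tendon forms from the muscle end and advances;
cartilage appears on the condyle later; a GDF-5 interzone separates it
from the femur; a patella forms at 90° flexion but not at 30–45° — and
then frozen.  Concentrations are in ng/ml with all sources at 10 ng/ml
(only ratios to thresholds matter); time is a dimensionless simulation
unit τ (the biology fixes no scale).

| parameter | default | role |
|---|---|---|
| D_TGFβ | 0.5 mm²/τ | attractant spreads fastest, fills the joint |
| D_FGF | 0.25 mm²/τ | sets the speed of the tendon-conversion front |
| D_BMP | 2×10⁻³ mm²/τ | slow; penetration gated by arc (source) width |
| D_GDF5 | 6×10⁻⁴ mm²/τ | slowest; confines the interzone to the interface |
| μ, χ | 0.06, 0.02 | cell motility and chemotactic sensitivity |
| r, b_max | 0.05/τ, 1.0 | logistic proliferation (Fisher front ≈0.11 mm/τ) |
| b_c, s_BMP, s_FGF, s_GDF5 | 0.25, 5.0, 2.0, 6.5 | differentiation thresholds |
| dt, steps | 0.05 τ, 9400 | horizon 470 τ |

The flexion-angle selectivity emerges from a race: the FGF front sweeping
from the muscle converts the Scx-rich tendon irreversibly, while BMP
leaking through the contact interface must push the *second* element
layer over its threshold first.  The attainable BMP level there scales
with the width of the source line — the wrap arc — reaching ≈5.5 (of 10)
at 90° but only ≈4.7 at 45° and less at 30°; the threshold 5.0 separates
the regimes.  At the default settings the 90° run yields a 16-element
detached patella (events: tendon 0.1 τ → first cartilage 1.4 τ →
interzone 36.5 τ → detachment 64.5 τ), 60° a 2-element incipient island,
and 45°/30° none.

The initial Scx domain is the proximal 28 % of the centerline (adjacent
to the muscle, ending one element before the arc): the muscle then senses
its progenitors immediately and the tendon forms from the muscle end
first, while cells must migrate onto the condyle before any cartilage can
appear — reproducing the observed event order.  Logistic proliferation is
enabled by default because the pure-diffusion Dirichlet sources saturate
the domain with TGF-β, after which chemotaxis alone cannot carry the
population to the distal arc; a proliferating population colonizes the
anlage as a Fisher-type travelling front.  Both choices are plain
configuration fields (`scx_end_frac`, `growth_rate`); conservation tests
run with growth off.

What these defaults emulate — and do not.  They are a minimal caricature
of the real signalling environment: single effective diffusivities, clean
threshold responses, no molecular decay or binding, no mechanical
feedback, a rigid femur, 2D geometry.  Passing runs demonstrate that the
proposed interaction logic *can* produce an embedded, detaching patella
with the observed angle dependence; they say nothing about quantitative
embryonic timing or concentrations.

## Shared elasticity core

Plane-stress bilinear quadrilaterals, 2×2 Gauss integration, small
strains.  Tissue properties (MPa): cartilage E=6.1, ν=0.497; tendon
matrix E=6.1, ν=0.4; tendon fiber E=800, ν=0.4.  Collagen fibers are
overlaid 2-node axial links along the element edges parallel to the local
centerline, each edge carrying half the element's through-thickness
extent as tributary cross-section, so the fiber area through any tendon
cross-section sums to the tendon thickness; a rank-one continuum variant
(E_f a⊗a added to D) sits behind `FiberSpec(model="continuum")`.  Loading
is a 1 mm prescribed displacement of the muscle end along the quadriceps
axis with the tibial end fixed; condyle contact is bilateral frictionless
sliding, imposed by rotating the contact-line degrees of freedom into a
tangent/normal frame (tangents from a least-squares circle fit through
the contact nodes, keeping the formulation frame-objective) and fixing
the normal component.  Plane strain and the 3-trace hydrostatic measure
are one configuration switch away.

Stress reporting distinguishes the matrix phase from the total.  With the
fibers carrying ≈40 MPa of axial tension, the total in-plane mean stress
is tensile everywhere; the compressive environment that matters for
mechanoregulation is the pressure in the inter-fiber matrix, which peaks
at −3.9 MPa on the contact line at 90°.  `stress_strain_measures`
defaults to the matrix phase; both fields are computed and exported.

## Theory II — Carter mechanoregulation

The rule: tendon differentiates to cartilage where σ_hyd ≤ σ_hyd^cart
and ε₁ ≤ ε_max, applied once (no iterative remodelling).  Per-angle
element fields are mapped onto the 90° mesh by the structured
correspondence and combined with the scenario weights (5/10/15/25/45 %,
60/25/9/5/1 %, 1/5/9/25/60 % over 30/45/60/90/110°).  The stress
threshold has no published value; the default is scale-free: 30 % of the
peak compressive matrix σ_hyd of the 90° solve (−1.18 MPa at default
settings), recorded in every output.  The strain cap default is 0.08:
under the 1 mm pull the fiber-dominated axial stretch is ≈0.05 nearly
everywhere, so a cap at 0.05 would sit on the measured strain itself;
0.08 keeps the gate active (it excludes the straight-segment stretch
peaks of 0.09–0.18) without suppressing the compressed arc.  Both are
configurable, absolute values included.

## Theory III — topology optimization

Standard SIMP: E_e = ρ_e³ E⁰ (fiber links scaled by the same ρ_e³ unless
disabled), compliance C = uᵀF, sensitivities ∂C/∂ρ_e = −p ρ_e^{p−1}
u_eᵀK⁰_e u_e ≤ 0, sensitivity filter of radius 1.5 mean element lengths
(off reproduces the unfiltered update), optimality-criteria update with
move limit 0.2 and damping 0.5, Lagrange multiplier by bisection on
[10⁻⁹, 10⁹] to relative width 10⁻⁵ with the volume constraint V/V₀ = f
verified to 10⁻³ at every accepted iterate.  Volume fraction f = 0.4 by
default (never stated anywhere; the qualitative conclusions hold for
f ∈ [0.3, 0.5]).  ρ_min = 10⁻³.

Because compliance minimization is ill-posed under displacement control
(removing material lowers uᵀF), the prescribed contraction is converted
to an equivalent force load: the full-density tendon is solved under the
1 mm pull and the muscle-end reactions are reapplied as nodal forces with
that end free.  This preserves nonpositive sensitivities and the usual
OC convergence behaviour.

Identifying the "patella".  Any load-carrying optimum threads ρ ≈ 1
material through every tendon cross-section, so the bare presence of a
dense element over the condyle cannot distinguish flexion angles.  The
package defines a patella-like zone as a *coherent thickening*: a solid
ρ > 0.8 block at least 3 element layers thick spanning at least half of
the anterodistal sector (the middle half of the wrap arc).  At default
settings the 90° and 110° optima form such a band (3×23 and 3×19 element
blocks); the 30° optimum instead builds thin inner/outer chords with
narrow shear webs (largest sector block 6×3) and fails the criterion, as
does 45° (2×14).

## Numerics

- Transport uses a lumped mass matrix with implicit-Euler diffusion
  (unconditionally stable) and an explicit chemotactic flux.  The
  Galerkin chemotaxis operator is stabilized by discrete upwinding:
  symmetric artificial diffusion d_ij = max(0, −c_ij, −c_ji) makes all
  off-diagonal entries nonnegative, preserving positivity at sharp cell
  fronts while keeping zero column sums, so total cell mass is an exact
  discrete invariant (drift < 10⁻⁸ relative over 1000 steps comes only
  from rounding).  A positivity/CFL bound dt ≤ min_i m_i/|l_ii| is
  checked every chemotaxis step and raises a stability error.
- Bilinear quads on the curved wrap are not exactly monotone next to
  Dirichlet jumps; nodal undershoots smaller than 10⁻⁴ of the field
  maximum are clamped to zero, larger ones raise a positivity error.
- Implicit systems are LU-factorized once per (species, tissue-state)
  combination and reused until differentiation changes the cartilage set.
- With χ = 0 the chemotaxis step is the diffusion step verbatim
  (difference < 10⁻¹²), which the reduction tests pin down.
- The elasticity solves are direct sparse factorizations; the relative
  residual on free DOFs is reported (< 10⁻⁹ required).
- All algorithms are deterministic: no random number generator is used
  anywhere, so identical configurations reproduce outputs bit-identically.

## Problem sizes

Default production resolution is 8 × 120 tendon elements (plus 4 × n_arc
femoral elements for Theory I); a full biochemical run is ≈1 minute on
one CPU, a five-angle Carter sweep ≈6 s, a knee SIMP optimization ≈10 s.
Validation fixtures use 100×1 (diffusion bar), 3×3 (patch), 1×1 (fiber
link), 32×20 (cantilever) and 4×20 (mini knee) meshes.  Several unit
tests run the same operators at 4 × 40 resolution for speed; the
acceptance checks always use the default resolution.

## Known limitations

- 2D plane models; no out-of-plane diffusion or stress.
- Linear kinematics despite the 1 mm / 19.7 mm load ratio, matching the
  linear-elastic formulation; strains of ~5 % stretch that assumption.
- Bilateral (no-separation) frictionless contact; the tendon cannot lift
  off the condyle.
- No coupling between theories: biochemistry sees no mechanics and vice
  versa.
- The biochemical time unit and all molecular magnitudes are calibrated,
  not measured; only the qualitative sequence and angle dependence are
  meaningful.
- Single-shot Carter differentiation (no remodelling loop); the phase
  rule is applied only in its cartilage corner.
- The patella-zone criterion for topology optimization is a shape
  heuristic; other defensible operationalizations exist, and very
  different f or filter settings change where its margins lie.
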