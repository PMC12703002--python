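# Methods

`atriatwin` implements the functional core of an ECG-calibrated volumetric
model of human atrial electrophysiology, exercised end-to-end on a synthetic
idealized biatrial and torso geometry.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
setting does and does not demonstrate.

## Synthetic anatomy

The generator replaces an image-derived anatomical twinning stage.  Each
atrium is a thick-walled ellipsoid built from a subdivided icosahedron
(subdivision depth chosen from the target edge length, default 0.9 mm, the
resolution appropriate for eikonal-type activation models).  The wall is
constructed as two layers — endocardial and epicardial — by inward offsets
along the ellipsoid normal; prisms between consecutive surfaces are split
into three tetrahedra with a minimum-index diagonal rule so adjacent prisms
conform.  Orifices (MV, LSPV, LIPV, RSPV, RIPV on the left; TV, SVC, IVC,
CS on the right) are caps removed by a cone-angle test around configured
axes; the exposed mid-wall rim of each hole is the orifice ring.
Appendages (LAA, RAA) are labeled surface patches rather than protruding
pouches: that is sufficient for every distance-based rule in the pipeline
and keeps the generator robust.  Both atria reuse the same sphere
tessellation (the left atrium mirrored), which provides an exact node
correspondence for the fossa-ovalis bridge — a small block of prisms
joining the facing septal epicardial patches, the only meshed inter-atrial
tissue.

Default dimensions: LA semi-axes (23, 25, 22) mm, RA (24, 26, 25) mm,
wall thickness LA 2.0 mm, RA 2.5 mm (split evenly between the layers),
septal gap 3 mm.  The thicknesses are surrogate a-priori values chosen
from the literature range for human atrial walls; imaging cannot resolve
them, so any twinning pipeline prescribes them, and they are configuration
parameters here.

The torso is a co-registered ellipsoid (default semi-axes 170 × 110 × 240
mm, homogeneous conductivity 0.2 S/m) with the nine standard electrodes
(RA, LA, LL, V1–V6) snapped to surface nodes at fixed parametric
positions.  An optional concentric-shell tetrahedral volume mesh supports
finite-element lead fields; its radial shells are cosine-graded — fine near
the surface (current injection sites) and near the center (where the field
is evaluated at the atria).

Mesh quality uses `q_e = 1 − V_e/V`, with `V` the volume of the equilateral
tetrahedron whose edge equals the element's average edge length.  The
worst element of the default mesh is ≈ 0.94, below the 0.99 threshold
regarded as critical for reaction–diffusion solvers.

## Anatomical labeling

Orifice rings are detected as surface nodes incident to both endo- and
epi-labeled elements (at an open rim the mid-wall nodes are exposed) and
chained into ordered closed loops.  Pulmonary veins are disambiguated by
the nearest-centroid cascade: the ring nearest the LAA is the LSPV, the
ring nearest the LSPV is the LIPV, the remaining ring nearest the LAA is
the RSPV, and the last is the RIPV.  Ties within relative tolerance 1e−6
raise an error rather than choosing silently.

Fifteen Laplace–Dirichlet (LD) fields are solved per the standard battery
(nine on the RA, six on the LA) with P1 elements; each is a harmonic
"distance ordering" between orifice rims, appendage patches, the endo/epi
surfaces, and the RA roof — the band where the plane through the IVC and
SVC centers and the RA center of mass meets the wall (half-width: half the
median edge length).  The same plane splits the tricuspid annulus into
septal and lateral halves.

Structures are marked from the fields plus metric widths:

* **SAN** — sphere of radius 2.50 mm centred on the SVC-rim node with
  minimal `phi_v2`.
* **FO annulus** — wall elements within 2.00 mm of the bridge attachment
  rim.
* **BB band** — nodes within 1.00 mm (half of the 2.00 mm width) of the
  geodesic polyline through the generator's bundle landmarks (Dijkstra
  paths on the edge graph).
* **TC** — iso-band 0.85 ≤ `phi_r2` ≤ 0.95 on the RA endocardial layer;
  **PM** — six periodic bands of `phi_v` (fill fraction 0.35) on the same
  layer.  Neither threshold family has published numeric values; these
  defaults reproduce the qualitative layout and are fully
  configuration-overridable.

Marking is monotone in every width, and overlaps resolve by the precedence
SAN > BB > TC > PM.

**Fibers** are a documented surrogate: the wall-tangent projection of the
gradient of one LD field per region (default `phi_ab`; appendage patches
use a field free of appendage boundary data), normalized to unit length,
with a neighbor-averaging fallback where the source gradient vanishes.
This yields a smooth, unit, wall-tangent family adequate for anisotropic
conduction, but it is not an anatomically validated fiber atlas; no claim
about real atrial fiber architecture follows from it.

## Universal atrial coordinates

Each atrium maps to a unit cuboid (α, β, γ):

1. A plane through the relevant orifice axes and the atrial center splits
   the atrium into two subdomains (septal/lateral for the RA,
   anterior/posterior for the LA; appendages are kept whole on their
   anatomical side).  The node bands where the two element sides meet form
   three transmural interfaces per atrium (valve-to-vein ×2, roof).
2. Interfaces and ring arcs are parameterized by the Bi-Eikonal value
   `s = d0/(d0 + d1)` from graph geodesic distances; the normalization
   cancels the first-order graph-metric bias.
3. α and β solve per-subdomain Laplace problems.  The embedded vein
   orifices (IVC/SVC, LSPV/RSPV) are recast in circumferential form as
   radius-R half-circles centred on (0, ½) and (1, ½) with R = 0.1; the
   valve annulus carries β ∈ {0, 1}; the roof interface β = ½; the
   valve-to-vein interfaces α ∈ {0, 1}.
4. γ is harmonic with 0 on the endocardium and 1 on the epicardium.
5. The CS, LIPV and RIPV rings are repositioned onto circles of radius
   r = 0.04 centred at (0.2, 0.8), (0.25, 0.25) and (0.75, 0.25) by an
   updated-Lagrangian linear elasticity solve in the UAC cuboid
   (thickness 0.1 in γ units; Young modulus 1, Poisson ratio 0.3, five
   load increments, interfaces and embedded rims Dirichlet-fixed, each
   ring split at its extremal-α points into upper/lower semicircle arcs).

Like any square parameterization of an annular surface, the coordinates
are discontinuous across the subdomain cut; interface nodes conventionally
carry the septal/anterior value, and the per-subdomain solutions are
retained for any mapping that needs single-valued coordinates.

**Bijectivity.** Volumetric harmonic maps with prescribed rim embeddings
are not globally bijective: compressing a ~30 mm physical ring onto a
radius-0.1 half-circle inverts roughly 1–2 % of elements, all within about
two edge lengths of an embedded rim.  Away from the rims and the
subdomain cut the map is orientation-consistent (verified on both atria at
multiple resolutions).  Coordinates computed at 2.4 mm and 1.7 mm
resolution agree to < 0.02 RMS in (α, β) on matched epicardial sample
points away from the cut.

## Activation model

Conduction is anisotropic eikonal: `sqrt(∇τ·V∇τ) = 1` with
`V = v_l² ffᵀ + v_t²(I − ffᵀ)` per element.  Baseline region velocities
(m/s, longitudinal/transverse): RA 0.97/0.74, LA 0.98/0.76, TC 1.21/0.92,
PM 1.30/0.99, BB 1.40/1.08, FO rim 0.33/0.24.  The solver is a
fast-iterative method with closed-form Godunov local updates (vertex, edge
and face candidates per incident tetrahedron), numba-compiled, default
tolerance 1e−3 ms.  A Dijkstra solver on the edge graph with edge weight
`sqrt(eᵀV⁻¹e)` is the independent upper-bound oracle; note that the graph
metric carries a persistent metrication overestimate (~13 % on structured
grids) that does not vanish under refinement — the eikonal solver, not the
oracle, converges.  At front collisions the face update can undershoot the
pointwise minimum of single-seed solutions by up to one cell traversal
time (it interpolates across the shock); away from the watershed the
multi-seed solution equals the minimum exactly.

Inter-atrial connections are delay cables anchored at UAC-defined sites:
the activation delivered at the insertion is `τ(origin) + l/v` (and
retrograde by default).  The coronary-sinus cable origin sits 3.5 mm
superior to the CS ostium, within the anatomically reported 3–8 mm range.
Cables contribute delays only; their tissue is not added to the ECG source
integral (a cable's volumetric source density would under-represent the
real bundle anyway).  The biatrial map is the fixed point of alternating
tissue solves and cable deliveries; the update is monotone
(non-increasing), so a few passes suffice.

## P-wave forward model

The transmembrane voltage is a travelling logistic upstroke
`V_m(x,t) = U(t − τ(x))` (rest −80 mV, peak +20 mV, time constant 1 ms;
repolarization is outside the simulated 0–150 ms window).  The electrode
potential is the lead-field volume integral
`φ_e(t) = Σ V_e ∇Z·(G_i ∇V_m)` over atrial elements, with isotropic
intracellular conductivity G_i = 0.174 S/m by default.

Three lead fields are provided: the infinite-medium closed form
`Z = 1/(4πσ|x−x_e|)` (default), an exact closed form for a homogeneous
*bounded* sphere with insulated boundary (the Neumann Green's function;
its Legendre series sums to `2R/d + ln(2R²/(R² − x·a + Rd))` up to an
additive constant that cancels in electrode pairs), and a P1
finite-element solve on the torso volume mesh with unit current
injection/extraction and nodal gradient recovery (volume-weighted patch
averages interpolated barycentrically).  The bounded-sphere form is the
correct oracle for the FEM solver: a surface current source in an
insulated conductor produces about twice the infinite-medium potential, so
comparing FEM to the infinite-medium form would conflate physics with
discretization.  With 24 cosine-graded shells the FEM electrode-pair
gradients match the closed form to < 5 % RMS at the atrial centroids.

Leads: I = LA−RA, II = LL−RA, III = LL−LA, Goldberger augmented leads,
chest leads against the Wilson central terminal; the panel order is
aVL, I, −aVR, II, aVF, III, V1..V6 (−aVR stored alongside aVR).
Conditioning: zero-phase 2nd-order Butterworth band-pass 0.5–150 Hz, then
scaling by 0.2.  Calibration comparisons use a separate 60 Hz low-pass.

## Metrics

Per lead: `RMSE% = sqrt(Σ(φ_v−φ_r)²/Σφ_r²)·100`,
`ℓ2 = sqrt(Σ(φ_v−φ_r)²/N)`, `MAD = Σ|φ_v−φ̄|/N` against the family mean
wave; cross-lead summaries are arithmetic means.  A configuration switch
restores the literal no-root reading of the printed formulas for audit.
P-wave duration uses a sloping delineator: the onset (offset) is the
baseline intersection of a line fitted over a 10-sample window around the
steepest slope of the first (last) deflection exceeding 10 % of the peak
amplitude, with the fit window clamped to the flank so the apex never
contaminates it.  The detector is amplitude- and shift-invariant and
recovers a triangular pulse's base width within ±2 ms.

## Calibration

The 24-entry parameter vector comprises the global longitudinal-to-
transverse velocity ratio (bounds [1.0, 1.6]), longitudinal velocities for
TC/PM/BB ([1.0, 2.4] m/s) and RA/LA ([0.8, 1.8] m/s), and six epicardial
activation sites — two SAN exit sites, two BB insertions, CS and one
posterior connection — each as (α, β, t) within their bound boxes.  The
ratio sets `v_t = v_l/ratio` uniformly across regions; sites anchor to the
nearest epicardial node of their atrium and act as prescribed-onset seeds.
Samples are the first n points of a scrambled Sobol' sequence (nested in
n, deterministic in the seed); a classic Saltelli block layout
(A, B, AB_i; n(d+2) runs) is available as an option since the canonical
block count and a plain quasi-Monte-Carlo reading of "500 samples per
parameter" cannot both hold.  Each sample runs activation → P-wave →
60 Hz low-pass → lead-averaged ℓ2 against the reference; the best sample
minimizes the loss, failed runs score +inf.  Sites captured by a
propagating front before their onset are pruned; pruning is verified by
re-simulation to leave the activation map unchanged.

## Problem sizes and test design

The default geometry (0.9 mm, ≈ 53 k nodes / 209 k tets) runs the full
anatomical pipeline in about a minute and backs the deterministic
acceptance contracts.  Unit and property tests use a 2.4 mm variant
(≈ 13 k nodes) with proportionally thickened walls so the two layers stay
resolved, slab benchmarks for solver accuracy, and 8–32-sample sweeps for
calibration self-consistency; these sizes are the package's chosen test
conditions and all tolerances are stated per test.  Synthetic geometry
validates construction rules, solver correctness and the calibration
machinery; it does not establish anatomical realism, P-wave amplitude
realism (the idealized source distribution yields smaller amplitudes than
clinical P-waves), or identifiability of the 24 parameters on clinical
data.

## Known limitations

* Appendages are flat patches; activation lacks the extra path length of
  real appendage pouches.
* The fiber surrogate is smooth but not anatomically validated.
* UAC bijectivity fails in a thin collar around embedded rims (above).
* Cables deliver to single nodes (patch insertion is configurable only by
  adding cables), and their own tissue does not radiate into the ECG.
* The torso is homogeneous; no lungs, blood masses or conductivity
  inhomogeneities.
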