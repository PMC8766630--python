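# Methods

This note records the models, numerical choices, and open design
decisions behind `rhinoflow`, module by module, together with what the
synthetic phantoms do and do not demonstrate.

## 4-phase rhinomanometry

A recording is one full respiration cycle of differential pressure
Δp(t) (Pa, nasopharynx vs. mask) and signed volume flux V̇(t) (cm³/s,
positive at inspiration).  Two conventions for the effective resistance
coexist in the rhinomanometric literature and are both implemented:

* `rms_ratio` (default): R_eff = RMS(Δp)/RMS(V̇) — the defining
  equality "effective pressure over effective flux";
* `printed_integral`: R_eff = sqrt((1/T)∫(Δp/V̇)dt) — the commonly
  printed closed form, which equals the RMS ratio only when Δp/V̇ is
  constant in time.  For Δp = c·V̇ the former yields c, the latter √c;
  this deliberate discrepancy is pinned down by a unit test.

Quadrature is trapezoidal.  The integral form excludes samples with
|V̇| below 1% of the cycle peak, avoiding the division blow-up at flow
reversal; an all-excluded cycle is rejected as degenerate.

Logarithms are base 10 (the classification magnitudes only make sense
in base 10).  The two published per-class upper-bound tables are shipped
verbatim as configuration; because the printed two-sided column is
internally non-monotone (class 3's range lies below class 2's) and the
one-sided column has a small gap and overlap, classification runs
through a single ordered-threshold engine: the running maximum of the
printed upper bounds, with `value ≤ threshold → first matching class`,
so overlap values resolve to the LOWER class.  Thresholds are data, not
code.  The vertex resistance is Δp/V̇ at the sample of maximum |V̇|
within the requested phase.  Age-corrected thresholds for 6–19-year-olds
are not implemented (the correction is referenced but not specified in
the source material).

## CNN segmentation

The segmentation networks are intentionally small and are implemented
directly on numpy with explicit forward/backward passes (verified by
central finite differences through the whole network).  Architecture:
repeated `3×3 conv → ReLU → 2×2 max-pool (stride 2, zero padding) →
specialized 3×3 conv → ReLU` blocks; each block's specialized output is
resized to the full ROI by separable bilinear interpolation without
corner alignment (the backward pass is the exact transpose); branches
concatenate into a feature volume; a per-class 1×1 convolution yields
the prediction stack (sigmoid for binary, softmax over depth for 9
classes).  Admissible hyperparameters: 1–4 conv layers, 5–20 filters,
fixed 3×3 kernels, Adam with learning rate 0.01 and batch size 1,
truncated-normal initialization (mean 0, std 0.1, truncation ±2σ; the
std and truncation are our choices, the distribution family is given).
Parameter count is independent of the ROI size (everything is
convolutional).

Losses use the natural logarithm and a probability clamp of 1e-7.  The
binary class-balanced cross entropy weights the foreground sum by
β = |Y⁻|/|Y| and the background sum by 1−β, exactly as printed — note
the source text names Y⁻ the *foreground* set, inverting the usual
convention; we implement the printed formula and keep the naming
question out of the code.  The balanced focal loss applies per-image
class multipliers β_s = exp(−|X^s|/|X|) (β=1 for an absent class, which
then contributes an empty sum) and the modulating factor (1−P)^γ.
Gradients through softmax/sigmoid are computed analytically.

Convergence is declared when the absolute change of the window-5
smoothed training cost stays below 1e-5 for 30 consecutive iterations
("residual" is not further specified in the source; training cost is
the natural reading and the one implemented).  Argmax ties at inference
resolve to the lowest class index.  The ROI is a centered crop with a
configurable offset (the exact placement within full slices is
unspecified upstream).

The balancer greedily appends transformed copies of slices containing
the least-dominant sinus class — random integer translations up to
±10% of the ROI with zero fill, or horizontal flips that swap the
left/right sinus label channels (bilateral symmetry) — until the mean
absolute pairwise difference of sinus pixel counts stops decreasing or
the dataset reaches 10× its original size (the reference workflow grew
its set ~8×).  Original slices are never modified.

## Label post-processing and metrics

Connectivity is 26-neighborhood in 3-D and 8-neighborhood within
slices.  The combined maxillary class splits into left/right by
component centroid relative to the mid-sagittal plane (the volume's
x-midplane unless supplied).  Components smaller than 10 voxels
(strictly) dissolve voxel-wise into the mode of their 3³ neighborhood,
own label excluded; the pass can be repeated to a fixpoint and is then
idempotent.  The plausibility pass applies only to anatomy flagged
healthy: per sinus class the largest component keeps its label, and a
smaller component is recolored to another cavity's class when its
centroid falls inside that cavity's convex hull (Delaunay test) — the
geometric notion of "anatomically implausible" is only illustrated by
example in the source, so the convex-region test is our concrete
choice.

Metrics are averaged per slice over the 9 classes, then over slices
(the averaging order is not fully specified upstream; per-slice-then-
dataset matches the verbal description).  A class empty in both volumes
contributes 100% to the Jaccard mean.  The component match maps the
per-class absolute difference in 2-D component counts through
100%/(1+|Δ|); any monotone map with 0 → 100% would be admissible, and
the map is an injectable parameter.

Surface extraction runs marching cubes at iso-level 0.5 on the
zero-padded binary mask of the selected classes (padding guarantees
closed surfaces), converts to mm via spacing/origin, enforces outward
normals, and optionally smooths with Laplacian passes.

## Octree mesh generation

The initial cube is the geometry's bounding box inflated by 5% and
cubified about its center.  Cells subdivide into 8 children per level;
a child is *cut* when a surface triangle overlaps its box (separating-
axis test against the parent's candidate-triangle list), otherwise a
single center inside-test decides the whole cell — if no triangle
crosses a cell, the cell lies entirely on one side, so this is exact
and is the robust variant of deleting "outside" cells.  A center-only
deletion criterion remains available behind a flag.  Boundary and patch
refinement proceed to the final level; a 2:1 level balance across faces
is enforced by refining coarse face-neighbors iteratively.

Inside/outside tests use parity ray casting (vectorized
Möller–Trumbore) with three jittered ray directions voting per point;
the test suite cross-checks 1,000 random points against an independent
generalized-winding-number oracle.

For the solver, the octree is rasterized at its uniform level.  Fluid
cells are the cells whose centers lie inside the geometry; cut cells
with outside centers contribute wall links only.  (Keeping
outside-center cut cells as fluid widens every passage by up to a cell
— measured as a ~2× error in the duct pressure gradient — which is why
the inside-center rule is load-bearing.)  Per-direction wall distances
q ∈ (0,1] are computed by casting each cut link against the cell's
candidate triangles; links without a hit fall back to q = 1/2.

## Thermal lattice-Boltzmann solver

D3Q27 with c_s² = 1/3 and weights 8/27, 2/27, 1/54, 1/216 (the source
never lists them; these are the standard values).  The particle
distribution relaxes toward the Maxwell equilibrium with
ω = 1/(3ν+1/2); the total-energy distribution h_i, whose zeroth moment
is ρE with E = (3/2)RT + v²/2, relaxes with ω_t = 1/(3α+1/2), α = ν/Pr
and Pr = 0.72 for air (the source ties ω_t to the thermal conductivity
without giving the law), plus the cross-coupling term
(ω_t−ω_f)(ξ·v − v²/2)(f_i−F_i).  The printed viscosity unit m/s² is
read as m²/s.  Pressure obeys p = ρc_s².

Walls: interpolated bounce-back (Bouzidi, both q-branches) for f; for h
an anti-bounce-back Dirichlet rule pins the wall energy at the wall
temperature (body temperature 309.15 K by default; a per-cell wall
temperature field supports mixed-temperature benchmarks).  The cited
thermal wall scheme's exact parameters are not reproduced in the source;
the anti-bounce-back rule implements the same Dirichlet intent at
halfway walls and is exact for the 1-D conduction benchmark.

Nostrils: the density follows the modified Saint-Venant/Wantzel
relation ρ = (1 − ((γ−1)/2γ)·3·(ρv)²/ρ²)^{γ/(γ−1)} with γ = 1.4, the
factor 3 read as 1/c_s² and ambient ρ normalized to 1; the previous
step's momentum is extrapolated from the inner cells, the temperature
is the ambient 293.15 K, and boundary-cell distributions are rebuilt at
equilibrium (rebuilding the full set rather than only the missing
directions trades a little accuracy for robustness at coarse
resolution).  Pharynx: either a fixed pressure offset via p = ρc_s², or
a proportional-accumulating controller that adapts the outlet pressure
each step by gain·(Re_target − Re_current) (the source states only that
"the pressure is adapted"; the controller structure and default gain
1e-5…1e-6 lattice-pressure per Reynolds unit are ours, and the fixed
point enforces the target flux exactly).  The controller clamps the
outlet density to [0.8, 1.2]·ρ₀; operating points should stay well
inside that range, or the prescribed flux saturates.

The solver runs on the finest uniform level (multi-level streaming is
out of scope; the reference production meshes are uniformly refined).
Initialization is the rest state at ambient density and temperature.
An optional Guo body force supports channel-flow validation.  A
deterministic run-then-average driver accumulates time-averaged fields
and interval monitors.

Benchmarks in the suite: plane Poiseuille flow converges at observed
order 2.0 (L2 errors 0.28%/0.07% at widths 16/32, τ = 0.8); at the
"magic" relaxation (τ−1/2)² = 3/16 the bounce-back channel solution is
exact up to round-off slip.  Steady conduction between plates at
309.15 K/293.15 K is linear to round-off.  Mass is conserved to 1e-12
per step in periodic boxes, and interior duct mass flux is constant to
~1e-7 with Bouzidi walls.

## Flow post-processing

Boundary summaries are unweighted means over the labeled opening cells,
exactly as the per-cell 1/H prefactors prescribe (no area weighting on
cut cells); Δp_tot = Δp_dyn + Δp_stat holds to machine precision by
construction.  The printed mass-flux convention uses the reference
density ρ₀; because the compressible solver's conserved flux is ρv, the
summary optionally measures Σρv one or two layers inward of the
boundary-reconstruction cells — that is the quantity whose in/out
balance closes to <1e-3 on the duct benchmark.

Cross sections use the slab |(x−C)·n| < (√3/2)δx (the "±" of the
two half-space tests read as their conjunction) and breadth-first
26-neighbor growth from the seed cell, so only cells connected to the
centerline station are kept; the suite proves equality with a
brute-force slab ∩ connected-component oracle on duct, two-duct, and
Y-junction phantoms over 50 random stations.  Station averages are
arithmetic means; profiles report arclength as % of the total
centerline length and skip (with a warning) stations that exit the
mesh.  Moving temporal averages use a centered window of Δt+1 samples
(Δt even) with truncate-and-renormalize edge handling — chosen over
dropping edge samples so monitor series keep their length.

Production centerlines are accepted as polyline input (they come from
external vascular-modeling tooling in practice).  For phantoms,
`naive_centerline` returns the analytic axis; for voxel masks it runs
Dijkstra between two endpoints with edge costs penalized by the inverse
squared distance transform, which pulls the path onto the medial axis
(verified within 1.5 cells on an L-bend and 2% arclength on a torus
segment).

## Phantoms — what they demonstrate, and what they do not

All generators are seed-deterministic.  The duct carries the
rectangular-duct laminar series solution (profile and flux
coefficient).  The two-passage airway is a *topological* stand-in for a
nasal cavity: two curved passages merging into a pharynx tube, optional
sinus pockets with narrow ostia, and an asymmetry factor a that scales
the narrowed side's minimal section area by exactly a (radius by √a).
The labeled head emulates the 9-class layout and the severe class
imbalance (sinus classes < 5% of pixels) with nominal Hounsfield
intensities (air −1000, tissue +40, bone +700, configurable σ, window
[−1000, 1000] → [0,1]).  None of these phantoms reproduce anatomical
geometry, CT artifacts, partial-volume effects, or inter-patient
variability — passing tests demonstrate correctness of the algorithms
and the qualitative physics (e.g., narrowing raises that side's
pressure loss monotonically at fixed flux), not clinical accuracy.

Simulation problem sizes in the suite are desk-scale by design: airway
runs use a ~1.2 mm lattice (level 5 on a 38 mm domain, ~10³ fluid
cells, 7,000 steps at a lattice flux of 0.35 and ν = 0.05), ducts
level 4–5, channels 16–32 cells wide.  The physical operating points
correspond to lower Reynolds numbers than adult quiet breathing; the
monotonicity and accuracy statements are the scale-robust content.

## Workflow

Projects are keyed by an order-independent SHA-256 content hash of the
configuration (and any input files); MD5 appears in the source only as
a transport-dedup detail and is not security-relevant here, so a modern
hash is used.  Stages run in order (segmentation → geometry → mesh →
simulation → post-processing), each writing its products into the
project directory; a completed stage with existing products is skipped
on re-run, a failing stage marks the project failed and leaves earlier
products untouched.  Pipeline outputs are pure functions of
(configuration, seeds): identical runs produce identical reports.
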