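# Methods

This note documents the models, conventions and numerical choices behind
`trabstiff`, in the spirit of the methods documentation of mature
scientific packages: what is computed, under which assumptions, and what
the synthetic validation does and does not demonstrate.

## Imaging model and calibration

Input volumes are stacks of 8-bit cross-sections with isotropic voxels
(default 18 µm = 0.018 mm), first axis caudal → cranial.  Gray value g maps
to mineral density by the affine fit through two phantom anchors
(ρ = s·g + c, fitted exactly through both).  An optional Hounsfield-unit
route (gray → HU pinned at air = −1000, water = 0, then HU → density) is
provided; the composition is itself affine, so both routes have identical
form and the choice is a bookkeeping matter recorded in the calibration
object.  Calibrated densities below zero are clamped to 0 g/cm³: density is
physical, and marrow/air may fall below the fit's zero crossing.

Segmentation is the closed interval [lo, hi] on gray values (default
[70, 255]); both endpoints are inclusive so that hi = 255 retains the 8-bit
maximum.  No despeckling is applied (the flag exists and is an explicit
no-op).  The cylindrical ROI uses the voxel-center-in-circle test in-plane
and a half-open slice range axially; the same rule at every resolution.

## Structural parameters

* **BV/TV** — bone voxels / ROI voxels, percent.
* **BMD (apparent)** — mean calibrated density over *all* ROI voxels, bone
  and marrow.  Reported vertebral trabecular BMD values (≈ 0.07–0.30 g/cm³)
  sit far below mineralized-tissue density, which identifies the quantity
  as the ROI mean, not a bone-tissue mean.
* **Tb.Th / Tb.Sp** — maximal-inscribed-sphere local thickness of the bone
  / marrow phase.  The Euclidean distance transform gives each candidate
  center its distance v to the nearest background voxel center; that center
  anchors a digital sphere of reach v and diameter 2v − 1 voxels (an
  isolated voxel has thickness 1).  Spheres are painted largest-first; each
  phase voxel keeps the largest diameter that reaches it, and the parameter
  is the phase mean.  This convention reproduces a 5-voxel slab exactly
  (thickness 5) and a digital ball of radius 8 to 15.12 voxels (diameter
  band 16 ± 10 %); the alternative 2·(EDT − ½) convention fails the ball.
  Separation treats everything outside the ROI as background, so marrow at
  the ROI wall is bounded there; Tb.Sp of a mask equals Tb.Th of its
  complement by construction.
* **FD** — box counting.  Boxes are corner-anchored; the ladder is every
  edge length in [2, N/4] that divides all grid dimensions, so boxes tile
  the volume exactly and no partial boundary boxes bias counts.  A purely
  dyadic ladder was measured to underestimate a triadic test fractal (the
  81³ Menger sponge: 2.50 vs the similarity dimension log 20/log 3 ≈ 2.727)
  through lacunarity aliasing of misaligned box sizes; the divisor ladder
  is exact on the cube, plane and Menger fixtures.  When the grid admits
  fewer than two divisor sizes a dyadic ladder with padded partial boxes
  is the fallback.
* **Tb.Pf** — dilation method: (S₁ − S₂)/(V₁ − V₂) under a one-voxel
  face-connected dilation, surfaces by exposed-face counting, in 1/mm.
  The dilation is clipped to the ROI region, mirroring a clipped analysis
  volume: structure touching the ROI wall cannot grow outward, so enclosed
  and concave spaces dominate the surface change and well-connected
  structure yields negative values; isolated convex structure yields
  positive values.  A mask filling the whole region has no room to dilate
  and is rejected.
* **DA** — mean intercept length.  Test-line bundles (default 64 lines at
  0.5-voxel sampling) are cast along 49 quasi-uniform directions
  (Fibonacci hemisphere with a seeded longitude offset; the seed is part of
  the report).  MIL(n) = 2·bone length / boundary crossings; directions
  without crossings are capped at the volume diagonal.  The classical
  ellipsoid fit n᷀ᵀA n = MIL(n)⁻² gives principal lengths 1/√λ, and
  DA = 1 − MIL_min/MIL_max ∈ [0, 1): 0 isotropic, → 1 fully oriented.
  This orientation-of-scale convention matches reports that read smaller
  values as "toward isotropy".  Numeric parity with any particular
  scanner-software MIL variant is not claimed.
* **Conn.Dn** — Euler characteristic of the foreground cubical complex
  (closed unit cubes; vertices − edges + faces − cells), equivalent to
  26-connectivity of bone.  Conn = 1 − χ; Conn.Dn = Conn/TV in 1/mm³.
  β₀ is not forced to one: with several components Conn = 1 − χ is
  reported as-is and a warning is emitted.
* **2D analogs** (per slice, against normalized height 0 → 1): area
  fraction, disc mean density, largest-inscribed-disc thickness/separation,
  2D box counting, exposed-edge perimeter pattern factor, in-plane MIL
  ellipse anisotropy.  Connectivity has no slice-wise analog and is
  omitted by construction.

Scale behavior is tested explicitly: doubling the voxel size doubles
Tb.Th/Tb.Sp, halves Tb.Pf, divides Conn.Dn by 8, and leaves BV/TV, FD and
DA unchanged.

## Region selection

Specimens' 2D curves are linearly resampled to a common uniform grid
(default 100 points), averaged per group, and differenced between groups.
The pipeline default selects the fixed caudal 40 % of the cylinder — the
anatomical choice that avoids the mid-height vascular foramen.  A
quantitative surrogate is available: every contiguous window of the given
fraction is scored by the mean absolute difference, each parameter curve
first rescaled to unit maximum absolute difference so no unit dominates
(separation runs opposite to the volume-fraction family, hence absolute
values); ties break toward the caudal end.  The scored rule is a
reproducible stand-in for a by-inspection choice, and is exercised against
a brute-force window scan in the tests.

## Micro-FE model

Each bone voxel becomes an 8-node trilinear hexahedron at native voxel
size; no resizing or smoothing.  Before meshing, face-connected (6-
connectivity) components are filtered: every component touching both the
bottom and the top plane is kept — each is a parallel load path — and the
rest (floating or corner-hinged fragments, which would render the system
singular) are dropped, with the removed volume fraction logged and warned
about above 5 %.  If nothing spans, a no-load-path error is raised.

One isotropic linear-elastic material everywhere (default E = 24.5 GPa,
ν = 0.3; reported indentation work finds no modulus difference between
sham and estrogen-depleted rat bone, so a single material is the contract —
gray-value-mapped moduli and nonlinearity are out of scope).  Units are
mm–N–GPa (1 GPa = 10³ N/mm²); stiffness is N/mm.

Boundary conditions, one flag apart:

* **bonded** (default): bottom face fully fixed; top face axial
  displacement −Δd (Δd = strain × height, default strain 0.05), lateral
  components free.
* **frictionless**: axial constraints only on both faces, plus minimal
  lateral pins per load-bearing component (one bottom node pinned in x and
  y, a second at different x pinned in y).  The pins are compatible with a
  homogeneous uniaxial strain field, so the analytic oracles hold exactly:
  a solid cylinder gives k/k′ = voxelized/nominal area ≈ 1, and a vertical
  rod lattice gives k/k′ equal to the rods' share of the nominal circle to
  10⁻⁶.  Fixed-end constraint stiffening makes bonded-mode k ≥ frictionless
  k on the same mesh.

The canonical 24×24 element matrix (2×2×2 Gauss quadrature, exact for the
trilinear cube) is computed once — all elements are identical cubes — and
scattered into a global CSR matrix.  The reduced system is solved by
conjugate gradients with Jacobi preconditioning to relative residual 10⁻⁸
(deterministic for fixed inputs); iterative solutions match a dense direct
factorization to 10⁻⁸ relative on every test mesh, and summed axial
reactions balance top against bottom to 10⁻⁶ relative.  An assembled-CSR
operator was preferred over an element-by-element matrix-free product
because at the problem sizes used (≲ 10⁵ elements) assembly takes seconds,
memory stays modest, and the sparse product is faster per iteration; the
contract (iterative, diagonally preconditioned, deterministic) is
unchanged.

k = |ΣR_z on the fixation| / Δd.  k′ = E·A/L uses the *nominal* circle
area πD²/4 of the ROI and the height of the analyzed segment: the
normalization refers to the idealized solid cylinder, and the ≈ 0.6 %
voxelization discrepancy is inside the solid-cylinder tolerance.  Whether
the original normalization used the segment's or the whole cylinder's
length is unknown; the segment's own L and D are used (the index is
dimensionless either way).  Meshes can be exported as ABAQUS-dialect
`.inp` decks (C3D8) and re-parsed losslessly.

## Statistics

Mann–Whitney U (two-sided; exact enumeration for tie-free samples of ≤ 10,
otherwise tie-corrected normal approximation with continuity correction —
asymptotic is the reporting default, exact serves validation), Kruskal–
Wallis with tie correction (all-identical data degenerate to H = 0, p = 1),
Pearson r with the two-tailed t-transform on n − 2 dof.  Mid-ranks for
ties; no multiple-testing correction anywhere, matching the two-group
design's reporting conventions.  Summary tables carry mean ± SD per
group × level, a pooled Total column (with equal level sizes, the mean of
level means — the aggregation verified against printed table rows), and
pairwise level letters a/b/c at p < 0.05.  Correlations against k/k′ are
computed within group (the reference design) and pooled, the pooled rows
flagged as auxiliary.

## Synthetic data

Geometric fixtures (ball, torus, slab, Menger sponge, solid cylinder,
rod/plate lattices) have closed-form morphometry and serve as oracles.
Trabecular-like volumes are thresholded Gaussian random fields: seeded
white noise smoothed with sigma (4, 2, 2) voxels — twice as smooth axially
as in-plane, mimicking the vertical orientation of vertebral trabeculae
(measured DA ≈ 0.4 on defaults) and keeping the network axially
load-bearing at resorbed bone fractions; isotropic fields at ≈ 22 % BV/TV
were measured to lose their axial load path in the caudal-40 % window for
about one specimen in twenty, which real vertebral bone does not.  The
threshold is the field quantile hitting the target BV/TV within 0.5
percentage points.  A transverse mid-height channel emulates the vascular
foramen that depresses mid-height bone fraction.

The OVX-like transform raises the threshold on the *same* field, eroding
bone surface-inward: the output mask is a strict subset of its sham
sibling, bone volume and connectivity fall while surviving trabecular
thickness is largely preserved — the architectural signature of resorptive
loss, and the reason thickness differs little between groups while
stiffness collapses.  Default study: 10 specimens/group, one vertebral
level (the level on which the stiffness-correlation design rests),
cylinder 48 voxels across × 72 slices at 18 µm, sham BV/TV ~ N(35 %, 3 %),
deficit ~ N(12, 1.5) percentage points, mid-height foramen of 0.08 mm
radius, all per-specimen seeds spawned deterministically from one master
seed.  These sizes keep the full pipeline (morphometry + 20 FE solves) at
roughly four minutes on one CPU.

What passing tests show — and what they do not: the phantoms validate the
*computations* (every parameter against analytic or brute-force oracles,
the solver against closed forms and dense factorization, the study against
its configured contrasts).  They do not reproduce specimen-level values of
real rat vertebrae: random-field microstructure is less connected than
real trabecular networks at equal BV/TV, so absolute k/k′ runs lower
(sham ≈ 0.13 here) than scan-derived values, while directions of effect,
correlation signs and curve shapes do transfer.

## Known limitations

* Axis-aligned inputs only (transposition/flip, no oblique reorientation);
  no reconstruction, beam-hardening or ring-artifact handling.
* Single-material, geometrically linear, small-strain elasticity; no
  failure, viscosity or gray-value-mapped moduli.
* No Tb.N, SMI/plate-rod decomposition, or cortical parameters.
* MIL implementation details (line counts, rotation grids) differ between
  packages; DA values are convention-consistent, not vendor-matched.
* Phantoms have no cortex, growth plates, or scanner noise beyond additive
  Gaussian gray noise.
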