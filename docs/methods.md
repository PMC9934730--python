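# Methods

This note records the models implemented in `valvemetrics`, the numerical
choices behind them, and their known limitations. Units are mm, mm², and kPa
throughout.

## 1. Regurgitant orifice area (ROA)

**Problem.** Given a closed-valve surface mesh (e.g. the systolic frame of a
finite-element simulation) and a ring of user landmarks placed around the
orifice region, measure the area through which blood can actually leak. The
measurement must be three-dimensional — planar projections underestimate
tilted or tortuous gaps — and must not be fooled by deep creases or folds
between leaflets that look like gaps from above but are sealed below.

**Pipeline** (`valvemetrics.orifice.compute_roa`):

1. *Inflation.* FE leaflet meshes are midsurfaces; the physical occluder is
   the leaflet volume. Each vertex is offset ±t/2 along its area-weighted
   vertex normal and open boundary edges are stitched with side-wall quads,
   producing a watertight shell wherever the input winding permits. For a
   thickness of 0 the input mesh is used as-is (useful when the mesh already
   represents the occluder).
2. *Contour.* A periodic cubic spline is fitted through the landmarks
   (chord-length parameterization) and resampled to near-equal arc length.
   Degenerate inputs — fewer than 3 points, repeated points, collinear
   rings, self-intersections in the best-fit plane — are rejected.
3. *Cover surface.* A flat disk template (center vertex plus concentric
   rings; the outer ring matches the contour sample count) is warped onto
   the contour. Interior vertices are placed by harmonic interpolation of
   the boundary using the graph Laplacian, so the initial cover is smooth,
   interpolates the contour exactly, and obeys a discrete maximum principle.
4. *Shrink-wrap.* Iteratively: (a) several sweeps of boundary-pinned uniform
   Laplacian smoothing, which simultaneously regularizes the surface and
   redistributes vertices (connectivity stays fixed); (b) each free vertex
   moves toward its exactly-computed closest point on the occluder, with the
   step capped at half the mean edge length so the cover cannot tunnel
   through thin walls; (c) faces are classified *contact* vs *potential
   orifice* by centroid distance to the occluder. Iteration stops when the
   potential-orifice area changes by less than 0.1% (relative), with a hard
   iteration cap and a logged warning if that cap is hit.
5. *Ray filter.* For each potential face, up to 400 rays are cast from just
   above its centroid inside a 50°-apex cone about the face's through-flow
   normal. A face is a *valid* orifice patch as soon as one ray leaves the
   occluder unobstructed (travels 4× the occluder bounding-box diagonal);
   otherwise it is *invalid* (a bridged pocket). A strict mode
   (`escape_validates=False`) is also available, where a single obstructed
   ray invalidates the face; it is deliberately conservative and rejects
   collimated channels.
6. *Assembly.* Valid faces are grouped into edge-connected components, one
   per distinct orifice; the ROA is their total area.

**Numerical choices.**

- *Ray directions are deterministic and nested*: golden-angle azimuths
  combined with a base-2 radical-inverse polar coordinate, so the first m of
  n directions equal the m-direction set, the first direction is exactly the
  cone axis, and increasing the ray budget can only validate more faces
  (monotonicity). No randomness enters the pipeline anywhere, so results are
  bit-reproducible.
- *Through-flow orientation*: the cover's winding gives consistent normals;
  the global sign is chosen so normals point, on average, from the cover
  toward the center of the occluder's bounding box — i.e. into the channel
  the regurgitant flow must traverse. The sign can be overridden with
  `flip_normal` for unusual geometries.
- *Contact threshold*: 5% of the mean cover edge length. The wrap snaps
  contact vertices essentially onto the occluder (residual distance ≈ 0), so
  the threshold only needs to absorb smoothing residue; keeping it small
  keeps the misclassified rim band around each orifice thin. A fixed
  `contact_dist` can be supplied instead.
- *Exact geometry kernels*: point-to-triangle distance uses the standard
  Voronoi-region closest-point construction over k-d-tree candidates with a
  provable search-radius expansion, and ray casting uses Möller–Trumbore
  any-hit tests, both JIT-compiled (numba). Occluder meshes are coarse
  enough that brute-force per-ray triangle loops with early exit are fast
  without a bounding-volume hierarchy.

**Verification.** Plates with circular holes recover π·r² within 2% (the
residual is dominated by the inscribed rim polygon of the fixture itself);
multiple holes are reported as separate components with the correct area
ratio; an intact plate yields exactly zero. The crease-trap fixture — two
deep sealed trenches bridged by the wrap (≈120 mm² of false potential area)
plus one true 20 mm² through-slot continued by a 60 mm collimating shaft —
is resolved to within 10% of the slot area, and the filter's per-face
decisions are cross-checked against a 10⁵-random-ray visibility oracle. ROA
is invariant under rigid rotations to ~13 significant digits and stable
under a doubling of cover resolution to ~0.1%.

**Limitations.** The landmark ring must enclose all orifices and lie outside
them; the cover is a topological disk, so orifices outside the ring are
invisible. The inflation assumes a reasonably consistent winding; severely
self-intersecting leaflet meshes can produce a non-watertight occluder, which
weakens (but does not break) the ray filter. The escape-validates rule can
overestimate slightly at orifice rims, where a face partially overhanging
the hole still finds an escaping ray; the rim band is one face wide, so the
bias shrinks with cover resolution.

## 2. Contact / coaptation metrics

`contact_metrics` integrates per-cell FE output fields: contact area is the
total area of faces whose contact traction exceeds a threshold (default 0),
and `field_mean` computes area-weighted (or uniform) means of scalar cell
fields, e.g. principal stresses or strains. These are deliberately simple,
exact quadratures over piecewise-constant fields; they are refinement-
invariant by construction and are verified against hand-computed cases.

## 3. Lee–Sacks leaflet material

The isotropic, incompressible Lee–Sacks strain-energy function

    W(I1) = c0/2 (I1 − 3) + c1/2 [exp(c2 (I1 − 3)²) − 1]

models the soft-then-stiffening response of valve leaflet tissue: a
neo-Hookean toe region governed by `c0` and an exponentially stiffening
large-strain regime governed by `c1` and `c2`. For incompressible uniaxial
extension (I1 = λ² + 2/λ), the Cauchy stress is

    σ(λ) = 2 (λ² − 1/λ) dW/dI1.

Reference parameters (healthy mitral leaflet): c0 = 200 kPa, c1 = 2968.4 kPa,
c2 = 0.2661, thickness 0.396 mm. Sampling bounds for sensitivity studies are
±50% of these values.

Implemented tools:

- `uniaxial_stress` / `uniaxial_curve` — forward model; reduces exactly to
  σ = c0(λ² − 1/λ) when c1 = 0, and has small-strain modulus 3·c0.
- `stretch_at_stress` — inverse by bracketed root-finding (Brent); the
  stress is strictly increasing in λ > 1, so the root is unique.
- `derive_variant` — given a target extra extensibility (percent increase in
  stretch at a reference stress, default 100 kPa), scale (c0, c1) jointly by
  the closed-form factor s = σ_ref / σ_base(λ_target). This is exact because
  σ is jointly linear in (c0, c1) at fixed c2; the implementation verifies
  the achieved stretch anyway. `c2` and thickness are preserved, so variant
  curves keep the same strain-stiffening shape.

**Limitations.** The model is isotropic and incompressible; real leaflets
are anisotropic (collagen fiber families) and layered. The material module
characterizes parameter variants — it does not replace an FE solve, and
tissue-level stresses in a deformed valve cannot be derived from it alone.

## 4. Uncertainty quantification

- *Parameter spaces* map physical parameters to the unit cube [−1, 1]^d.
  The default space is the ±50% mitral Lee–Sacks box above.
- *OAT designs*: one parameter swept over n uniformly spaced levels
  (including both bounds) while the others stay at reference — 4 × 5 = 20
  rows by default. `run_study` evaluates a quantity of interest per row with
  per-row fault isolation (a failed run is recorded, not fatal, unless all
  rows fail), and `oat_summary` reports relative ranges and sweep skewness.
- *WAFP designs*: a large candidate pool in the cube is scored by the
  Christoffel-weighted total-degree Legendre Vandermonde matrix; a pivoted
  QR factorization of its transpose picks the first n rows (weighted
  approximate Fekete points). This yields well-conditioned least-squares
  problems at n ≈ 2× the basis size (80 points for the 35-term
  total-degree-3 basis in 4 dimensions).
- *PCE*: orthonormal Legendre polynomials (√(2k+1) P_k, tensorized over a
  total-degree index set) fitted by least squares. Because the basis is
  orthonormal under the uniform measure, the surrogate's mean, variance and
  Sobol indices are read directly off the coefficients: first-order indices
  sum squared coefficients whose multi-index involves only variable i;
  total-order indices sum those involving i at all.
- *Ordering consistency*: given a matrix of a metric across conditions
  (rows) × scenarios (columns), ranks are computed per column (average rank
  for ties) and the ordering is *preserved* iff all columns share one rank
  vector; pairwise Kendall tau quantifies partial agreement. Constant
  columns are flagged — a metric that does not vary cannot order conditions.

**Verification.** Ishigami (a = 7, b = 0.1) total indices from a
total-degree-10 PCE on a 600-point WAFP design match the closed-form values
to ≈3×10⁻⁵ and an independent 2¹⁴-sample Saltelli/Jansen estimate to ≈1%;
f = 2x₁ + x₂ gives S_T = (0.8, 0.2) to machine precision; the surrogate is
exact on polynomials of the fit degree; indices are invariant under affine
rescaling of the output.

**Limitations.** PCE assumes independent, uniformly distributed parameters
over the box; correlated or non-uniform priors require a different basis or
a rosenblatt transform (not implemented). Total-degree-3 in 4 dimensions
resolves smooth responses; strongly discontinuous QoIs (e.g. a valve
snapping between leaking and sealed) need higher order or segmented fits.

## 5. Synthetic fixtures

All verification geometry is generated, deterministic, and carries analytic
truth values:

- plates with circular holes (2-D Delaunay with rim-conforming vertex rings;
  truth = Σ πr², plus the exact inscribed-polygon area actually meshed),
- an intact plate (truth = 0),
- the crease trap (two sealed 3×20×10 mm trenches at ±8 mm bridged by the
  wrap, one 2×10 mm through-slot with a 60 mm collimating shaft; truth =
  slot area, trap footprint = 120 mm²),
- a spherical dome with a polar hole and a coapted-leaflet pair with a
  central gap (truths flagged `approximate`: chord-disk and projected-gap
  areas respectively),
- a traction plate for the contact metrics with an exactly known contact
  area.

Fixture specifications validate their own feasibility (holes inside the
plate, landmark ring enclosing every opening, slot smaller than the trap) so
an infeasible study fails loudly at construction, not silently at analysis.
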