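# Methods

This note documents the geometric model, the numerical choices and the
synthetic data underlying `owhto`, and what the tests do and do not show
about real CT-derived data.

## Model of the surgery

Medial open-wedge high tibial osteotomy is idealised as a rigid rotation:
the bone is split by the cutting plane, the proximal fragment rotates by θ
about a hinge axis lying in that plane, and the distal fragment is fixed.
Three simplifications are inherited from this idealisation and are
deliberate:

* **No wedge fill.** The opened gap is not closed with new surface; faces
  that straddle the plane keep their vertex connectivity and stretch.
  Cutting is by vertex classification (strict signed distance > 0 is
  proximal; ties stay distal so hinge vertices do not move), never by face
  clipping or re-triangulation.  Scoring is unaffected because similarity
  is measured on the proximal fragments only, cropped to faces entirely
  above the plane.
* **No bone deformation.** The real lateral cortical hinge deforms
  plastically; here the fragment motion is exactly rigid, so the recovered
  rotation angle equals θ to 1e-6°, which the tests exploit as an
  invariant.
* **Fibula fixed.** The medial procedure does not cut the fibula; vertices
  labelled `fibula` never move regardless of their side of the plane.

The rotation sign is chosen per axis so that positive θ opens the wedge
medially (valgus): a probe point medial of the hinge must move towards the
proximal side of the plane.  This makes the convention robust to the
orientation of the axis direction vector.

## Anatomical constructions

* **Tibial frame** (origin at the distal articular centre): z is the unit
  vector to the ACL/PCL midpoint, y the component of (ACL − PCL) orthogonal
  to z, x = y × z.  Published tibial-frame conventions differ in detail;
  this one is fixed, documented, and uses exactly the three landmarks.  The
  construction is equivariant under rigid motion of the landmarks (tested).
* **Cutting plane**: contains M0 = medial plateau edge − 35 mm·ẑ (offset
  configurable) and the fibular head, with a normal constrained to the
  frontal x–z plane and pointing proximally.  This is the horizontal plane
  rotated about the anteroposterior axis — the oblique single-plane cut.
* **Hinge axes**: no published coordinates exist for the clinically
  observed hinge variants, so the defaults are *illustrative*: a base point
  inset 8 mm medially from the lateral plateau edge, projected vertically
  onto the plane; axis1 anteroposterior through that point, axis2 parallel
  and 10 mm medial (distinct axes must be separated perpendicular to their
  direction), axis3 oblique through two points offset ±12 mm
  anteroposteriorly.  Explicit `l0…l3` landmarks override the defaults;
  points farther than 2 mm from the plane are projected with a warning and
  rejected beyond 10 mm.  Every returned axis lies in the plane to 1e-9.
* **Left knees** are mirrored about the sagittal plane on load (with face
  winding reversed), so all internal math assumes a right knee.

## Similarity scoring

* **Average surface distance** is vertex-to-nearest-triangle, never
  vertex-to-vertex (independently acquired meshes share no vertices).  The
  default symmetric mode averages the two one-sided means and is exactly
  symmetric in its arguments; one-sided is available by flag.  Distances
  are exact: a k-d tree over triangle centroids proposes the nearest
  candidates, a point is certified once its k-th centroid distance minus
  the maximum triangle circumradius exceeds the running minimum, and the
  remaining points are finished with a ball query over every triangle that
  could still win.  On meshes small enough to brute-force, the accelerated
  result matches the all-triangle minimum to 1e-9 mm (tested, plus an
  independent cross-check against `trimesh.proximity`).  The per-pair
  kernel is numba-compiled; a pure-numpy implementation of the same
  closest-point-on-triangle case analysis is kept as the oracle.
* **Registration** is point-to-surface ICP with a Kabsch (cross-covariance
  SVD) update, identity initialisation (both meshes are frame-normalised
  upstream), convergence when the RMS changes by < 1e-6 mm, and a budget of
  100 iterations per phase; non-convergence is reported, never silent.
  Outliers are handled in two ways, both chosen after the obvious
  alternative failed:
  * correspondences whose nearest point lies on a triangle at an *open
    boundary* of the target (the rim of the plate-removal hole, the cut
    edge) are excluded from every fit — such points have no true
    counterpart, and they are what otherwise drags the fit into the hole;
  * the trim fraction (default 0.9) is applied once, as a *frozen* inlier
    subset selected by distance rank after the boundary-filtered descent
    has converged, and the fit is refined on that fixed subset.
    Re-ranking the trimmed set every iteration was tested and rejected: it
    preferentially discards the distinctive geometry (metaphyseal flare,
    fibular head) that prevents the near-cylindrical shaft from sliding
    axially, and it stalls convergence.  The trim fraction should be set
    below the expected overlap when holes are large.
  Sources above 2 000 vertices are subsampled with a deterministic even
  stride.
* **Model comparison** crops both meshes at the plane, registers the
  postoperative distal fragment onto the simulation's fixed fragment,
  applies the recovered transform to the whole postoperative mesh, and
  scores the proximal fragments.  Because the postoperative mesh arrives
  with an unknown rigid offset, the plane crop before alignment is
  approximate; the crop-and-register step therefore runs twice (rough
  align → re-crop at the aligned pose → refine).  A single pass left a
  residual misalignment of ~0.2 mm that biased the distance-vs-θ curve
  towards smaller angles.
* **Grid search** reuses one registration for all 60 models after
  verifying their distal fragments are bit-identical (they are, by the
  rigid-fragment invariant), and caches the postoperative proximal query
  structure.  Failures are recorded as missing rows, not fatal errors.
  Ties in the argmin prefer the smaller θ (least invasive correction),
  then the axis label order.

## Alignment evaluation

The mechanical line runs from the hip joint centre to the centre of the
distal tibia.  The hip centre and the plateau edges are mapped by the
fragment transform — the femur is assumed to keep its preoperative
relation to the tibial plateau — while the ankle end stays fixed; this is
what makes the plateau crossing increase monotonically with θ.  The
crossing is computed in the frontal (x–z) projection against the
supporting line of the medial→lateral plateau segment; values outside
[0, 100] % are valid and reported as-is (severe deformity).

Acceptability is the inclusive band Fujisawa ± tolerance (default
62.5 ± 5 %), with a 1e-9 % guard against floating-point dust at the
boundaries.  The equivalent construction of an arc through the two band
endpoints centred on the hip is implemented as an independent validation
route (`arc_acceptable`); the two selections agree on the test grids away
from the 0.1 % knife edge.

## Synthetic data

The surrogate tibia is a closed surface of stacked elliptical
cross-sections: an elliptical shaft (semi-axes 14 × 11.2 mm — elliptical
on purpose, so axial rotation is observable by registration), a smooth
metaphyseal flare over the top 60 mm into an 80 × 55 mm plateau cap, a
mild distal (ankle) flare, and an ellipsoidal fibular head (radius 8 mm)
as a separate component whose apex defines the fibular-head landmark.
Varus is a rotation about the anteroposterior axis blended smoothly over a
50-mm metaphyseal transition zone (default 8°); the plateau and everything
above it move rigidly, so plateau landmarks and the hip centre (placed one
femur length along the tilted plateau normal) are analytically exact.  At
zero varus the mechanical line crosses the plateau at exactly 50 %; at the
default 8° it crosses at ≈ 24 % (varus), and corrections of ≈ 9–11° reach
the Fujisawa band.  Every output is a pure function of the parameters.

Ground-truth postoperative meshes are manufactured by regenerating the
same surface at a shifted angular phase and a 0.85× edge length (no vertex
identity with the preoperative mesh apart from the four sampling-
independent axial pole points), applying the known plan, then:

* Gaussian displacement along vertex normals (segmentation noise,
  default σ = 0.1 mm — at the truth the average surface distance
  approaches E|N(0, σ)| ≈ 0.08 mm);
* deletion of a connected patch grown by face adjacency on the medial
  cortex below the cut (the manually removed fixation plate; the patch is
  kept distal because its role is to stress the distal-fragment
  registration, and the similarity index is measured proximally);
* a bounded random rigid offset rotating about the bone centroid (a
  scanner-pose mismatch tilts the object; rotating about the ankle origin
  would displace the knee by ~5 mm per degree, which is not what a bounded
  pose offset means).

What the surrogate does **not** emulate: condylar spines, the tibial
tuberosity, cortical-versus-cancellous contrast, segmentation topology
errors, and any real bone deformation at the hinge.  Passing tests
therefore demonstrate the geometric correctness and robustness of the
pipeline under controlled corruption — not clinical accuracy on patient
CT reconstructions.

## Problem sizes and determinism

Default meshes use a nominal 1.5 mm edge length (~43 000 vertices,
~87 000 faces); most unit tests run a 3 mm surrogate.  The end-to-end
recovery study in the acceptance tests runs one fixed condition
(axis2, θ* = 10°, σ = 0.1 mm, 10 % patch, ≤ 10°/10 mm offset) plus 20
randomized trials with θ* ∈ {3…18}°, random axis and σ ∈ [0, 0.2] mm at
the default resolution, asserting exact θ recovery in ≥ 95 % of trials and
|Δθ| ≤ 1° always.  All randomness flows through seeded
`numpy.random.Generator` instances; generators, grids and file outputs are
bit-reproducible given the same configuration (the run manifest embeds a
configuration hash; the manifest's timing field is the one output that
varies between reruns).

## Known limitations

* The hinge-axis defaults are geometric placeholders, not validated
  clinical hinge types; studies of hinge-position effects should supply
  their own `l0…l3`.
* Biplane (tuberosity-preserving) osteotomy, plate/implant modelling and
  weight-bearing-line estimation from radiographs are out of scope.
* The fallback resampling for non-parametric meshes (midpoint subdivision)
  retains the parent vertices; only the parametric regeneration guarantees
  vertex-disjoint ground truth.
* ICP capture range is roughly 20°/20 mm of initial misalignment; inputs
  should be landmark-frame-normalised first.
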