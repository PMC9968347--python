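# Methods

## The measurement problem

Percutaneous cement discoplasty (PCD) injects acrylic bone cement into a
degenerated, vacuum-phenomenon disc so the hardened cement acts as a spacer
between the vertebrae and indirectly decompresses the exiting nerves.  The
outcome quantity implemented here is the *free neuroforaminal volume* V of a
functional spinal unit (FSU, two vertebrae plus disc) in a loaded pose, and
its change

    dV = V_discoplasty − V_nucleotomy

between the pre-operative surrogate (nucleotomy: emptied nucleus) and the
post-operative condition, measured separately for flexion and extension at
peak load.

The chain mirrors an ex vivo workflow in which an optical system (digital
image correlation, DIC) records the lateral surface of the loaded specimen
while the 3D bone geometry comes from a clinical CT scan:

1. **Surface reconstruction.** The DIC point cloud (one frame at peak load)
   gets per-point normals from the best-fit plane of its 100 nearest
   neighbours, consistently oriented by propagation along a minimum-spanning
   tree and a global outward flip.  The surface is reconstructed by the
   ball-pivoting algorithm with the radius schedule 0.8, 1.0, 1.1 mm
   (clustering radius 20% of the ball radius, angle threshold 90°) and a
   final 1.25 mm pass at 10% clustering that only adds triangles which do
   not superpose existing ones.  Reconstruction never resamples: output
   vertices are input points.
2. **Segmentation.** The CT image is thresholded at > 700 HU (strict
   inequality) into a bone-plus-soft-tissue mask; bone and cement are
   separated by disjoint intensity bands with largest-connected-component
   cleaning (26-connectivity), the bone mask splits into caudal and cranial
   vertebrae by connected components (or a user plane when they touch), and
   each mask becomes a world-coordinate surface by marching cubes at
   iso-level 0.5 on the binary mask.
3. **Registration.** Each per-vertebra DIC patch is rigidly registered onto
   its CT surface by point-to-surface ICP (exact closest-point
   correspondences, Kabsch re-fit from the original points each iteration).
   The inverse of each registration carries the CT geometry into the
   experimental pose; the caudal vertebra anchors the frame and the relative
   cranial pose T_rel = T_caudal ∘ T_cranial⁻¹ is the kinematic output,
   invariant to any global motion common to both patches.
4. **Volumetry.** A measurement cylinder (90 mm long, axis through both
   neuroforamina, radius fixed per specimen × motion across both conditions)
   is Boolean-subtracted by the union of the two posed vertebrae; the free
   volume is reported for each condition and differenced into dV.
5. **Statistics.** Cohort dV is tested by a paired Wilcoxon signed-rank
   test, the cement-volume/dV relation by Spearman rank correlation, and
   rater repeatability by two-way absolute-agreement intraclass correlation
   (single measurement for intra-rater, mean of k = 4 for inter-rater),
   with F-method 95% confidence intervals.  α = 0.05 throughout.

## Volume back-ends

*Exact* — the vertebrae are sliced perpendicular to the cylinder axis; each
solid cross section (assembled per closed shell from the triangle/plane
segments under the even-odd rule) is unioned and intersected with the
cylinder disc (a 1024-gon) using polygon Booleans, and the occluded area is
integrated by the midpoint rule (default step 0.1 mm, 0.2 mm inside the
pipeline).  The same disc polygon provides the total cylinder volume, so a
fully buried cylinder measures exactly zero.  This path requires watertight
meshes and is deterministic.

*Voxel* — cylinder and vertebrae are rasterized on a lattice (default
0.2 mm, with a deterministic sub-cell shift in the disc plane that avoids
the systematic counting bias of a circle aligned with the lattice) and free
lattice cells are counted.  The two back-ends are implemented independently
and agree within 0.5% on phantom configurations; the voxel path doubles as
the oracle for the exact one.

## The synthetic phantom

Real inputs (cadaveric FSUs with DIC recordings and clinical CT) are not
shippable, so every stage is exercised on a parametric phantom with known
ground truth.  Each vertebra is a watertight union of primitives: a
chamfered, beveled prismatic body (34 × 44 × 26 mm by default), two pedicle
bars tilted by a mirrored ±12° about the antero-posterior axis, and a
posterior arch whose roof and floor slope by 8°.  Two stacked vertebrae
enclose a genuine transverse tunnel — the neuroforamen — along +y through
both foramina and the canal.  The tilts/slopes matter: anatomically,
pedicles and laminae are angled, and a phantom whose foramen-bounding faces
are parallel to scan-grid planes would couple a coherent half-voxel
iso-surface offset into dV (degenerate phantom/grid alignment, the same
reason voxel centers are offset from primitive faces by a sub-voxel origin
shift during CT emulation).

Conditions and poses: the canonical frame is the CT pose (discoplasty,
neutral, cement block in the disc space).  Nucleotomy removes the
distraction (default 3 mm — the cement-spacer height gain); flexion and
extension are relative rotations of the cranial vertebra about the
medio-lateral axis through the disc center (defaults 5° and 4°, lumbar
FSU-scale angles).  Loading forces are out of scope by design: the
measurement happens at peak load, so the pose is the sufficient statistic.

DIC-like patches sample the lateral-facing surfaces (face normal within 90°
of the +y view direction) of both vertebrae plus a disc-region surrogate at
4 points/mm² (≈0.5 mm spacing, matching the reconstruction radii), with
isotropic Gaussian noise of SD 0.002 mm — the instrument-accuracy order of a
validated DIC system — and per-point provenance labels standing in for the
manual selection of vertebral sub-surfaces.  CT emulation rasterizes bone at
1200 HU and cement at 2000 HU on a 0.214 × 0.214 × 0.3 mm grid
(clinical-like geometry) with additive Gaussian noise (default SD 25 HU).
Voxels are binary (no partial-volume ramp); consequently iso-surfaces carry
up to half-voxel positional uncertainty that real CT, with its
partial-volume gradients, can partially avoid — phantom results therefore
bound the *geometric* fidelity of the chain, not scanner physics.

The cohort generator draws cement volumes uniformly from 2–9 ml (the
clinically reported range) and, by default, couples the distraction to the
injected volume (0.5 + 0.45 mm/ml ± 0.6 mm specimen noise, clipped to
0.2–5.5 mm), producing the positive cement-to-decompression relation the
cohort statistics are meant to detect.  A null cohort (zero distraction)
supports type-I-error studies.

What the phantom does **not** emulate: anatomical surface texture and
curvature (primitives only), soft tissue around the bone, cement leakage and
irregular cement shapes, partial-volume and beam-hardening physics, DIC
correlation dropouts.  Passing tests show the measurement chain is
geometrically sound and statistically calibrated, not that it handles every
pathology of real data.

## Numerical choices

- **ICP convergence**: stop when one iteration improves the RMSE by less
  than 1e-6 mm (max 400 correspondence evaluations).  Partial lateral
  patches slide tangentially with tiny per-step gains; a looser 1e-4
  tolerance stops prematurely and costs ~0.2° / 0.2 mm of pose accuracy.
  When consecutive steps point the same way, the increment is extrapolated
  (doubled) while the *measured* RMSE keeps improving — candidates are only
  accepted on improvement, so the RMSE history stays non-increasing.
- **Coarse alignment**: centroids plus the four proper principal-axes sign
  combinations, each polished by 15 ICP iterations on a 500-point subsample
  and selected by refined RMSE (a raw distance score cannot tell a good
  basin from a nearby local minimum).  Inside the pipeline, registrations
  warm-start from the previous result of the same vertebra.
- **BPA details**: clustering is enforced by rejecting unused candidate
  points closer than the clustering radius to the pivot edge's endpoints;
  the final-pass superposition guard rejects candidates that fold flat onto
  the front triangle on the same side; boundary edges of one radius pass are
  re-tried at the next radius.
- **Ties and degeneracies**: Wilcoxon drops zero differences, mid-ranks
  ties, and switches from exact sign-pattern enumeration to the
  continuity-and-tie-corrected normal approximation above n = 15; Dice of
  two empty masks is defined as 1; an all-zero difference vector returns
  p = 1 with a warning; a constant rater table raises (ICC undefined).
- **Problem sizes**: the test suite and the acceptance script run the
  full-resolution chain on single specimens and a 10-specimen cohort
  (flexion arm) with registration on 2000-point subsamples and measurement
  slices of 0.2 mm; the type-I calibration uses 1000 simulated measurement
  tables rather than 1000 full pipeline runs.  These sizes keep a complete
  run on one CPU in minutes while leaving every stage of the chain in play.

## Known limitations

- Binary-HU voxelization caps achievable dV accuracy at roughly 1–2% for
  clinically-sized distractions; specimens with sub-millimetre distraction
  have dV below the discretization floor.
- The exact volume path assumes watertight inputs; non-watertight meshes
  must use (or fall back to) the voxel path.
- Principal-axes initialization can be ambiguous for near-symmetric
  geometry; the polish step mitigates but cannot guarantee the global
  basin for arbitrary inputs.
- The measurement cylinder radius remains a configuration input (with a
  heuristic suggestion based on axis-to-bone clearance); "entirely filling"
  a foramen is not an algorithmic criterion.
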