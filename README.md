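# foramenvol

Measuring how much percutaneous cement discoplasty (PCD) decompresses the
neuroforamen of a loaded spine segment.

PCD fills a severely degenerated intervertebral disc with acrylic bone
cement; the hardened cement acts as a spacer that restores disc height and
indirectly widens the bony tunnel (the neuroforamen) through which spinal
nerves exit.  `foramenvol` implements the complete geometric measurement
chain used to quantify that effect ex vivo: surface points acquired
optically (digital image correlation, DIC) on the loaded specimen are
reconstructed into meshes, rigidly registered onto CT-derived vertebra
geometry, composed into the loaded pose, and the free foraminal volume is
measured by cylinder subtraction,

    V = volume(cylinder) − volume(cylinder ∩ (caudal ∪ cranial)),
    dV = V_discoplasty − V_nucleotomy,

with one 90-mm measurement cylinder per specimen × motion aligned with the
transverse axis of both foramina and a radius shared across the two disc
conditions.  Cohort effects are tested with a paired Wilcoxon signed-rank
test, cement-volume/dV correlation with Spearman's rank test, and rater
repeatability with two-way absolute-agreement ICC (A,1 and A,k) with 95%
confidence intervals.

The package is aimed at spine-biomechanics groups who have (a) DIC-like
surface point clouds of a loaded specimen and (b) a CT scan of the same
specimen, and want a scripted, reproducible alternative to interactive
mesh-processing GUIs.  Because real cadaveric inputs cannot ship with the
code, a synthetic spine-phantom generator with exact ground truth (known
poses, known foramen geometry, CT-like images, DIC-like noisy patches)
makes every stage testable end to end.

## What is in the box

| module                      | role |
|-----------------------------|------|
| `foramenvol.mesh`           | point clouds, normal estimation, ball-pivoting reconstruction, mesh volume, exact point-to-surface distances, planar sections |
| `foramenvol.phantom`        | synthetic FSU generator: geometry, true poses, DIC-like patches, CT-like images |
| `foramenvol.segmentation`   | HU thresholding (> 700 HU), cement/bone band separation, vertebra splitting, marching-cubes iso-surfaces |
| `foramenvol.registration`   | rigid transforms, Kabsch landmark alignment, point-to-surface ICP, caudal-anchored pose composition |
| `foramenvol.volumetry`      | measurement cylinder, exact (slice-Boolean) and voxel free-volume back-ends, per-specimen dV |
| `foramenvol.quality`        | Dice, Metro-style Hausdorff summaries, percentile criteria, outlier flagging, registration RMSE |
| `foramenvol.stats`          | paired Wilcoxon (exact ≤ 15), Spearman, ICC(A,1)/ICC(A,k) with CIs, cohort reports |
| `foramenvol.pipeline`       | end-to-end specimen/cohort orchestration, manifests, determinism hashes |
| `foramenvol.cli`            | `foramenvol simulate / run / measure / evaluate / cohort` |

## Worked example

Measure one synthetic specimen through the full chain (CT emulation →
segmentation → registration of DIC-like patches → cylinder volumetry):

```python
from foramenvol import PhantomParams, generate_fsu
from foramenvol.pipeline import PipelineConfig, run_phantom_specimen

specimen = generate_fsu(PhantomParams(distraction_discoplasty=3.0, seed=7))
result = run_phantom_specimen(
    specimen, seed=42, config=PipelineConfig(reconstruct=False)
)
for motion, m in result.measurements.items():
    truth = specimen.ground_truth_measurement(motion)
    print(f"{motion:9s}  V_nucleotomy = {m.v_nucleotomy:8.1f} mm^3   "
          f"V_discoplasty = {m.v_discoplasty:8.1f} mm^3   "
          f"dV = {m.delta_v:6.1f} mm^3  (truth {truth.delta_v:6.1f})")
rmse = max(r.rmse for r in result.registrations.values())
print(f"worst registration RMSE = {rmse:.3f} mm")
```

prints

```
flexion    V_nucleotomy =  17292.7 mm^3   V_discoplasty =  17795.2 mm^3   dV =  502.5 mm^3  (truth  504.3)
extension  V_nucleotomy =  15945.7 mm^3   V_discoplasty =  17140.3 mm^3   dV = 1194.6 mm^3  (truth 1195.2)
worst registration RMSE = 0.036 mm
```

The 3-mm cement-spacer distraction frees about 0.5 cm³ of foraminal space in
flexion and about 1.2 cm³ in extension for this phantom — extension
decompresses more because the posterior gap is the one the cylinder probes —
and the pipeline recovers both within a few mm³ of the known truth.  The
registration RMSE (distance of the registered surface points to the
CT-derived surface) is far below the voxel size, i.e. the rigid-body
alignment is limited by the CT resolution, not by the optimizer.

`docs/methods.md` describes the model, the two volume back-ends, the
phantom's realism envelope and all numerical conventions.

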