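# condyseg

Semi-automatic, region-growing-based segmentation of mandibular condyles from
cone-beam CT (CBCT) volumes, as a scriptable Python library and CLI — together
with the validation metrics used in clinical rater studies (Dice overlap,
surface distance maps, intraclass correlation) and a synthetic CBCT condyle
phantom generator with simulated observers, so the entire protocol can be
exercised and validated without patient data.

## Why

The condyle — the articulating head of the mandible in the temporomandibular
joint — is notoriously hard to segment from CBCT: bone density is low,
Hounsfield units are unreliable, partial-volume blur softens the cortical
boundary, and the adjacent glenoid fossa produces spurious bright connections
in thresholded masks. Accurate 3D condylar morphometry matters clinically for
distinguishing progressive condylar resorption from physiological remodelling
after orthognathic surgery.

## The protocol

1. **VOI selection.** Segmentation runs inside a small volume of interest
   around one condyle.
2. **Sparse annotation.** On every ~5th slice along one anatomical axis, an
   observer places a seed point inside the condyle and tunes an intensity
   threshold until the 2D region-growing outline (`grow_2d`, 8-connected,
   inclusive lower bound) fits the cortical boundary.
3. **Threshold interpolation.** Thresholds on unannotated slices are obtained
   by piecewise-linear interpolation in slice index
   (`interpolate_thresholds`), with constant extrapolation outside the
   annotated range — a *local* threshold profile that tracks the intensity
   inhomogeneity of CBCT.
4. **3D region growing.** `grow_3d` returns the 6-connected component of all
   voxels passing their own slice's local threshold, grown from the central
   seed point.
5. **Post-processing.** Optional per-slice corrections (add/replace), then
   morphological opening with a 3×3×3 element to sever thin condyle–fossa
   bridges, then retention of the seed's connected component.
6. **Surface and metrics.** Marching-cubes surface extraction with Taubin
   smoothing; Dice `D = 2|A∩B|/(|A|+|B|)` between masks; symmetric
   closest-point surface-distance maps summarised by median / 90th
   percentile / range; two-way absolute-agreement ICC(A,1) over a
   subjects × raters volume table.

## Worked example

```python
import condyseg as cs

spec = cs.PhantomSpec(rng_seed=7)            # 88x72x64 voxels at 0.4 mm
volume, truth = cs.generate_phantom(spec)

observer = cs.ObserverParams(rng_seed=1)     # seeds + thresholds every 5th slice
annotations = cs.simulate_observer(volume, truth, observer)
print("annotated slices :", annotations.slice_indices)

mask, log = cs.run_protocol(volume, annotations)
print("stage voxel counts:", [(s["stage"], s["voxels"]) for s in log.stages])
print(f"condylar volume   : {cs.mask_volume_mm3(mask):.1f} mm^3")
print(f"Dice vs truth     : {cs.dice(mask, truth):.4f}")

summary = cs.surface_distance(cs.extract_surface(mask), cs.extract_surface(truth))
print(f"surface distance  : median {summary.median:.3f} mm, p90 {summary.p90:.3f} mm")
```

prints

```
annotated slices : [16, 21, 26, 31, 36, 41, 46, 51, 56, 61, 66]
stage voxel counts: [('grow_3d', 30289), ('opening', 30096), ('keep_seed_component', 30096)]
condylar volume   : 1926.1 mm^3
Dice vs truth     : 0.9928
surface distance  : median 0.007 mm, p90 0.126 mm
```

The simulated observer annotated 11 of the condyle's ~55 slices; the full 3D
growth captured a ~1926 mm³ condyle (ground truth 1942 mm³); the opening
removed the 193 voxels belonging to fossa bridges; the final mask overlaps
the ground truth with Dice 0.993 and a median surface error of 0.007 mm —
far below the 0.4 mm voxel size.

The same pipeline is available from the shell:

```bash
condyseg phantom --seed 7 --out-volume vol.nii.gz --out-truth truth.raw
condyseg simulate-observer --volume vol.nii.gz --truth truth.raw --seed 1 --out ann.json
condyseg segment --volume vol.nii.gz --annotations ann.json --out seg.raw
condyseg postprocess --mask seg.raw --open cube:3 --out seg_open.raw
condyseg metrics dice --a seg_open.raw --b truth.raw
condyseg bench --n 10 --seed 1 --report report.csv
```

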