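# Methods

## Segmentation model

The segmentation criterion is a per-slice inclusive intensity lower bound.
An observer fixes (seed, threshold) pairs on a sparse subset of slices along
one anatomical axis; every other slice in the VOI receives a threshold by
piecewise-linear interpolation in slice index, with nearest-endpoint
(constant) extrapolation outside the annotated range. Linear interpolation is
the lowest-order scheme that reproduces the annotated values exactly and
cannot overshoot between annotations; higher-order interpolants were rejected
because threshold overshoot translates directly into boundary drift in the
mask.

The 3D result is the connected component, containing the central seed voxel,
of the admissible set `{v in VOI : I(v) >= t(slice(v))}`. Connectivity is
6-connected by default: the condyle–fossa joint space is often only one to
two voxels wide after partial-volume blur, and diagonal (26) adjacency lets
the growth leak through checkerboard configurations across that gap. 26 is
available for compact, well-separated structures. In-plane (2D) growing is
8-connected, matching the behaviour an observer expects of an interactive
outline tool.

"Central seed point" is the seed of the annotation closest to the median
annotated slice (ties to the lower index), overridable via `central_index`.
The median is preferred over the midpoint of the VOI because annotations
cluster on structure-containing slices.

Thresholds have no upper bound: condylar bone is the brightest local tissue,
and a single adjustable lower bound per slice is the clinically practised
control.

## Post-processing

Pipeline order is fixed: slice corrections → morphological opening →
seed-component retention. Corrections are exact single-slice edits (OR or
replace); opening uses a 3×3×3 cube by default — "size three" interpreted as
edge length, with cross and ball variants exposed — and treats everything
outside the grid as background, so masks shrink at VOI borders rather than
hallucinate support there. Opening is last-but-one because its purpose is to
sever the thin condyle–fossa bridges that survive growing and correction;
the subsequent component selection then discards the disconnected fossa
remnant. If the opening erodes the central seed voxel itself (never observed
on condyle-scale masks; possible for pathological thin shapes) the largest
component is kept and the run log records the substitution.

## Surfaces and metrics

Meshes are 0.5-level marching-cubes iso-surfaces of the 0/1 grid, in mm
coordinates (`index·spacing + origin`), after padding the mask with one
background layer so surfaces close at VOI borders. Optional smoothing is
Taubin's low-shrinkage two-pass filter (λ=0.5, ν=0.53, default 10
iterations), which changes enclosed volume by well under 1% on condyle-sized
shapes (asserted <2% in tests); all compared meshes must use identical
smoothing settings, since smoothing is a shared systematic, not noise.

Surface distance maps sample each mesh's vertices plus area-uniform face
samples at a configurable density (default 1 point/mm² for the CLI, 0.5 in
the benchmark — vertices dominate at marching-cubes resolution), and compute
each point's exact distance to the closest point on any triangle of the
other mesh. The implementation prunes candidate triangles with a KD-tree
bound (nearest-vertex distance plus the maximal triangle circumradius) and
evaluates exact point–triangle distances on the survivors, so results are
identical to exhaustive search. Symmetric mode pools both directed distance
sets before summarising; summaries are median, 90th percentile (linear
interpolation between order statistics — p90 of {1..10} is 9.1), min and
max.

Dice is computed on voxel masks, not meshes. The ICC is the single-measures
two-way absolute-agreement coefficient

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

from the two-way layout without replication; for absolute agreement the
mixed/random distinction does not change the value, so one formula serves
both conventions.

## The synthetic phantom

`generate_phantom` emulates the imaging situation, not CBCT physics. The
condyle is an ellipsoidal head (default semi-axes 8×10×5 mm, volume
≈ 1676 mm³ — the scale of adult condyles) with a cylindrical neck (radius
3.5 mm) extending 6 mm past the head's lower pole, spanning ~40 axial slices
at 0.4 mm isotropic voxels (~55 with the neck). A fossa-like bright shell
sits above the head at a 1.2 mm joint gap (thickness 1.6 mm), and by default
two single-voxel bright bridges cross the gap — the artifact the
morphological opening exists to remove. Intensities are two-level (soft
tissue 60, bone 160, arbitrary units) plus:

* **axial linear drift**, 0.5 units/slice (±~14 units over the condyle) —
  the minimal inhomogeneity under which local thresholds measurably beat the
  best single global threshold (asserted in a test);
* **partial-volume blur**, Gaussian σ = 0.3 mm;
* **additive Gaussian noise**, SD 10 (10% of the bone–soft contrast).

Noise and drift magnitudes are package assumptions, chosen so that slicewise
optimal thresholds vary by several units and mask boundaries move by ~1
voxel between observers; they are exposed in `PhantomSpec` and documented
here rather than hidden. Everything is deterministic given `rng_seed`.

**What the phantom does not model:** scatter, beam hardening, motion
artifacts, cone-beam peripheral noise gradients, trabecular texture, the
articular disc, and real condylar shape variation. Passing the phantom suite
shows the *protocol and code* are correct and stable under the modelled
degradations; it does not certify accuracy on patient anatomy, where
observer judgment of a blurred cortical boundary is the dominant error
source.

## Simulated observers

`simulate_observer` automates the human loop: every 5th structure-containing
slice is annotated; the seed is the in-plane centroid of the true region
snapped onto it (±1 voxel uniform jitter, kept inside the structure); the
threshold is the grid value (default grid 70–150 in steps of 2) whose 2D
region growing maximises in-plane Dice against the true outline, ties broken
toward the lower threshold (observers trace the outer cortical boundary),
then perturbed by Gaussian noise (SD 2 units) truncated so the seed stays
admissible. Two observers differ only in their random streams; observer
randomness is separated from phantom randomness so observers can be varied
on a fixed phantom.

## The benchmark experiment

`run_benchmark` is the desk-scale analog of a two-rater validation study:
10 phantoms, 2 simulated observers each, full protocol per observer. A
per-phantom size factor (normal, SD 7%, clipped to [0.82, 1.18]) scales head
and neck, giving the volume table a ~20% coefficient of variation — the
between-subject spread of adult condylar volumes — without which a rater ICC
would be meaningless. Reported summaries: min/mean inter-observer Dice,
minimum Dice against ground truth, ICC(A,1) of the 10×2 volume table, paired
volume differences, and surface-distance summaries observer-vs-truth and
observer-vs-observer. The 10-phantom, 88×72×64-voxel problem size keeps a
full benchmark run in seconds on one CPU while leaving every statistic
well-conditioned.

## Numerical and convention choices

* Indexing 0-based; VOI half-open `[lo, hi)`; axis 0 = axial, 1 = coronal,
  2 = sagittal, stored explicitly.
* Raw mask export: uint8 0/1, C order, little-endian, mandatory JSON sidecar
  (shape, dtype, spacing, origin, order) — self-describing so round-trips
  are exact.
* DICOM intensities are used after slope/intercept only; no HU calibration
  (absolute HU is unreliable in cone-beam CT). Slice spacing must be
  consistent within 1%.
* Marching-cubes iso-level fixed at 0.5; winding fixed so enclosed volume is
  positive. The iso-surface of an isolated voxel is the octahedron through
  half-voxel edge midpoints (area √3·s²), not a voxel cube — a property of
  every marching-cubes extractor.
* All configs are versioned JSON; unknown keys are errors.

## Known limitations

* One annotation axis per 3D run; thresholds chosen on different axes cannot
  be mixed in a single growth (per-slice corrections on any axis can follow).
* No automatic seed or threshold selection for real data — the simulated
  observer needs a ground truth and exists for validation only.
* No resampling or registration; volumes are processed on their native grid.
* The ICC denominator is zero for tables with no between-subject variance
  (for example a 2×2 anti-symmetric table); such degenerate inputs are the
  caller's responsibility and the Monte-Carlo test covers only realistic
  volume tables.
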