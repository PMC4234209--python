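"""Synthetic CBCT condyle phantoms and simulated observers.

The phantom emulates the imaging situation the segmentation protocol was
designed for, at 0.4 mm isotropic voxels: a bright condyle-like solid
(ellipsoidal head plus cylindrical neck) sitting below a fossa-like bright
shell, separated by a thin dark joint gap that may be crossed by a few
single-voxel bright bridges; a linear intensity drift along the axial axis
(the inhomogeneity that makes *local* thresholds pay off); Gaussian
partial-volume blur; and additive Gaussian noise. Everything is deterministic
given the spec's ``rng_seed``.

The simulated observer automates the human loop: it seeds every
``annotation_spacing``-th slice that contains the structure, searches a
threshold grid for the best in-plane region-growing fit, and perturbs both
seed and threshold to emulate inter-observer variability. Two observers with
different seeds on the same phantom stand in for the two-rater study design.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .postprocess import (
    SliceCorrection,
    StructuringElement,
    apply_correction,
    keep_seed_component,
    morphological_open,
)
from .segmentation import (
    AnnotationSet,
    SliceAnnotation,
    grow_2d,
    grow_3d,
    interpolate_thresholds,
)
from .volume_io import VOI, BinaryMask, ImageVolume

__all__ = [
    "PhantomSpec",
    "ObserverParams",
    "PipelineConfig",
    "RunLog",
    "generate_phantom",
    "simulate_observer",
    "run_protocol",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise model of one synthetic condyle phantom.

    Defaults give a head volume of ``4/3·π·8·10·5 ≈ 1676 mm³`` — the scale of
    adult condyles — spanning ~40 axial slices at 0.4 mm voxels, with the neck
    extending the structure to ~55 slices.
    """

    shape: tuple[int, int, int] = (88, 72, 64)
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4)
    head_semiaxes: tuple[float, float, float] = (8.0, 10.0, 5.0)  # mm, (axial, cor, sag)
    neck_radius: float = 3.5  # mm
    neck_length: float = 6.0  # mm beyond the head's lower pole
    fossa_gap: float = 1.2  # mm joint space between head and fossa shell
    fossa_thickness: float = 1.6  # mm radial thickness of the fossa shell
    n_bridges: int = 2  # single-voxel bright condyle-fossa connections
    bone_intensity: float = 160.0
    soft_intensity: float = 60.0
    drift_per_slice: float = 0.5  # intensity units per axial slice
    psf_sigma: float = 0.3  # mm, partial-volume blur
    noise_sd: float = 10.0  # intensity units
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.head_semiaxes) <= 0 or self.neck_radius <= 0 or self.neck_length <= 0:
            raise ValueError("geometric parameters must be positive")
        if self.fossa_gap <= 0 or self.fossa_thickness <= 0:
            raise ValueError("fossa gap and thickness must be positive")
        if self.psf_sigma < 0 or self.noise_sd < 0:
            raise ValueError("psf_sigma and noise_sd must be >= 0")
        if self.n_bridges < 0:
            raise ValueError("n_bridges must be >= 0")


@dataclass(frozen=True)
class ObserverParams:
    """Behaviour of one simulated observer annotating a phantom."""

    annotation_spacing: int = 5  # annotate every 5th structure slice
    seed_jitter: int = 1  # max in-plane seed displacement, voxels
    threshold_noise_sd: float = 2.0  # intensity units added to the chosen threshold
    threshold_grid: tuple[float, float, float] = (70.0, 150.0, 2.0)  # (min, max, step)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.annotation_spacing < 1:
            raise ValueError("annotation_spacing must be >= 1")
        if self.seed_jitter < 0:
            raise ValueError("seed_jitter must be >= 0")
        if self.threshold_grid[2] <= 0:
            raise ValueError("threshold grid step must be > 0")


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def _mm_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, BinaryMask]:
    """Generate one phantom volume and its ground-truth condyle mask.

    The ground truth is the voxelisation of head ∪ neck; the fossa shell and
    any bridges are bright in the image but excluded from the truth.
    """
    n0, n1, n2 = spec.shape
    s0, s1, s2 = spec.spacing
    a0, a1, a2 = spec.head_semiaxes

    # head centre: axial placed so fossa (above) and neck (below) both fit
    c0 = 0.40 * n0 * s0
    c1 = 0.5 * (n1 - 1) * s1
    c2 = 0.5 * (n2 - 1) * s2

    margin_mm = 3 * max(spec.spacing)
    top_extent = a0 + spec.fossa_gap + spec.fossa_thickness
    if (
        c0 - top_extent < margin_mm
        or c0 + a0 + spec.neck_length > (n0 - 1) * s0 - margin_mm
        or c1 - a1 < margin_mm
        or c1 + a1 > (n1 - 1) * s1 - margin_mm
        or c2 - a2 < margin_mm
        or c2 + a2 > (n2 - 1) * s2 - margin_mm
    ):
        raise ValueError("phantom geometry does not fit inside the grid with a 3-voxel margin")

    g0, g1, g2 = _mm_grids(spec.shape, spec.spacing)
    head = (
        ((g0 - c0) / a0) ** 2 + ((g1 - c1) / a1) ** 2 + ((g2 - c2) / a2) ** 2
    ) <= 1.0
    in_plane_r2 = (g1 - c1) ** 2 + (g2 - c2) ** 2
    neck = (
        (in_plane_r2 <= spec.neck_radius**2)
        & (g0 >= c0)
        & (g0 <= c0 + a0 + spec.neck_length)
    )
    truth = head | neck

    # fossa: a shell at distance (gap, gap+thickness] from the head, above it
    dist_to_truth = ndimage.distance_transform_edt(~truth, sampling=spec.spacing)
    shell = (dist_to_truth > spec.fossa_gap) & (
        dist_to_truth <= spec.fossa_gap + spec.fossa_thickness
    )
    fossa = shell & (g0 < c0 - 0.25 * a0)

    rng = np.random.default_rng(spec.rng_seed)

    # bridges: single-voxel columns spanning the gap between head top and fossa
    bridges = np.zeros(spec.shape, dtype=bool)
    if spec.n_bridges > 0:
        candidates = []
        for j in range(n1):
            for k in range(n2):
                col_truth = np.flatnonzero(truth[:, j, k])
                col_fossa = np.flatnonzero(fossa[:, j, k])
                if col_truth.size == 0 or col_fossa.size == 0:
                    continue
                top = col_truth[0]  # head's upper pole along this column
                below = col_fossa[col_fossa < top]
                if below.size == 0:
                    continue
                gap_len = top - below[-1] - 1
                if 1 <= gap_len <= int(np.ceil(spec.fossa_gap / s0)) + 2:
                    candidates.append((j, k, below[-1] + 1, top))
        if candidates:
            picks = rng.choice(len(candidates), size=min(spec.n_bridges, len(candidates)), replace=False)
            for p in np.atleast_1d(picks):
                j, k, lo, hi = candidates[int(p)]
                bridges[lo:hi, j, k] = True

    image = np.full(spec.shape, spec.soft_intensity, dtype=np.float64)
    image[truth | fossa | bridges] = spec.bone_intensity
    if spec.drift_per_slice != 0:
        image += spec.drift_per_slice * (np.arange(n0) - n0 / 2.0)[:, None, None]
    if spec.psf_sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=[spec.psf_sigma / s for s in spec.spacing])
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=spec.shape)

    volume = ImageVolume(data=image, spacing=spec.spacing)
    return volume, BinaryMask(data=truth, spacing=spec.spacing)


# ---------------------------------------------------------------------------
# simulated observer
# ---------------------------------------------------------------------------

def _slice_dice(a: np.ndarray, b: np.ndarray) -> float:
    total = int(a.sum()) + int(b.sum())
    return 2.0 * int((a & b).sum()) / total if total else 0.0


def _take_slice(data: np.ndarray, axis: int, index: int) -> np.ndarray:
    sl = [slice(None)] * 3
    sl[axis] = index
    return data[tuple(sl)]


def simulate_observer(
    volume: ImageVolume,
    truth: BinaryMask,
    params: ObserverParams = ObserverParams(),
    axis: int = 0,
    voi_margin: int = 5,
) -> AnnotationSet:
    """Produce the annotation set a human observer would generate.

    Every ``annotation_spacing``-th slice containing the structure is
    annotated: the seed is the in-plane centroid of the true region (snapped
    onto it, then jittered within the structure), and the threshold is the
    grid value whose in-plane region growing best matches the true outline by
    Dice (ties to the lowest threshold — observers trace the outer cortical
    boundary), perturbed by truncated Gaussian noise so the seed stays
    admissible.
    """
    rng = np.random.default_rng(params.rng_seed)
    structure_slices = np.flatnonzero(truth.data.any(axis=tuple(a for a in (0, 1, 2) if a != axis)))
    if structure_slices.size == 0:
        raise ValueError("ground truth is empty along the annotation axis")

    # VOI: structure bounding box padded in every direction
    lo, hi = [], []
    for ax in range(3):
        occupied = np.flatnonzero(truth.data.any(axis=tuple(a for a in (0, 1, 2) if a != ax)))
        lo.append(max(0, occupied[0] - voi_margin))
        hi.append(min(volume.shape[ax], occupied[-1] + 1 + voi_margin))
    voi = VOI(tuple(lo), tuple(hi))

    t_min, t_max, t_step = params.threshold_grid
    grid = np.arange(t_min, t_max + 0.5 * t_step, t_step)

    annotations: list[SliceAnnotation] = []
    for s in structure_slices[:: params.annotation_spacing]:
        truth2d = _take_slice(truth.data, axis, int(s))
        img2d = _take_slice(volume.data, axis, int(s))
        coords = np.argwhere(truth2d)
        centroid = coords.mean(axis=0)
        seed = tuple(coords[np.argmin(((coords - centroid) ** 2).sum(axis=1))])
        if params.seed_jitter > 0:
            jitter = rng.integers(-params.seed_jitter, params.seed_jitter + 1, size=2)
            cand = np.asarray(seed) + jitter
            # stay inside the structure: snap back to the nearest true voxel
            seed = tuple(coords[np.argmin(((coords - cand) ** 2).sum(axis=1))])

        seed_intensity = img2d[seed]
        admissible = grid[grid <= seed_intensity]
        if admissible.size == 0:
            raise ValueError(
                f"slice {s}: seed intensity {seed_intensity:.1f} is below the "
                f"threshold grid minimum {t_min}"
            )
        best_t, best_d = None, -1.0
        for t in admissible:
            d = _slice_dice(grow_2d(img2d, seed, float(t)), truth2d)
            if d > best_d:  # strict: ties keep the lowest threshold
                best_t, best_d = float(t), d
        if params.threshold_noise_sd > 0:
            best_t += float(rng.normal(0.0, params.threshold_noise_sd))
            best_t = min(best_t, float(seed_intensity))  # seed stays admissible
        annotations.append(SliceAnnotation(int(s), seed, best_t))

    return AnnotationSet(axis=axis, annotations=annotations, voi=voi)


# ---------------------------------------------------------------------------
# full protocol
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Options for one end-to-end protocol run."""

    corrections: list[SliceCorrection] = field(default_factory=list)
    opening: StructuringElement | None = StructuringElement("cube", 3)
    keep_seed: bool = True
    connectivity: int | None = None  # None: use the annotation set's setting


@dataclass
class RunLog:
    """Per-stage record of one protocol run, in execution order."""

    stages: list[dict] = field(default_factory=list)
    thresholds: dict[int, float] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    version: str = ""

    def add_stage(self, name: str, mask: BinaryMask, t0: float) -> None:
        self.stages.append(
            {"stage": name, "voxels": mask.count(), "seconds": round(time.perf_counter() - t0, 4)}
        )


def run_protocol(
    volume: ImageVolume,
    annotations: AnnotationSet,
    config: PipelineConfig | None = None,
) -> tuple[BinaryMask, RunLog]:
    """Run the full segmentation protocol in its fixed order.

    3D region growing under interpolated local thresholds, then slice
    corrections, then morphological opening, then retention of the seed's
    connected component. Deterministic: identical inputs give bit-identical
    masks.
    """
    from . import __version__

    if config is None:
        config = PipelineConfig()
    log = RunLog(version=__version__)
    profile = interpolate_thresholds(annotations)
    log.thresholds = {
        int(i): float(v)
        for i, v in zip(range(profile.start, profile.start + len(profile.values)), profile.values)
    }
    log.config = {
        "opening": None if config.opening is None else f"{config.opening.shape}:{config.opening.size}",
        "keep_seed": config.keep_seed,
        "connectivity": config.connectivity or annotations.connectivity,
        "n_corrections": len(config.corrections),
    }

    t0 = time.perf_counter()
    mask = grow_3d(volume, annotations, connectivity=config.connectivity)
    log.add_stage("grow_3d", mask, t0)

    for corr in config.corrections:
        t0 = time.perf_counter()
        mask = apply_correction(mask, corr)
        log.add_stage(f"correction[{corr.mode}@axis{corr.axis}:{corr.slice_index}]", mask, t0)

    if config.opening is not None:
        t0 = time.perf_counter()
        mask = morphological_open(mask, config.opening)
        log.add_stage("opening", mask, t0)

    if config.keep_seed:
        t0 = time.perf_counter()
        seed = annotations.central_voxel()
        if mask.data[seed]:
            mask = keep_seed_component(
                mask, seed, connectivity=config.connectivity or annotations.connectivity
            )
            log.add_stage("keep_seed_component", mask, t0)
        else:
            # the opening eroded the seed voxel itself: keep the largest component
            structure = ndimage.generate_binary_structure(
                3, 1 if (config.connectivity or annotations.connectivity) == 6 else 3
            )
            labels, n = ndimage.label(mask.data, structure=structure)
            if n > 0:
                sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
                mask = BinaryMask(
                    data=labels == (1 + int(np.argmax(sizes))),
                    spacing=mask.spacing,
                    origin=mask.origin,
                )
            log.add_stage("keep_largest_component(seed eroded)", mask, t0)

    return mask, log
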