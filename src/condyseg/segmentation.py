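"""Seeded region growing with locally varying, interpolated thresholds.

The segmentation protocol works on a volume of interest (VOI) around one
condyle. An observer places a seed point and chooses an intensity threshold on
a subset of slices (every fifth slice is the recommended cadence) along one
anatomical axis. Thresholds on unannotated slices are obtained by piecewise
linear interpolation in slice index, so the inclusion criterion adapts to the
slow intensity drift typical of cone-beam CT. A 3D connected-component region
growing, started from the central seed point, then returns every voxel that is
connected to the seed through voxels passing their own slice's local
threshold.

Thresholds are inclusive lower bounds: condylar bone is brighter than the
surrounding soft tissue, and the protocol uses a single adjustable threshold
per slice with no upper bound. In-plane growing is 8-connected; 3D growing is
6-connected by default (diagonal adjacency would let the segmentation leak
across the thin condyle-fossa gap) and can be switched to 26.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import AXIS_BY_NAME, BinaryMask, ImageVolume, VOI

__all__ = [
    "SliceAnnotation",
    "AnnotationSet",
    "ThresholdProfile",
    "grow_2d",
    "trace_outline",
    "interpolate_thresholds",
    "grow_3d",
]

_STRUCT_2D_8 = np.ones((3, 3), dtype=bool)


def _structure_3d(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"3D connectivity must be 6 or 26, got {connectivity}")


@dataclass(frozen=True)
class SliceAnnotation:
    """One observer input: a seed point and threshold on a single slice."""

    slice_index: int
    seed: tuple[int, int]  # in-plane (row, col) voxel indices
    threshold: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "slice_index", int(self.slice_index))
        object.__setattr__(self, "seed", tuple(int(v) for v in self.seed))
        object.__setattr__(self, "threshold", float(self.threshold))


@dataclass
class AnnotationSet:
    """Ordered per-slice annotations along one axis, plus the VOI.

    ``central_index`` selects the annotation whose seed starts the 3D growth;
    when ``None`` the annotation closest to the median annotated slice is used
    (ties broken toward the lower slice index).
    """

    axis: int | str
    annotations: list[SliceAnnotation]
    voi: VOI
    central_index: int | None = None
    connectivity: int = 6

    def __post_init__(self) -> None:
        if isinstance(self.axis, str):
            try:
                self.axis = AXIS_BY_NAME[self.axis]
            except KeyError:
                raise ValueError(f"unknown axis name {self.axis!r}") from None
        self.axis = int(self.axis)
        if self.axis not in (0, 1, 2):
            raise ValueError(f"axis must be 0, 1 or 2, got {self.axis}")
        if not self.annotations:
            raise ValueError("AnnotationSet needs at least one annotation")
        idx = [a.slice_index for a in self.annotations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"slice indices must be strictly increasing, got {idx}")
        lo, hi = self.voi.lo[self.axis], self.voi.hi[self.axis]
        if idx[0] < lo or idx[-1] >= hi:
            raise ValueError(
                f"annotated slices {idx[0]}..{idx[-1]} fall outside VOI range [{lo},{hi})"
            )
        if self.central_index is not None:
            self.central_index = int(self.central_index)
            if not 0 <= self.central_index < len(self.annotations):
                raise ValueError(
                    f"central_index {self.central_index} out of range for "
                    f"{len(self.annotations)} annotations"
                )
        if self.connectivity not in (6, 26):
            raise ValueError(f"connectivity must be 6 or 26, got {self.connectivity}")

    @property
    def slice_indices(self) -> list[int]:
        return [a.slice_index for a in self.annotations]

    @property
    def central_annotation(self) -> SliceAnnotation:
        if self.central_index is not None:
            return self.annotations[self.central_index]
        idx = np.asarray(self.slice_indices)
        median = np.median(idx)
        # nearest to the median slice; ties go to the lower slice index
        best = int(np.argmin(np.abs(idx - median)))
        return self.annotations[best]

    def central_voxel(self) -> tuple[int, int, int]:
        """Full-volume (i, j, k) index of the central seed voxel."""
        ann = self.central_annotation
        pos = [0, 0, 0]
        pos[self.axis] = ann.slice_index
        in_plane = [ax for ax in (0, 1, 2) if ax != self.axis]
        pos[in_plane[0]], pos[in_plane[1]] = ann.seed
        return tuple(pos)


@dataclass
class ThresholdProfile:
    """A local threshold for every slice of the VOI along the annotation axis."""

    axis: int
    start: int  # first slice index covered (VOI lo along axis)
    values: np.ndarray  # one threshold per slice, start .. start+len-1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or not np.all(np.isfinite(self.values)):
            raise ValueError("threshold profile must be a finite 1D array")

    def __getitem__(self, slice_index: int) -> float:
        i = int(slice_index) - self.start
        if not 0 <= i < len(self.values):
            raise IndexError(f"slice {slice_index} outside profile range")
        return float(self.values[i])


def grow_2d(
    slice_image: np.ndarray, seed: tuple[int, int], threshold: float
) -> np.ndarray:
    """8-connected in-plane region growing from a seed at an inclusive threshold.

    Returns the connected component of ``{slice_image >= threshold}`` that
    contains the seed, as a boolean grid of the slice's shape.

    Raises
    ------
    ValueError
        If the seed is out of bounds or its intensity falls below the
        threshold (the observer chose an invalid seed/threshold pair).
    """
    slice_image = np.asarray(slice_image)
    if slice_image.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {slice_image.shape}")
    r, c = (int(v) for v in seed)
    if not (0 <= r < slice_image.shape[0] and 0 <= c < slice_image.shape[1]):
        raise ValueError(f"seed {seed} outside slice bounds {slice_image.shape}")
    if slice_image[r, c] < threshold:
        raise ValueError(
            f"seed intensity {slice_image[r, c]} is below threshold {threshold}"
        )
    admissible = slice_image >= threshold
    labels, _ = ndimage.label(admissible, structure=_STRUCT_2D_8)
    return labels == labels[r, c]


def trace_outline(mask2d: np.ndarray) -> list[tuple[int, int]]:
    """Ordered boundary voxels of a 2D mask (the interactive outline).

    A voxel is on the boundary when it is true and has at least one false or
    out-of-grid 4-neighbour; the voxel set equals ``mask & ~erode4(mask)``.
    Voxels are ordered by walking each 8-connected boundary chain from its
    lexicographically smallest voxel.
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    if mask2d.ndim != 2:
        raise ValueError(f"expected a 2D mask, got shape {mask2d.shape}")
    if not mask2d.any():
        raise ValueError("cannot trace the outline of an empty mask")
    eroded = ndimage.binary_erosion(
        mask2d, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    boundary = mask2d & ~eroded
    labels, n = ndimage.label(boundary, structure=_STRUCT_2D_8)
    ordered: list[tuple[int, int]] = []
    offsets = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
    for lab in range(1, n + 1):
        chain = {tuple(p) for p in np.argwhere(labels == lab)}
        cur = min(chain)
        visited = {cur}
        ordered.append(cur)
        while len(visited) < len(chain):
            for dr, dc in offsets:
                nxt = (cur[0] + dr, cur[1] + dc)
                if nxt in chain and nxt not in visited:
                    cur = nxt
                    break
            else:
                # disconnected remainder within the same label cannot occur for
                # 8-connected components, but guard by jumping to the nearest
                remaining = chain - visited
                cur = min(remaining, key=lambda p: (p[0] - ordered[-1][0]) ** 2 + (p[1] - ordered[-1][1]) ** 2)
            visited.add(cur)
            ordered.append(cur)
    return ordered


def interpolate_thresholds(annotations: AnnotationSet) -> ThresholdProfile:
    """Piecewise-linear threshold profile over every VOI slice along the axis.

    Annotated slices keep their threshold exactly; slices between two
    annotations are linearly interpolated in slice index; slices outside the
    annotated range (but inside the VOI) take the nearest endpoint's value.
    """
    ax = annotations.axis
    lo, hi = annotations.voi.lo[ax], annotations.voi.hi[ax]
    xp = np.asarray(annotations.slice_indices, dtype=float)
    fp = np.asarray([a.threshold for a in annotations.annotations], dtype=float)
    values = np.interp(np.arange(lo, hi, dtype=float), xp, fp)
    return ThresholdProfile(axis=ax, start=lo, values=values)


def grow_3d(
    volume: ImageVolume,
    annotations: AnnotationSet,
    connectivity: int | None = None,
) -> BinaryMask:
    """3D connected-component region growing under local slice thresholds.

    A voxel inside the VOI is admissible when its intensity reaches the
    interpolated threshold of its slice along the annotation axis. The result
    is the connected component of the admissible set containing the central
    seed voxel, embedded in a full-shape mask (false outside the VOI).
    """
    if connectivity is None:
        connectivity = annotations.connectivity
    structure = _structure_3d(connectivity)
    voi = annotations.voi
    voi.check_within(volume.shape)
    profile = interpolate_thresholds(annotations)
    ax = annotations.axis

    sub = volume.data[voi.slices]
    thr_shape = [1, 1, 1]
    thr_shape[ax] = sub.shape[ax]
    thresholds = profile.values.reshape(thr_shape)
    admissible = sub >= thresholds

    seed = annotations.central_voxel()
    seed_local = tuple(s - l for s, l in zip(seed, voi.lo))
    if not all(0 <= s < n for s, n in zip(seed_local, sub.shape)):
        raise ValueError(f"central seed voxel {seed} lies outside the VOI")
    if not admissible[seed_local]:
        raise ValueError(
            f"central seed voxel {seed} fails its slice's local threshold"
        )

    labels, _ = ndimage.label(admissible, structure=structure)
    component = labels == labels[seed_local]

    full = np.zeros(volume.shape, dtype=bool)
    full[voi.slices] = component
    return BinaryMask(data=full, spacing=volume.spacing, origin=volume.origin)
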