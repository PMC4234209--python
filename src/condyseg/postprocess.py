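"""Slice corrections and morphological opening of a 3D segmentation.

After the 3D region growing, an observer may correct individual slices (adding
to or replacing the label on one slice along any axis) and finally open the
mask with a small structuring element to cut the thin spurious connections
between the condyle and the glenoid fossa. The fixed pipeline order is
corrections -> opening -> seed-component selection.

Erosion treats everything outside the volume as background, so masks shrink at
the VOI border; this is the conservative choice for condyles close to the VOI
edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import AXIS_BY_NAME, BinaryMask

__all__ = [
    "SliceCorrection",
    "StructuringElement",
    "apply_correction",
    "morphological_open",
    "keep_seed_component",
]


@dataclass
class SliceCorrection:
    """Replace or extend the segmentation label on one slice.

    ``mode='add'`` ORs the new label into the existing slice; ``'replace'``
    overwrites the slice. All other slices stay bit-identical.
    """

    axis: int | str
    slice_index: int
    new_label: np.ndarray
    mode: str = "add"

    def __post_init__(self) -> None:
        if isinstance(self.axis, str):
            self.axis = AXIS_BY_NAME[self.axis]
        self.axis = int(self.axis)
        self.slice_index = int(self.slice_index)
        self.new_label = np.asarray(self.new_label, dtype=bool)
        if self.new_label.ndim != 2:
            raise ValueError("correction label must be a 2D grid")
        if self.mode not in ("add", "replace"):
            raise ValueError(f"mode must be 'add' or 'replace', got {self.mode!r}")


@dataclass(frozen=True)
class StructuringElement:
    """Structuring element for binary morphology; size is edge length/diameter."""

    shape: str = "cube"
    size: int = 3

    def __post_init__(self) -> None:
        if self.shape not in ("cube", "cross", "ball"):
            raise ValueError(f"element shape must be cube, cross or ball, got {self.shape!r}")
        if self.size < 1 or self.size % 2 == 0:
            raise ValueError(f"element size must be an odd integer >= 1, got {self.size}")

    def footprint(self) -> np.ndarray:
        n, r = self.size, self.size // 2
        if self.shape == "cube":
            return np.ones((n, n, n), dtype=bool)
        grid = np.indices((n, n, n)) - r
        if self.shape == "cross":
            return (np.abs(grid) > 0).sum(axis=0) <= 1
        return (grid**2).sum(axis=0) <= r**2  # ball

    @classmethod
    def parse(cls, text: str) -> "StructuringElement":
        """Parse the CLI syntax ``shape:size``, e.g. ``cube:3``."""
        shape, _, size = text.partition(":")
        return cls(shape=shape, size=int(size or 3))


def apply_correction(mask: BinaryMask, correction: SliceCorrection) -> BinaryMask:
    """Apply one slice correction, returning a new mask."""
    ax, idx = correction.axis, correction.slice_index
    if not 0 <= idx < mask.shape[ax]:
        raise ValueError(f"slice {idx} out of bounds along axis {ax}")
    plane_shape = tuple(n for a, n in enumerate(mask.shape) if a != ax)
    if correction.new_label.shape != plane_shape:
        raise ValueError(
            f"correction label shape {correction.new_label.shape} does not match "
            f"in-plane shape {plane_shape} for axis {ax}"
        )
    data = mask.data.copy()
    sl = [slice(None)] * 3
    sl[ax] = idx
    sl = tuple(sl)
    if correction.mode == "add":
        data[sl] = data[sl] | correction.new_label
    else:
        data[sl] = correction.new_label
    return BinaryMask(data=data, spacing=mask.spacing, origin=mask.origin)


def morphological_open(
    mask: BinaryMask, element: StructuringElement = StructuringElement("cube", 3)
) -> BinaryMask:
    """Binary opening (erosion then dilation) with the given element.

    Removes structures thinner than the element — in this protocol the thin
    bright bridges between condyle and fossa — while leaving compact shapes
    essentially intact. Opening is anti-extensive (output is a subset of the
    input), monotone in the mask, and idempotent.
    """
    footprint = element.footprint()
    eroded = ndimage.binary_erosion(mask.data, structure=footprint, border_value=0)
    opened = ndimage.binary_dilation(eroded, structure=footprint, border_value=0)
    return BinaryMask(data=opened, spacing=mask.spacing, origin=mask.origin)


def keep_seed_component(
    mask: BinaryMask, seed: tuple[int, int, int], connectivity: int = 6
) -> BinaryMask:
    """Retain only the connected component containing the seed voxel."""
    seed = tuple(int(v) for v in seed)
    if not all(0 <= s < n for s, n in zip(seed, mask.shape)):
        raise ValueError(f"seed {seed} outside mask bounds {mask.shape}")
    if not mask.data[seed]:
        raise ValueError(f"seed voxel {seed} is not set in the mask")
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    labels, _ = ndimage.label(mask.data, structure=structure)
    return BinaryMask(
        data=labels == labels[seed], spacing=mask.spacing, origin=mask.origin
    )
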