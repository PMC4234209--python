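"""Image-volume and binary-mask I/O, VOI cropping, coordinate conventions.

Conventions
-----------
* Indexing is 0-based; a :class:`VOI` is half-open ``[lo, hi)`` per axis.
* Array axis 0 is the axial slice index, axis 1 coronal, axis 2 sagittal
  (stored explicitly in :attr:`ImageVolume.axis_roles` so volumes from other
  conventions can be remapped at load time).
* Raw mask export is one ``uint8`` byte per voxel (0/1), C order (last index
  fastest), little-endian, with a mandatory JSON sidecar recording shape,
  dtype, spacing, origin and order, so round-trips are exact and testable.
* CBCT intensities are used as stored (after the format's slope/intercept);
  no Hounsfield-unit calibration is attempted, since absolute HU values are
  unreliable in cone-beam CT.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

AXIS_ROLES = {0: "axial", 1: "coronal", 2: "sagittal"}
AXIS_BY_NAME = {v: k for k, v in AXIS_ROLES.items()}

__all__ = [
    "AXIS_ROLES",
    "AXIS_BY_NAME",
    "ImageVolume",
    "VOI",
    "BinaryMask",
    "read_volume",
    "write_mask_raw",
    "write_nifti",
    "crop_voi",
]


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with voxel spacing and origin in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_roles: dict[int, str] = field(default_factory=lambda: dict(AXIS_ROLES))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"volume data must be 3D with each dimension >= 1, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths (mm), got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class VOI:
    """Axis-aligned volume of interest, half-open ``[lo, hi)`` in array indices."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lo", tuple(int(v) for v in self.lo))
        object.__setattr__(self, "hi", tuple(int(v) for v in self.hi))
        for ax, (a, b) in enumerate(zip(self.lo, self.hi)):
            if a < 0 or a >= b:
                raise ValueError(f"VOI axis {ax}: need 0 <= lo < hi, got lo={a}, hi={b}")

    def check_within(self, shape: Sequence[int]) -> None:
        for ax, (b, n) in enumerate(zip(self.hi, shape)):
            if b > n:
                raise ValueError(f"VOI axis {ax}: hi={b} exceeds volume extent {n}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(b - a for a, b in zip(self.lo, self.hi))

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.lo, self.hi))

    @classmethod
    def full(cls, shape: Sequence[int]) -> "VOI":
        return cls((0, 0, 0), tuple(int(n) for n in shape))


@dataclass
class BinaryMask:
    """A 3D boolean grid aligned to an :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask data must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# raw uint8 + JSON sidecar dialect
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_mask_raw(mask: BinaryMask, path: str | Path) -> None:
    """Export a binary mask as a raw uint8 dataset plus JSON sidecar.

    One byte per voxel (0/1), C order, little-endian. The sidecar (written at
    ``<path>.json``) records shape, dtype, spacing, origin and element order;
    :func:`read_volume` with ``format='raw'`` inverts the export exactly.
    """
    path = Path(path)
    meta = {
        "shape": list(mask.shape),
        "dtype": "uint8",
        "byteorder": "little",
        "order": "C",
        "spacing": list(mask.spacing),
        "origin": list(mask.origin),
    }
    try:
        path.write_bytes(np.ascontiguousarray(mask.data, dtype=np.uint8).tobytes())
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    except OSError as exc:
        raise IOError(f"cannot write raw mask to {path}: {exc}") from exc


def _read_raw(path: Path) -> ImageVolume:
    if path.suffix == ".json" and path.exists():
        sidecar, data_path = path, path.with_name(path.name[: -len(".json")])
    else:
        sidecar, data_path = _sidecar_path(path), path
    if not data_path.exists():
        raise IOError(f"raw volume not found: {data_path}")
    if not sidecar.exists():
        raise IOError(f"missing JSON sidecar for raw volume: {sidecar}")
    meta = json.loads(sidecar.read_text())
    shape = tuple(meta["shape"])
    dtype = np.dtype(meta.get("dtype", "uint8"))
    if meta.get("byteorder", "little") == "little":
        dtype = dtype.newbyteorder("<")
    else:
        dtype = dtype.newbyteorder(">")
    buf = data_path.read_bytes()
    expected = int(np.prod(shape)) * dtype.itemsize
    if len(buf) != expected:
        raise IOError(
            f"raw volume {data_path}: file has {len(buf)} bytes, sidecar implies {expected}"
        )
    data = np.frombuffer(buf, dtype=dtype).reshape(shape, order=meta.get("order", "C"))
    return ImageVolume(
        data=np.array(data),
        spacing=tuple(meta.get("spacing", (0.4, 0.4, 0.4))),
        origin=tuple(meta.get("origin", (0.0, 0.0, 0.0))),
    )


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def write_nifti(volume: ImageVolume | BinaryMask, path: str | Path) -> None:
    """Write a volume or mask to NIfTI (.nii / .nii.gz); masks become uint8."""
    import nibabel as nib

    data = volume.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def _read_nifti(path: Path) -> ImageVolume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several file-format errors
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = img.get_fdata()  # applies the header scl slope/intercept only
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3D NIfTI volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(data=data, spacing=tuple(float(z) for z in zooms), origin=origin)


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _read_dicom_series(path: Path) -> ImageVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise IOError(f"no DICOM files found in {path}")
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception as exc:
            raise IOError(f"cannot read DICOM file {f}: {exc}") from exc

    def z_of(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=z_of)
    first = datasets[0]
    rows, cols = int(first.Rows), int(first.Columns)
    pr, pc = (float(v) for v in first.PixelSpacing)

    zs = [z_of(ds) for ds in datasets]
    if len(zs) > 1:
        steps = np.diff(zs)
        mean_step = float(np.mean(steps))
        if mean_step == 0:
            raise IOError(f"DICOM series {path}: slices share an identical position")
        if np.any(np.abs(steps - mean_step) > 0.01 * abs(mean_step)):
            raise IOError(
                f"DICOM series {path}: inconsistent slice spacing beyond 1% tolerance"
            )
        slice_spacing = abs(mean_step)
    else:
        slice_spacing = float(getattr(first, "SliceThickness", 1.0))

    grid = np.empty((len(datasets), rows, cols), dtype=np.float64)
    for i, ds in enumerate(datasets):
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        grid[i] = arr * slope + intercept

    origin = (0.0, 0.0, 0.0)
    if hasattr(first, "ImagePositionPatient"):
        x, y, z = (float(v) for v in first.ImagePositionPatient)
        origin = (z, y, x)  # axial index runs along patient z
    return ImageVolume(data=grid, spacing=(slice_spacing, pr, pc), origin=origin)


def read_volume(path: str | Path, format: str | None = None) -> ImageVolume:
    """Read a 3D volume from a DICOM series directory, NIfTI file, or raw+sidecar.

    Parameters
    ----------
    path
        Directory (DICOM series) or file (NIfTI ``.nii``/``.nii.gz``, or the
        raw data file / its JSON sidecar).
    format
        One of ``'dicom_series'``, ``'nifti'``, ``'raw'``; inferred from the
        path when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume path does not exist: {path}")
    if format is None:
        if path.is_dir():
            format = "dicom_series"
        elif path.name.endswith((".nii", ".nii.gz")):
            format = "nifti"
        else:
            format = "raw"
    if format in ("dicom", "dicom_series"):
        return _read_dicom_series(path)
    if format == "nifti":
        return _read_nifti(path)
    if format == "raw":
        return _read_raw(path)
    raise ValueError(f"unknown volume format: {format!r}")


def crop_voi(volume: ImageVolume, voi: VOI) -> ImageVolume:
    """Extract the sub-volume covered by a VOI; origin shifts by ``lo * spacing``."""
    voi.check_within(volume.shape)
    data = volume.data[voi.slices].copy()
    origin = tuple(
        o + a * s for o, a, s in zip(volume.origin, voi.lo, volume.spacing)
    )
    return ImageVolume(
        data=data,
        spacing=volume.spacing,
        origin=origin,
        axis_roles=dict(volume.axis_roles),
    )
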