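"""Validation statistics for segmentations: Dice, surface distance maps, ICC.

Conventions fixed here because the summary numbers depend on them:

* Dice is computed on voxel masks, not meshes: ``D = 2|A∩B| / (|A|+|B|)``.
* Distance maps are symmetric by default — closest-point distances are pooled
  over both directions; a directed mode is kept for diagnostics.
* Percentiles use linear interpolation between order statistics (the same
  convention as ``numpy.percentile`` default), so the 90th percentile of
  {1..10} is 9.1.
* The ICC is the single-measures two-way absolute-agreement coefficient
  (ICC(A,1)); for absolute agreement the mixed/random distinction does not
  change the computed value, so one formula serves both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import cKDTree

from .volume_io import BinaryMask

__all__ = [
    "DistanceSummary",
    "VolumeTable",
    "dice",
    "surface_distance",
    "icc_absolute_agreement",
    "volume_difference_stats",
]


@dataclass(frozen=True)
class DistanceSummary:
    """Median / 90th percentile / range of closest-point surface distances (mm)."""

    median: float
    p90: float
    min: float
    max: float
    n_samples: int

    def __post_init__(self) -> None:
        if not 0 <= self.min <= self.median <= self.p90 <= self.max:
            raise ValueError(
                f"inconsistent distance summary: min={self.min}, median={self.median}, "
                f"p90={self.p90}, max={self.max}"
            )


@dataclass
class VolumeTable:
    """An n_subjects x k_raters table of condylar volumes (mm^3)."""

    values: np.ndarray
    subjects: list[str] | None = None
    raters: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("volume table must be 2D (subjects x raters)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError(f"need >= 2 subjects and >= 2 raters, got {n} x {k}")
        if not np.all(self.values > 0):
            raise ValueError("all volumes must be positive")
        if self.subjects is None:
            self.subjects = [f"S{i+1}" for i in range(n)]
        if self.raters is None:
            self.raters = [f"R{j+1}" for j in range(k)]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "VolumeTable":
        return cls(df.to_numpy(dtype=float), list(map(str, df.index)), list(map(str, df.columns)))


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap coefficient ``2|A∩B| / (|A|+|B|)`` between two masks.

    Ranges from 0 (complete lack of overlap) to 1 (perfect agreement).
    Undefined — and an error — when both masks are empty.
    """
    a = a.data if isinstance(a, BinaryMask) else np.asarray(a, dtype=bool)
    b = b.data if isinstance(b, BinaryMask) else np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        raise ValueError("Dice is undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / total


def _surface_points(mesh: trimesh.Trimesh, samples_per_mm2: float, seed: int) -> np.ndarray:
    """Mesh vertices plus area-uniform face samples at the requested density."""
    pts = [np.asarray(mesh.vertices)]
    n_extra = int(np.ceil(mesh.area * samples_per_mm2))
    if n_extra > 0:
        sampled, _ = trimesh.sample.sample_surface(mesh, n_extra, seed=seed)
        pts.append(np.asarray(sampled))
    return np.vstack(pts)


def _points_to_mesh_distances(points: np.ndarray, target: trimesh.Trimesh) -> np.ndarray:
    """Exact distance from each point to the closest point on any triangle.

    A KD-tree over the target's vertices gives an upper bound ``ub`` per
    point; every triangle whose closest point could beat that bound has its
    centroid within ``ub + R`` of the point, where ``R`` is the largest
    centroid-to-vertex radius over all triangles. Exact point-triangle
    distances are then evaluated on those candidates only.
    """
    tri = np.asarray(target.triangles)  # (m, 3, 3)
    centroids = tri.mean(axis=1)
    radius = np.linalg.norm(tri - centroids[:, None, :], axis=2).max()
    ub, _ = cKDTree(np.asarray(target.vertices)).query(points)
    candidates = cKDTree(centroids).query_ball_point(points, r=ub + radius + 1e-12)

    pt_idx = np.concatenate([[i] * len(c) for i, c in enumerate(candidates)])
    tri_idx = np.concatenate([np.asarray(c, dtype=int) for c in candidates])
    closest = trimesh.triangles.closest_point(tri[tri_idx], points[pt_idx])
    pair_d = np.linalg.norm(points[pt_idx] - closest, axis=1)

    dists = np.full(len(points), np.inf)
    np.minimum.at(dists, pt_idx, pair_d)
    return dists


def _directed_distances(
    source: trimesh.Trimesh, target: trimesh.Trimesh, samples_per_mm2: float, seed: int
) -> np.ndarray:
    points = _surface_points(source, samples_per_mm2, seed)
    return _points_to_mesh_distances(points, target)


def surface_distance(
    a: trimesh.Trimesh,
    b: trimesh.Trimesh,
    mode: str = "symmetric",
    samples_per_mm2: float = 1.0,
    seed: int = 0,
    return_distances: bool = False,
) -> DistanceSummary | tuple[DistanceSummary, np.ndarray]:
    """Distance map between two surfaces, summarised by median / p90 / range.

    Points are sampled on the source surface (all vertices plus area-uniform
    face samples at ``samples_per_mm2``), and each point's distance to the
    closest point on any triangle of the other mesh is computed. In symmetric
    mode (default) the two directed point-distance sets are pooled before
    summarising, which makes the result invariant to argument order.
    """
    for name, mesh in (("a", a), ("b", b)):
        if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
            raise ValueError(f"mesh {name!r} is degenerate (no faces)")
    if mode == "directed":
        dists = _directed_distances(a, b, samples_per_mm2, seed)
    elif mode == "symmetric":
        dists = np.concatenate(
            [
                _directed_distances(a, b, samples_per_mm2, seed),
                _directed_distances(b, a, samples_per_mm2, seed),
            ]
        )
    else:
        raise ValueError(f"mode must be 'directed' or 'symmetric', got {mode!r}")
    summary = DistanceSummary(
        median=float(np.median(dists)),
        p90=float(np.percentile(dists, 90)),  # linear-interpolation percentile
        min=float(dists.min()),
        max=float(dists.max()),
        n_samples=int(len(dists)),
    )
    return (summary, dists) if return_distances else summary


def icc_absolute_agreement(table: VolumeTable | np.ndarray | pd.DataFrame) -> float:
    """Single-measures two-way ICC on absolute agreement, ICC(A,1).

    From the two-way layout without replication, with MSR the between-subject
    mean square, MSC the between-rater mean square and MSE the residual::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    An ICC of 1 means the raters' measurements agree exactly.
    """
    if isinstance(table, pd.DataFrame):
        table = VolumeTable.from_dataframe(table)
    elif not isinstance(table, VolumeTable):
        table = VolumeTable(np.asarray(table))
    x = table.values
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("ICC is undefined for a table with zero total variance")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse)))


def volume_difference_stats(a, b) -> dict[str, float]:
    """Paired volume differences: mean |a_i - b_i| and its percentage.

    The percentage of each pair is taken relative to the pairwise mean volume
    ``(a_i + b_i) / 2`` and then averaged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError(f"need two equal-length 1D lists, got {a.shape} and {b.shape}")
    diff = np.abs(a - b)
    pairwise_mean = (a + b) / 2.0
    return {
        "mean_abs_diff": float(diff.mean()),
        "mean_abs_diff_percent": float((100.0 * diff / pairwise_mean).mean()),
    }
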