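"""Shared fixtures and independent oracles for the test suite.

The oracles here (BFS flood fill, shift-based morphology, piecewise-linear
evaluation, brute-force ANOVA sums of squares) deliberately avoid the code
paths used by the implementation so that agreement is meaningful.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from condyseg import ObserverParams, PhantomSpec, run_benchmark

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

OFFSETS_2D_8 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
OFFSETS_3D_6 = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
]
OFFSETS_3D_26 = [
    (di, dj, dk)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    for dk in (-1, 0, 1)
    if (di, dj, dk) != (0, 0, 0)
]


def flood_fill_oracle(admissible: np.ndarray, seed: tuple, offsets) -> np.ndarray:
    """Brute-force BFS connected component of the admissible set from a seed."""
    admissible = np.asarray(admissible, dtype=bool)
    assert admissible[seed]
    out = np.zeros_like(admissible)
    out[seed] = True
    queue = deque([seed])
    while queue:
        cur = queue.popleft()
        for off in offsets:
            nxt = tuple(c + o for c, o in zip(cur, off))
            if all(0 <= v < n for v, n in zip(nxt, admissible.shape)):
                if admissible[nxt] and not out[nxt]:
                    out[nxt] = True
                    queue.append(nxt)
    return out


def piecewise_linear_oracle(xs, ys, x):
    """Evaluate the piecewise-linear interpolant with constant extrapolation."""
    if x <= xs[0]:
        return float(ys[0])
    if x >= xs[-1]:
        return float(ys[-1])
    for (x0, y0), (x1, y1) in zip(zip(xs, ys), zip(xs[1:], ys[1:])):
        if x0 <= x <= x1:
            return float(y0 + (y1 - y0) * (x - x0) / (x1 - x0))
    raise AssertionError("unreachable")


def _shift(mask: np.ndarray, off) -> np.ndarray:
    """``out[x] = mask[x + off]``, with out-of-grid voxels reading as False."""
    out = np.zeros_like(mask)
    src = tuple(slice(max(0, o), mask.shape[a] + min(0, o)) for a, o in enumerate(off))
    dst = tuple(slice(max(0, -o), mask.shape[a] - max(0, o)) for a, o in enumerate(off))
    out[dst] = mask[src]
    return out


def shift_morphology_oracle(mask: np.ndarray, footprint: np.ndarray, op: str) -> np.ndarray:
    """Erosion/dilation as an explicit AND/OR over shifted copies of the mask.

    ``erode(m)[x] = AND_o m[x+o]`` and ``dilate(m)[x] = OR_o m[x-o]`` over the
    footprint offsets o; out-of-grid voxels count as background in both.
    """
    mask = np.asarray(mask, dtype=bool)
    offsets = np.argwhere(footprint) - np.asarray(footprint.shape) // 2
    if op == "erode":
        acc = np.ones_like(mask)
        for off in offsets:
            acc &= _shift(mask, off)
    else:
        acc = np.zeros_like(mask)
        for off in offsets:
            acc |= _shift(mask, -off)
    return acc


def opening_oracle(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    eroded = shift_morphology_oracle(mask, footprint, "erode")
    return shift_morphology_oracle(eroded, footprint, "dilate")


def anova_icc_oracle(table: np.ndarray) -> float:
    """ICC(A,1) from explicitly looped two-way sums of squares."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    grand = table.sum() / (n * k)
    ss_rows = ss_cols = ss_total = 0.0
    for i in range(n):
        ss_rows += k * (table[i].mean() - grand) ** 2
    for j in range(k):
        ss_cols += n * (table[:, j].mean() - grand) ** 2
    for i in range(n):
        for j in range(k):
            ss_total += (table[i, j] - grand) ** 2
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def random_blob_mask(rng: np.random.Generator, shape=(16, 16, 16), level=0.52) -> np.ndarray:
    """A random smooth blob mask (thresholded filtered noise), possibly empty."""
    from scipy import ndimage

    noise = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2.0)
    return noise > np.quantile(noise, level)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

SMALL_SPEC = PhantomSpec(
    shape=(56, 48, 40),
    head_semiaxes=(4.8, 6.0, 3.5),
    neck_radius=2.5,
    neck_length=4.0,
)


@pytest.fixture
def small_spec() -> PhantomSpec:
    """A reduced condyle phantom that keeps unit tests fast."""
    return SMALL_SPEC


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140)


@pytest.fixture(scope="session")
def bench_result():
    """The scaled-down two-observer experiment: 10 phantoms, 2 observers each."""
    return run_benchmark(
        n_phantoms=10, seed=1, observer_params=ObserverParams(), samples_per_mm2=0.5
    )
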