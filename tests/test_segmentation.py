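"""Region growing, outline tracing and threshold interpolation.

Every growing result is checked against the brute-force BFS flood-fill oracle
from conftest; the interpolation against an independent piecewise-linear
evaluator.
"""

import numpy as np
import pytest
from scipy import ndimage

from condyseg import (
    VOI,
    AnnotationSet,
    ImageVolume,
    SliceAnnotation,
    grow_2d,
    grow_3d,
    interpolate_thresholds,
    trace_outline,
)
from conftest import (
    OFFSETS_2D_8,
    OFFSETS_3D_6,
    OFFSETS_3D_26,
    flood_fill_oracle,
    piecewise_linear_oracle,
)


def _single_annotation_set(volume_shape, seed3d, threshold, axis=0, connectivity=6):
    in_plane = tuple(v for a, v in enumerate(seed3d) if a != axis)
    return AnnotationSet(
        axis=axis,
        annotations=[SliceAnnotation(seed3d[axis], in_plane, threshold)],
        voi=VOI.full(volume_shape),
        connectivity=connectivity,
    )


class TestGrow2D:
    def test_constant_slice_fills_whole_plane(self):
        out = grow_2d(np.full((7, 9), 100.0), (3, 4), 50.0)
        assert out.all()

    def test_two_blocks_only_seed_block_grows(self):
        img = np.zeros((5, 5))
        img[0:2, 0:2] = 200  # block A
        img[3:5, 3:5] = 200  # block B
        out = grow_2d(img, (0, 0), 100.0)
        assert out.sum() == 4
        assert out[0:2, 0:2].all()
        oracle = flood_fill_oracle(img >= 100.0, (0, 0), OFFSETS_2D_8)
        assert np.array_equal(out, oracle)

    def test_seed_below_threshold_is_an_error(self):
        img = np.zeros((5, 5))
        img[0:2, 0:2] = 200
        with pytest.raises(ValueError, match="below threshold"):
            grow_2d(img, (0, 0), 201.0)

    def test_seed_out_of_bounds(self):
        with pytest.raises(ValueError, match="bounds"):
            grow_2d(np.ones((4, 4)), (4, 0), 0.5)

    def test_matches_flood_fill_on_random_slices(self, rng):
        for _ in range(30):
            img = ndimage.gaussian_filter(rng.normal(size=(24, 24)), 1.5)
            t = np.quantile(img, rng.uniform(0.3, 0.8))
            admissible = img >= t
            if not admissible.any():
                continue
            seed = tuple(np.argwhere(admissible)[0])
            assert np.array_equal(
                grow_2d(img, seed, t), flood_fill_oracle(admissible, seed, OFFSETS_2D_8)
            )


class TestTraceOutline:
    def test_single_voxel(self):
        m = np.zeros((3, 3), dtype=bool)
        m[1, 1] = True
        assert trace_outline(m) == [(1, 1)]

    def test_solid_block_perimeter(self):
        m = np.zeros((6, 6), dtype=bool)
        m[1:5, 1:5] = True
        outline = trace_outline(m)
        assert len(outline) == 12  # 4x4 block: 16 voxels minus 2x2 interior
        assert (2, 2) not in outline and (3, 3) not in outline

    def test_matches_erosion_difference_oracle(self, rng):
        from conftest import random_blob_mask

        blob = random_blob_mask(rng, shape=(20, 20, 1))[:, :, 0]
        if not blob.any():
            pytest.skip("empty blob draw")
        expected = blob & ~ndimage.binary_erosion(
            blob, structure=ndimage.generate_binary_structure(2, 1), border_value=0
        )
        assert set(trace_outline(blob)) == {tuple(p) for p in np.argwhere(expected)}

    def test_ordering_is_a_boundary_walk(self):
        m = np.zeros((6, 6), dtype=bool)
        m[1:5, 1:5] = True
        outline = trace_outline(m)
        steps = np.abs(np.diff(np.asarray(outline), axis=0)).max(axis=1)
        assert (steps == 1).all()  # consecutive outline voxels are 8-adjacent

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            trace_outline(np.zeros((4, 4), dtype=bool))


class TestInterpolateThresholds:
    def _annset(self, pairs, n_slices=20, axis=0):
        return AnnotationSet(
            axis=axis,
            annotations=[SliceAnnotation(s, (0, 0), t) for s, t in pairs],
            voi=VOI((0, 0, 0), (n_slices, 4, 4)),
        )

    def test_single_annotation_is_constant(self):
        profile = interpolate_thresholds(self._annset([(7, 120.0)]))
        assert np.all(profile.values == 120.0)
        assert len(profile.values) == 20

    def test_two_point_linear_values(self):
        profile = interpolate_thresholds(self._annset([(0, 100.0), (5, 200.0)]))
        assert profile[2] == pytest.approx(140.0)
        assert profile[4] == pytest.approx(180.0)

    def test_three_point_profile_with_extrapolation(self):
        profile = interpolate_thresholds(self._annset([(0, 100.0), (5, 200.0), (10, 150.0)]))
        assert profile[8] == pytest.approx(170.0)
        assert profile[12] == pytest.approx(150.0)  # constant beyond the last annotation

    def test_matches_independent_evaluator_everywhere(self, rng):
        slices = np.sort(rng.choice(np.arange(2, 38), size=5, replace=False))
        values = rng.uniform(80, 180, size=5)
        annset = self._annset(list(zip(slices.tolist(), values.tolist())), n_slices=40)
        profile = interpolate_thresholds(annset)
        for s in range(40):
            assert profile[s] == pytest.approx(
                piecewise_linear_oracle(slices, values, s), abs=1e-9
            )

    def test_annotated_slices_reproduced_exactly_and_piecewise_linear(self):
        annset = self._annset([(2, 101.5), (9, 188.0), (15, 130.0)])
        profile = interpolate_thresholds(annset)
        for ann in annset.annotations:
            assert profile[ann.slice_index] == ann.threshold
        second_diff = np.diff(profile.values[2:10], 2)
        assert np.allclose(second_diff, 0.0, atol=1e-9)


class TestGrow3D:
    def _volume_with_cube(self):
        data = np.zeros((10, 10, 10))
        data[2:8, 2:8, 2:8] = 200.0
        return ImageVolume(data)

    def test_homogeneous_cube_fully_segmented(self):
        vol = self._volume_with_cube()
        mask = grow_3d(vol, _single_annotation_set(vol.shape, (4, 4, 4), 100.0))
        assert mask.count() == 216
        assert mask.data[2:8, 2:8, 2:8].all()

    def test_bridge_cut_by_local_threshold(self):
        # two bright cubes joined by one bright voxel whose slice threshold
        # exceeds its intensity: only the seed cube survives
        data = np.zeros((12, 7, 7))
        data[1:4, 2:5, 2:5] = 200.0
        data[7:10, 2:5, 2:5] = 200.0
        data[4:7, 3, 3] = 150.0  # the bridge
        vol = ImageVolume(data)
        annotations = AnnotationSet(
            axis=0,
            annotations=[
                SliceAnnotation(2, (3, 3), 100.0),
                SliceAnnotation(5, (3, 3), 160.0),  # bridge slice: too strict
                SliceAnnotation(8, (3, 3), 100.0),
            ],
            voi=VOI.full(vol.shape),
            central_index=0,
        )
        mask = grow_3d(vol, annotations)
        assert mask.data[1:4, 2:5, 2:5].all()
        assert not mask.data[7:10].any()
        # brute-force oracle on the locally-thresholded admissible set
        profile = interpolate_thresholds(annotations)
        admissible = vol.data >= np.array([profile[s] for s in range(12)])[:, None, None]
        oracle = flood_fill_oracle(admissible, (2, 3, 3), OFFSETS_3D_6)
        assert np.array_equal(mask.data, oracle)

    @pytest.mark.parametrize("connectivity,both", [(6, False), (26, True)])
    def test_corner_touching_cubes_connectivity(self, connectivity, both):
        data = np.zeros((8, 8, 8))
        data[1:4, 1:4, 1:4] = 200.0
        data[4:7, 4:7, 4:7] = 200.0  # touches the first cube only diagonally
        vol = ImageVolume(data)
        annset = _single_annotation_set(vol.shape, (2, 2, 2), 100.0, connectivity=connectivity)
        mask = grow_3d(vol, annset)
        assert mask.data[4:7, 4:7, 4:7].any() == both
        offsets = OFFSETS_3D_26 if connectivity == 26 else OFFSETS_3D_6
        assert np.array_equal(mask.data, flood_fill_oracle(data >= 100.0, (2, 2, 2), offsets))

    def test_result_confined_to_voi(self):
        data = np.full((10, 10, 10), 200.0)
        vol = ImageVolume(data)
        annset = AnnotationSet(
            axis=0,
            annotations=[SliceAnnotation(4, (2, 2), 100.0)],
            voi=VOI((2, 2, 2), (8, 8, 8)),
        )
        mask = grow_3d(vol, annset)
        assert mask.data[2:8, 2:8, 2:8].all()
        assert mask.count() == 216

    def test_monotone_in_annotated_thresholds(self, rng):
        data = ndimage.gaussian_filter(rng.normal(100, 40, size=(16, 16, 16)), 1.0)
        vol = ImageVolume(data)
        seed = tuple(np.unravel_index(np.argmax(data), data.shape))
        base_t = float(data[seed]) - 30.0
        in_plane = (seed[1], seed[2])
        lo = AnnotationSet(0, [SliceAnnotation(seed[0], in_plane, base_t)], VOI.full(data.shape))
        hi = AnnotationSet(0, [SliceAnnotation(seed[0], in_plane, base_t + 15.0)], VOI.full(data.shape))
        m_lo, m_hi = grow_3d(vol, lo), grow_3d(vol, hi)
        assert not (m_hi.data & ~m_lo.data).any()  # raising thresholds only removes

    def test_seed_always_included_and_passes_threshold(self, rng):
        data = ndimage.gaussian_filter(rng.normal(100, 40, size=(14, 14, 14)), 1.0)
        vol = ImageVolume(data)
        seed = tuple(np.unravel_index(np.argmax(data), data.shape))
        annset = _single_annotation_set(data.shape, seed, float(data[seed]) - 10.0)
        mask = grow_3d(vol, annset)
        assert mask.data[seed]
        profile = interpolate_thresholds(annset)
        for v in np.argwhere(mask.data):
            assert data[tuple(v)] >= profile[v[0]]

    def test_inadmissible_central_seed_rejected(self):
        vol = self._volume_with_cube()
        annset = _single_annotation_set(vol.shape, (0, 0, 0), 100.0)
        with pytest.raises(ValueError, match="threshold"):
            grow_3d(vol, annset)


class TestAnnotationSet:
    def test_central_defaults_to_median_slice(self):
        annset = AnnotationSet(
            axis=0,
            annotations=[SliceAnnotation(s, (1, 1), 100.0) for s in (0, 5, 10, 15, 40)],
            voi=VOI((0, 0, 0), (41, 4, 4)),
        )
        assert annset.central_annotation.slice_index == 10

    def test_central_tie_breaks_to_lower_slice(self):
        annset = AnnotationSet(
            axis=0,
            annotations=[SliceAnnotation(s, (1, 1), 100.0) for s in (0, 10)],
            voi=VOI((0, 0, 0), (11, 4, 4)),
        )
        assert annset.central_annotation.slice_index == 0

    def test_axis_names_accepted(self):
        annset = AnnotationSet(
            axis="coronal",
            annotations=[SliceAnnotation(1, (1, 1), 5.0)],
            voi=VOI((0, 0, 0), (4, 4, 4)),
        )
        assert annset.axis == 1
        assert annset.central_voxel() == (1, 1, 1)

    def test_non_increasing_slices_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            AnnotationSet(
                axis=0,
                annotations=[SliceAnnotation(3, (0, 0), 1.0), SliceAnnotation(3, (0, 0), 1.0)],
                voi=VOI((0, 0, 0), (8, 4, 4)),
            )

    def test_annotation_outside_voi_rejected(self):
        with pytest.raises(ValueError, match="VOI"):
            AnnotationSet(
                axis=0,
                annotations=[SliceAnnotation(9, (0, 0), 1.0)],
                voi=VOI((0, 0, 0), (8, 4, 4)),
            )
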