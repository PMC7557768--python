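"""Track-density maps, MPMs and the percentage-overlap statistic."""

import numpy as np
import pytest

from ppntract.core import AffineTransform, BinaryMask, ImageGrid, Tractogram, Volume, voxel_to_world
from ppntract.density import (
    DensityMap,
    mask_density,
    maximum_probability_map,
    percentage_overlap,
    subject_connectivity_cluster,
    threshold_relative,
    track_density_map,
)
from ppntract.selection import densify


@pytest.fixture
def grid():
    return ImageGrid.from_spacing((20, 20, 20), 1.0, origin=(0, 0, 0))


def oracle_visited(points, grid):
    """Independent per-(streamline, voxel) membership test: sample each chord
    at <= half-voxel spacing, then scan every voxel's half-open interval."""
    inv = grid.inverse_affine
    samples = densify(points, 0.5 * float(np.min(grid.voxel_size)))
    cont = samples @ inv[:3, :3].T + inv[:3, 3]
    visited = set()
    for i in range(grid.dims[0]):
        for j in range(grid.dims[1]):
            for k in range(grid.dims[2]):
                v = np.array([i, j, k])
                if np.any(np.all((cont >= v - 0.5) & (cont < v + 0.5), axis=1)):
                    visited.add((i, j, k))
    return visited


class TestTrackDensityMap:
    def test_axis_aligned_streamline_marks_its_voxels(self, grid):
        s = np.array([[3.0, 7, 7], [7.0, 7, 7]])
        d = track_density_map(Tractogram([s], grid, "t"), grid)
        hit = np.argwhere(d.values > 0)
        assert {tuple(v) for v in hit} == {(x, 7, 7) for x in range(3, 8)}
        assert d.values.max() == 1

    def test_duplicated_streamline_doubles_counts_on_same_support(self, grid):
        s = np.array([[3.0, 7, 7], [7.0, 7, 7]])
        d1 = track_density_map(Tractogram([s], grid, "t"), grid)
        d2 = track_density_map(Tractogram([s, s.copy()], grid, "t"), grid)
        np.testing.assert_array_equal(d2.values, 2 * d1.values)

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        """100 random streamlines on a 20^3 grid against a brute-force
        oracle that tests every (streamline, voxel) pair."""
        grid = ImageGrid.from_spacing((20, 20, 20), 1.0, origin=(0, 0, 0))
        streamlines = [
            rng.uniform(-2, 21, size=(rng.integers(2, 6), 3)) for _ in range(100)
        ]
        d = track_density_map(Tractogram(streamlines, grid, "r"), grid)
        expected = np.zeros(grid.dims, dtype=int)
        for s in streamlines:
            for v in oracle_visited(s, grid):
                expected[v] += 1
        np.testing.assert_array_equal(d.values, expected)

    def test_empty_tractogram_gives_zero_map(self, grid):
        d = track_density_map(Tractogram([], grid, "e"), grid)
        assert d.values.sum() == 0


class TestMaskDensity:
    def test_all_ones_roi_is_identity(self, grid, rng):
        d = DensityMap(Volume(grid, rng.integers(0, 5, grid.dims).astype(float)))
        roi = BinaryMask(grid, np.ones(grid.dims, dtype=np.uint8))
        np.testing.assert_array_equal(mask_density(d, roi).values, d.values)

    def test_disjoint_supports_give_zero(self, grid):
        vals = np.zeros(grid.dims)
        vals[0, 0, 0] = 3
        d = DensityMap(Volume(grid, vals))
        roi = np.zeros(grid.dims, dtype=np.uint8)
        roi[5, 5, 5] = 1
        assert mask_density(d, BinaryMask(grid, roi)).values.sum() == 0

    def test_support_is_intersection(self, grid, rng):
        d = DensityMap(Volume(grid, (rng.random(grid.dims) > 0.6) * 4.0))
        roi = BinaryMask(grid, (rng.random(grid.dims) > 0.5).astype(np.uint8))
        out = mask_density(d, roi)
        expected = (d.values > 0) & (roi.values > 0)
        np.testing.assert_array_equal(out.values > 0, expected)

    def test_grid_mismatch_errors(self, grid):
        other = ImageGrid.from_spacing((5, 5, 5), 1.0)
        d = DensityMap(Volume(grid, np.zeros(grid.dims)))
        with pytest.raises(ValueError, match="grid"):
            mask_density(d, BinaryMask(other, np.zeros((5, 5, 5), dtype=np.uint8)))


class TestThresholdRelative:
    def test_quarter_of_max(self, grid):
        vals = np.zeros(grid.dims)
        vals[0, 0, :4] = [1, 10, 40, 100]
        mask = threshold_relative(DensityMap(Volume(grid, vals)), 0.25)
        kept = {tuple(v) for v in np.argwhere(mask.values > 0)}
        assert kept == {(0, 0, 2), (0, 0, 3)}

    def test_uniform_map_keeps_all_nonzero(self, grid):
        vals = (np.arange(np.prod(grid.dims)).reshape(grid.dims) % 3 == 0) * 7.0
        mask = threshold_relative(DensityMap(Volume(grid, vals)), 0.25)
        np.testing.assert_array_equal(mask.values, (vals > 0).astype(np.uint8))

    def test_zero_map_gives_zero_mask(self, grid):
        assert threshold_relative(DensityMap(Volume(grid, np.zeros(grid.dims)))).count() == 0

    def test_raising_fraction_never_adds_voxels(self, grid, rng):
        d = DensityMap(Volume(grid, rng.integers(0, 50, grid.dims).astype(float)))
        prev = threshold_relative(d, 0.1).values
        for f in (0.25, 0.5, 0.75, 0.9):
            cur = threshold_relative(d, f).values
            assert np.all(cur <= prev)
            prev = cur


class TestMPM:
    @pytest.mark.parametrize("n", [3, 4, 5, 100])
    def test_matches_count_and_compare_oracle(self, n, rng):
        """Thresholded MPM equals a direct per-voxel count >= ceil(N/2)."""
        grid = ImageGrid.from_spacing((8, 8, 8), 1.0)
        masks = [
            BinaryMask(grid, (rng.random(grid.dims) > 0.6).astype(np.uint8))
            for _ in range(n)
        ]
        mpm, thresholded = maximum_probability_map(masks, 0.5)
        stack = np.stack([m.values for m in masks])
        counts = stack.sum(axis=0)
        np.testing.assert_array_equal(mpm.volume.values, counts)
        np.testing.assert_array_equal(
            thresholded.values, (counts >= -(-n // 2)).astype(np.uint8)
        )

    def test_at_least_half_boundary_cases(self):
        grid = ImageGrid.from_spacing((1, 1, 2), 1.0)
        m1 = BinaryMask(grid, np.array([[[1, 1]]], dtype=np.uint8))
        m0 = BinaryMask(grid, np.array([[[0, 1]]], dtype=np.uint8))
        _, t = maximum_probability_map([m1, m1, m0, m0], 0.5)
        # voxel 0 covered by 2 of 4 subjects: retained at cut ceil(2) = 2
        assert t.values[0, 0, 0] == 1 and t.values[0, 0, 1] == 1

    def test_single_subject_voxel_removed_at_n4(self):
        grid = ImageGrid.from_spacing((1, 1, 1), 1.0)
        one = BinaryMask(grid, np.ones((1, 1, 1), dtype=np.uint8))
        zero = BinaryMask(grid, np.zeros((1, 1, 1), dtype=np.uint8))
        _, t = maximum_probability_map([one, zero, zero, zero], 0.5)
        assert t.values[0, 0, 0] == 0

    def test_retention_mask_shrinks_as_fraction_rises(self, rng):
        grid = ImageGrid.from_spacing((6, 6, 6), 1.0)
        masks = [
            BinaryMask(grid, (rng.random(grid.dims) > 0.5).astype(np.uint8))
            for _ in range(9)
        ]
        prev = maximum_probability_map(masks, 0.25)[1].values
        for f in (0.5, 0.75, 1.0):
            cur = maximum_probability_map(masks, f)[1].values
            assert np.all(cur <= prev)
            prev = cur


class TestPercentageOverlap:
    def test_identical_masks_give_100(self, grid, rng):
        m = BinaryMask(grid, (rng.random(grid.dims) > 0.5).astype(np.uint8))
        assert percentage_overlap(m, m) == 100.0

    def test_disjoint_masks_give_0(self, grid):
        a = np.zeros(grid.dims, dtype=np.uint8)
        b = np.zeros(grid.dims, dtype=np.uint8)
        a[0, 0, 0] = 1
        b[5, 5, 5] = 1
        assert percentage_overlap(BinaryMask(grid, a), BinaryMask(grid, b)) == 0.0

    def test_three_of_twelve_gives_25(self, grid):
        a = np.zeros(grid.dims, dtype=np.uint8)
        b = np.zeros(grid.dims, dtype=np.uint8)
        b[0, 0, :12] = 1
        a[0, 0, :3] = 1
        assert percentage_overlap(BinaryMask(grid, a), BinaryMask(grid, b)) == 25.0

    def test_asymmetric_when_sizes_differ(self, grid):
        a = np.zeros(grid.dims, dtype=np.uint8)
        b = np.zeros(grid.dims, dtype=np.uint8)
        a[0, 0, :8] = 1
        b[0, 0, :2] = 1
        ab = percentage_overlap(BinaryMask(grid, a), BinaryMask(grid, b))
        ba = percentage_overlap(BinaryMask(grid, b), BinaryMask(grid, a))
        assert ab == 100.0 and ba == 25.0 and ab != ba

    def test_empty_reference_errors(self, grid):
        a = BinaryMask(grid, np.ones(grid.dims, dtype=np.uint8))
        b = BinaryMask(grid, np.zeros(grid.dims, dtype=np.uint8))
        with pytest.raises(ValueError, match="empty"):
            percentage_overlap(a, b)

    def test_territory_overlaps_bounded_by_cluster_size(self, template_subject):
        """Territories are disjoint, so summed intersections cannot exceed
        the cluster volume."""
        roi = template_subject.masks["GPi_R"]
        cluster = subject_connectivity_cluster(
            template_subject.tractograms["R_GPi_ipsi"], roi,
            AffineTransform.identity(), template_subject.grid,
        )
        total = 0
        for terr in ("limbic", "associative", "sensorimotor"):
            t = template_subject.territory_masks[f"GPi_R_{terr}"]
            total += int(np.sum(cluster.values & t.values))
        assert total <= cluster.count()


class TestSubjectConnectivityCluster:
    def test_single_file_bundle_marks_traversed_roi_voxels(self, grid):
        roi = np.zeros(grid.dims, dtype=np.uint8)
        roi[10:15, 10, 10] = 1
        s = np.array([[2.0, 10, 10], [18.0, 10, 10]])
        cluster = subject_connectivity_cluster(
            Tractogram([s], grid, "b"), BinaryMask(grid, roi),
            AffineTransform.identity(), grid,
        )
        hit = {tuple(v) for v in np.argwhere(cluster.values > 0)}
        assert hit == {(x, 10, 10) for x in range(10, 15)}

    def test_empty_bundle_gives_empty_cluster(self, grid):
        roi = BinaryMask(grid, np.ones(grid.dims, dtype=np.uint8))
        cluster = subject_connectivity_cluster(
            Tractogram([], grid, "e"), roi, AffineTransform.identity(), grid
        )
        assert cluster.count() == 0

    def test_cluster_centroid_lands_in_planted_territory(self, template_subject):
        """GPi bundle endpoints are planted centrally, i.e. in the
        associative tercile; the cluster centroid must fall there."""
        roi = template_subject.masks["GPi_R"]
        cluster = subject_connectivity_cluster(
            template_subject.tractograms["R_GPi_ipsi"], roi,
            AffineTransform.identity(), template_subject.grid,
        )
        assert cluster.count() > 0
        idx = np.argwhere(cluster.values > 0)
        centroid = np.round(idx.mean(axis=0)).astype(int)
        assoc = template_subject.territory_masks["GPi_R_associative"]
        assert assoc.values[tuple(centroid)] == 1
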