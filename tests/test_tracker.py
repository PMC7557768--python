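"""Streamline propagation: parameter resolution, sampling, arc geometry."""

import numpy as np
import pytest

from ppntract.core import BinaryMask, ImageGrid
from ppntract.tracker import (
    OrientationField,
    TrackingParams,
    propagate,
    resolve_params,
    sample_direction,
    track_from_seed_mask,
)


def uniform_field(grid, direction=(1.0, 0.0, 0.0), amplitude=0.5):
    d = np.asarray(direction) / np.linalg.norm(direction)
    dirs = np.broadcast_to(d, grid.dims + (1, 3)).copy()
    amps = np.full(grid.dims + (1,), amplitude)
    return OrientationField(grid, dirs, amps)


class TestResolveParams:
    def test_default_hires_voxel_size(self):
        step, angle = resolve_params(1.25, TrackingParams())
        assert step == pytest.approx(1.5625)
        assert angle == pytest.approx(37.5)

    def test_unit_voxel(self):
        step, angle = resolve_params(1.0, TrackingParams())
        assert step == pytest.approx(1.25)
        assert angle == pytest.approx(37.5)

    @pytest.mark.parametrize("vs", [0.7, 1.0, 1.25, 2.0, 3.3])
    def test_max_angle_invariant_to_voxel_size(self, vs):
        _, angle = resolve_params(vs, TrackingParams())
        assert angle == pytest.approx(37.5)


class TestSampleDirection:
    def test_single_lobe_in_cone_returned_sign_aligned(self, rng):
        grid = ImageGrid.from_spacing((5, 5, 5), 1.0)
        field = uniform_field(grid, (1, 0, 0), 0.5)
        prev = np.array([-1.0, 0.0, 0.0])
        d = sample_direction(field, np.zeros(3), prev, 37.5, rng)
        np.testing.assert_allclose(d, [-1.0, 0.0, 0.0])

    def test_amplitude_below_cutoff_terminates(self, rng):
        grid = ImageGrid.from_spacing((5, 5, 5), 1.0)
        field = uniform_field(grid, (1, 0, 0), 0.01)
        assert sample_direction(field, np.zeros(3), None, 37.5, rng) is None

    def test_out_of_cone_lobe_terminates(self, rng):
        grid = ImageGrid.from_spacing((5, 5, 5), 1.0)
        field = uniform_field(grid, (1, 0, 0), 0.5)
        prev = np.array([0.0, 0.0, 1.0])  # 90 degrees off the only lobe
        assert sample_direction(field, np.zeros(3), prev, 37.5, rng) is None

    def test_selection_frequency_proportional_to_amplitude(self, rng):
        grid = ImageGrid.from_spacing((3, 3, 3), 1.0)
        dirs = np.zeros(grid.dims + (2, 3))
        dirs[..., 0, :] = (1.0, 0.0, 0.0)
        dirs[..., 1, :] = (0.0, 1.0, 0.0)
        amps = np.zeros(grid.dims + (2,))
        amps[..., 0] = 0.2
        amps[..., 1] = 0.8
        field = OrientationField(grid, dirs, amps)
        n = 20_000
        hits = sum(
            sample_direction(field, np.zeros(3), None, 37.5, rng)[1] > 0.5
            for _ in range(n)
        )
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(hits / n - 0.8) < 3 * se

    def test_point_outside_grid_errors(self, rng):
        grid = ImageGrid.from_spacing((3, 3, 3), 1.0)
        field = uniform_field(grid)
        with pytest.raises(ValueError, match="outside"):
            sample_direction(field, np.array([50.0, 0, 0]), None, 37.5, rng)


class TestPropagate:
    def test_straight_field_gives_straight_streamline(self, rng):
        grid = ImageGrid.from_spacing((32, 9, 9), 1.25)
        field = uniform_field(grid, (1, 0, 0), 0.5)
        params = TrackingParams()
        step, _ = resolve_params(1.25, params)
        s = propagate(np.zeros(3), field, params, rng)
        assert s is not None
        # spans to the grid boundary in both directions
        assert s[:, 0].min() < -17 and s[:, 0].max() > 17
        assert np.abs(s[:, 1]).max() < 1e-9 and np.abs(s[:, 2]).max() < 1e-9
        chords = np.linalg.norm(np.diff(s, axis=0), axis=1)
        np.testing.assert_allclose(chords, step, atol=1e-6)

    def test_seed_in_background_rejected(self, rng):
        grid = ImageGrid.from_spacing((9, 9, 9), 1.0)
        field = uniform_field(grid, (1, 0, 0), 0.01)
        assert propagate(np.zeros(3), field, TrackingParams(), rng) is None

    def test_max_length_respected(self, rng):
        grid = ImageGrid.from_spacing((64, 9, 9), 1.0)
        field = uniform_field(grid, (1, 0, 0), 0.5)
        params = TrackingParams(max_length_mm=10.0)
        s = propagate(np.zeros(3), field, params, rng)
        length = np.linalg.norm(np.diff(s, axis=0), axis=1).sum()
        assert length <= 10.0 + 1e-9


class TestTrackFromSeedMask:
    def test_count_bound_and_containment(self, rng):
        grid = ImageGrid.from_spacing((12, 5, 5), 1.0)
        field = uniform_field(grid, (1, 0, 0), 0.5)
        vals = np.zeros(grid.dims, dtype=np.uint8)
        vals[5:7, 2, 2:4] = 1  # 4 seed voxels
        mask = BinaryMask(grid, vals)
        t = track_from_seed_mask(mask, field, TrackingParams(seeds_per_voxel=10), rng)
        assert 0 < len(t) <= 40

    def test_background_mask_gives_empty_tractogram(self, rng):
        grid = ImageGrid.from_spacing((8, 8, 8), 1.0)
        field = uniform_field(grid, (1, 0, 0), 0.01)
        vals = np.zeros(grid.dims, dtype=np.uint8)
        vals[4, 4, 4] = 1
        t = track_from_seed_mask(BinaryMask(grid, vals), field, TrackingParams(), rng)
        assert len(t) == 0

    def test_empty_mask_errors(self, rng):
        grid = ImageGrid.from_spacing((4, 4, 4), 1.0)
        field = uniform_field(grid)
        with pytest.raises(ValueError, match="empty"):
            track_from_seed_mask(
                BinaryMask(grid, np.zeros(grid.dims, dtype=np.uint8)),
                field,
                TrackingParams(),
                rng,
            )

    def test_determinism(self, subject0):
        params = TrackingParams(seeds_per_voxel=2)
        a = track_from_seed_mask(
            subject0.masks["GPi_L"], subject0.field, params, np.random.default_rng(5)
        )
        b = track_from_seed_mask(
            subject0.masks["GPi_L"], subject0.field, params, np.random.default_rng(5)
        )
        assert len(a) == len(b)
        for x, y in zip(a.streamlines, b.streamlines):
            np.testing.assert_array_equal(x, y)


@pytest.fixture(scope="module")
def tracked(subject0):
    params = TrackingParams(seeds_per_voxel=3)
    return track_from_seed_mask(
        subject0.masks["GPi_R"], subject0.field, params, np.random.default_rng(8)
    )


class TestArcGeometryOnPhantom:
    """Curvature and chord-length invariants on realistically tracked data."""

    def test_chord_lengths_bounded_by_arc_step(self, subject0, tracked):
        step, max_angle = resolve_params(1.25, TrackingParams())
        theta = np.deg2rad(max_angle)
        min_chord = 2.0 * (step / theta) * np.sin(theta / 2.0)
        for s in tracked.streamlines:
            chords = np.linalg.norm(np.diff(s, axis=0), axis=1)
            assert chords.max() <= step + 1e-6
            assert chords.min() >= min_chord - 1e-6

    def test_turning_angle_bounded(self, tracked):
        # consecutive chords are arc bisectors, so their relative angle is at
        # most the per-step curvature bound
        for s in tracked.streamlines:
            if len(s) < 3:
                continue
            v = np.diff(s, axis=0)
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            cos = np.clip(np.einsum("ij,ij->i", v[:-1], v[1:]), -1, 1)
            assert np.rad2deg(np.arccos(cos)).max() <= 37.5 + 1e-6


def test_tracking_params_validation():
    with pytest.raises(ValueError):
        TrackingParams(seeds_per_voxel=0)
    with pytest.raises(ValueError):
        TrackingParams(cutoff=0.0)
    with pytest.raises(ValueError):
        TrackingParams(angle_factor_deg=80.0)  # resolved angle would exceed 90
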