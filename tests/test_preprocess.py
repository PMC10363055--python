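"""HU normalization, resampling, bounding boxes, cropping and embedding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mandseg.io import BinaryMask, CTVolume
from mandseg.preprocess import (
    BoundingBox3D,
    EmptySegmentationError,
    PreprocessConfig,
    clip_and_normalize_hu,
    compute_bounding_box,
    crop_to_bbox,
    embed_prediction,
    pad_bounding_box,
    resample_mask,
    resample_volume,
    threshold_segment,
)


class TestNormalization:
    @pytest.mark.parametrize("hu,expected", [
        (-1024.0, 0.0), (3071.0, 1.0), (-3000.0, 0.0), (5000.0, 1.0),
        (1023.5, 0.5),
    ])
    def test_endpoints_and_midpoint(self, hu, expected):
        vol = CTVolume(np.full((2, 2, 2), hu))
        out = clip_and_normalize_hu(vol)
        assert np.allclose(out.voxels, expected)

    def test_monotone(self, rng):
        pairs = rng.uniform(-3000, 5000, size=(1000, 2))
        lo, hi = pairs.min(axis=1), pairs.max(axis=1)
        n = clip_and_normalize_hu(CTVolume(np.stack([lo, hi]).reshape(2, 1000, 1)))
        assert np.all(n.voxels[0] <= n.voxels[1] + 1e-15)

    def test_nonfinite_rejected(self):
        vox = np.zeros((2, 2, 2))
        vox[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            CTVolume(vox)

    def test_geometry_unchanged(self):
        vol = CTVolume(np.zeros((3, 3, 3)), spacing=(2, 0.4, 0.4), origin=(1, 2, 3))
        out = clip_and_normalize_hu(vol)
        assert out.spacing == vol.spacing and out.origin == vol.origin


class TestResampling:
    def test_identity_shape(self, rng):
        vol = CTVolume(rng.normal(size=(10, 10, 10)))
        out = resample_volume(vol, (10, 10, 10), order=3)
        assert np.allclose(out.voxels, vol.voxels)

    @pytest.mark.parametrize("shape", [(5, 5, 5), (16, 16, 16), (7, 12, 9)])
    def test_constant_preserved(self, shape):
        vol = CTVolume(np.full((12, 12, 12), 3.7))
        out = resample_volume(vol, shape, order=3)
        assert np.allclose(out.voxels, 3.7, atol=1e-9)

    def test_linear_ramp_interior_exact(self):
        # third-degree splines reproduce linear fields away from borders
        n = 32
        ramp = np.broadcast_to(np.arange(n, dtype=float)[:, None, None],
                               (n, n, n)).copy()
        out = resample_volume(CTVolume(ramp), (16, 16, 16), order=3)
        expected = (np.arange(16) + 0.5) * 2.0 - 0.5
        interior = slice(4, 12)  # spline boundary effects decay within ~4 voxels
        got = out.voxels[interior, 8, 8]
        assert np.allclose(got, expected[interior], atol=1e-6)

    def test_spacing_rescaled_extent_preserved(self):
        vol = CTVolume(np.zeros((20, 10, 10)), spacing=(1.0, 0.5, 0.5))
        out = resample_volume(vol, (10, 10, 10))
        assert np.allclose(out.spacing, (2.0, 0.5, 0.5))
        # physical extent: n * spacing unchanged per axis
        assert np.allclose(np.array(out.shape) * out.spacing,
                           np.array(vol.shape) * vol.spacing)

    def test_mask_identity_and_full(self, rng):
        mask = BinaryMask(rng.random((8, 8, 8)) < 0.4)
        assert np.array_equal(resample_mask(mask, (8, 8, 8)).voxels, mask.voxels)
        full = BinaryMask(np.ones((8, 8, 8), dtype=bool))
        for shape in [(4, 4, 4), (12, 12, 12)]:
            assert resample_mask(full, shape).voxels.all()

    def test_mask_downsample_centered_cube(self):
        # centered 8^3 cube in 16^3, halved -> centered 4^3 cube
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[4:12, 4:12, 4:12] = True
        out = resample_mask(BinaryMask(mask), (8, 8, 8))
        expected = np.zeros((8, 8, 8), dtype=bool)
        expected[2:6, 2:6, 2:6] = True
        assert np.array_equal(out.voxels, expected)


class TestBoundingBoxes:
    def test_single_voxel(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[3, 4, 5] = True
        bb = compute_bounding_box(BinaryMask(m))
        assert bb.lower == (3, 4, 5) and bb.upper == (4, 5, 6)

    def test_two_corners(self):
        m = np.zeros((10, 10, 10), dtype=bool)
        m[0, 0, 0] = m[9, 9, 9] = True
        bb = compute_bounding_box(BinaryMask(m))
        assert bb.lower == (0, 0, 0) and bb.upper == (10, 10, 10)

    def test_empty_rejected(self):
        with pytest.raises(EmptySegmentationError):
            compute_bounding_box(BinaryMask(np.zeros((4, 4, 4), dtype=bool)))

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(30):
            m = np.zeros((12, 12, 12), dtype=bool)
            idx = rng.integers(0, 12, size=(50, 3))
            m[idx[:, 0], idx[:, 1], idx[:, 2]] = True
            bb = compute_bounding_box(BinaryMask(m))
            pts = np.argwhere(m)
            assert bb.lower == tuple(pts.min(axis=0))
            assert bb.upper == tuple(pts.max(axis=0) + 1)

    @pytest.mark.parametrize("margin,expected_lower,expected_upper", [
        (0, (10, 10, 10), (20, 20, 20)),
        (2, (8, 8, 8), (22, 22, 22)),
    ])
    def test_padding(self, margin, expected_lower, expected_upper):
        bb = BoundingBox3D((10, 10, 10), (20, 20, 20))
        out = pad_bounding_box(bb, margin, (144, 144, 144))
        assert out.lower == expected_lower and out.upper == expected_upper

    def test_padding_clamped_at_corner(self):
        bb = BoundingBox3D((0, 0, 0), (3, 3, 3))
        out = pad_bounding_box(bb, 5, (10, 10, 10))
        assert out.lower == (0, 0, 0) and out.upper == (8, 8, 8)


class TestCropEmbed:
    def test_full_grid_crop_identity(self, rng):
        vol = CTVolume(rng.normal(size=(6, 6, 6)))
        out = crop_to_bbox(vol, BoundingBox3D((0, 0, 0), (6, 6, 6)))
        assert np.array_equal(out.voxels, vol.voxels)

    def test_one_voxel_crop_and_origin_shift(self):
        vox = np.arange(27.0).reshape(3, 3, 3)
        vol = CTVolume(vox, spacing=(1, 2, 3), origin=(0, 0, 0))
        out = crop_to_bbox(vol, BoundingBox3D((1, 2, 0), (2, 3, 1)))
        assert out.voxels.shape == (1, 1, 1)
        assert out.voxels[0, 0, 0] == vox[1, 2, 0]
        assert np.allclose(out.origin, (1.0, 4.0, 0.0))

    def test_embed_all_true_block(self):
        crop = BinaryMask(np.ones((4, 4, 4), dtype=bool))
        bb = BoundingBox3D((2, 2, 2), (6, 6, 6))
        full = embed_prediction(crop, bb, (8, 8, 8))
        assert full.voxels.sum() == 64
        assert full.voxels[2:6, 2:6, 2:6].all()

    def test_crop_embed_round_trip(self, rng):
        for _ in range(30):
            shape = tuple(rng.integers(6, 14, 3))
            m = BinaryMask(rng.random(shape) < 0.3)
            lower = tuple(rng.integers(0, s - 2) for s in shape)
            upper = tuple(int(rng.integers(l + 1, s)) + 1 for l, s in zip(lower, shape))
            bb = BoundingBox3D(lower, tuple(min(u, s) for u, s in zip(upper, shape)))
            crop = crop_to_bbox(m, bb)
            back = embed_prediction(crop, bb, shape)
            assert np.array_equal(back.voxels[bb.slices()], m.voxels[bb.slices()])
            outside = np.ones(shape, dtype=bool)
            outside[bb.slices()] = False
            assert not back.voxels[outside].any()


class TestThresholdSegment:
    def test_all_zero_empty(self):
        assert not threshold_segment(CTVolume(np.zeros((4, 4, 4))), 250.0).voxels.any()

    def test_boundary_inclusive(self):
        vol = CTVolume(np.full((2, 2, 2), 250.0))
        assert threshold_segment(vol, 250.0).voxels.all()

    def test_streaks_exceed_threshold(self, phantom_spec_48):
        from mandseg.phantom import add_metal_artifacts, generate_phantom
        ct, mask = generate_phantom(phantom_spec_48, seed=3)
        ct_art = add_metal_artifacts(ct, mask, phantom_spec_48, seed=4)
        base = threshold_segment(ct, 250.0).voxels
        art = threshold_segment(ct_art, 250.0).voxels
        assert art.sum() > base.sum()
        assert (art & ~mask.voxels).sum() > (base & ~mask.voxels).sum()


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_config_validation_and_normalize_range(seed):
    rng = np.random.default_rng(seed)
    vol = CTVolume(rng.uniform(-5000, 8000, (4, 4, 4)))
    out = clip_and_normalize_hu(vol, PreprocessConfig())
    assert out.voxels.min() >= 0.0 and out.voxels.max() <= 1.0
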