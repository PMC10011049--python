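"""Patch seeding, Hann-window blending and the two-step pipeline."""

import logging

import numpy as np
import pytest

from chpseg.cascade import (
    CascadeConfig,
    Patch,
    PatchLocation,
    ProbabilityMap,
    binarize,
    downsample,
    extract_patch,
    find_seed_voxels,
    hann_window,
    merge_patches,
    predict_one_step,
    predict_two_step,
)
from chpseg.io_preproc import Volume
from chpseg.metrics import dice_score
from chpseg.phantom import PhantomParams, generate_phantom
from chpseg.training import make_step1_target


class TestDownsample:
    def test_constant_stays_constant(self):
        v = Volume.from_spacing(np.full((32, 32, 32), 2.5, np.float32))
        out = downsample(v, (8, 8, 8))
        assert out.shape == (8, 8, 8)
        assert np.allclose(out.grid, 2.5, atol=1e-5)

    def test_full_size_maps_to_lowres(self):
        v = Volume.from_spacing(np.zeros((176, 240, 256), np.float32))
        assert downsample(v, (72, 96, 104)).shape == (72, 96, 104)

    def test_lowres_larger_than_input_rejected(self):
        v = Volume.from_spacing(np.zeros((16, 16, 16), np.float32))
        with pytest.raises(ValueError, match="axis"):
            downsample(v, (32, 16, 16))

    def test_reconstruction_error_decreases_with_smoothness(self):
        """Down-then-up on separable cosine fields: smoother fields survive

        the round trip better (interpolation oracle on known bandwidth)."""
        from chpseg.io_preproc import _zoom_to_shape

        errs = []
        for cycles in (1, 4):
            ax = [np.cos(2 * np.pi * cycles * np.arange(32) / 32) for _ in range(3)]
            f = (ax[0][:, None, None] * ax[1][None, :, None]
                 * ax[2][None, None, :]).astype(np.float32)
            low = downsample(Volume.from_spacing(f), (16, 16, 16))
            up = _zoom_to_shape(low.grid, (32, 32, 32), order=1)
            errs.append(np.abs(up - f).max())
        assert errs[0] < errs[1]


class TestSeeding:
    def test_all_zero_map_yields_no_seeds(self):
        assert find_seed_voxels(np.zeros((8, 8, 8)), 0.8, (32, 32, 32)) == []

    def test_single_suprathreshold_voxel_maps_to_scaled_index(self):
        p = np.full((8, 8, 8), 0.5, np.float32)
        p[2, 3, 4] = 0.9
        locs = find_seed_voxels(p, 0.8, (32, 32, 32))
        assert locs == [PatchLocation((8, 12, 16))]

    def test_threshold_is_strict(self):
        p = np.zeros((4, 4, 4), np.float32)
        p[1, 1, 1] = 0.8
        assert find_seed_voxels(p, 0.8, (8, 8, 8)) == []
        p[1, 1, 1] = np.nextafter(np.float32(0.8), np.float32(1.0))
        assert len(find_seed_voxels(p, 0.8, (8, 8, 8))) == 1

    def test_seed_count_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        p = rng.random((10, 10, 10)).astype(np.float32)
        counts = [len(find_seed_voxels(p, t, (40, 40, 40)))
                  for t in (0.2, 0.5, 0.8, 0.95)]
        assert counts == sorted(counts, reverse=True)


class TestSampling:
    def test_under_cap_returns_all(self):
        from chpseg.cascade import sample_patch_locations

        cands = [PatchLocation((i, i, i)) for i in range(3)]
        out = sample_patch_locations(cands, 500, np.random.default_rng(0))
        assert out == cands

    def test_cap_enforced_exactly(self):
        from chpseg.cascade import sample_patch_locations

        cands = [PatchLocation((i, 0, 0)) for i in range(10_000)]
        out = sample_patch_locations(cands, 500, np.random.default_rng(0))
        assert len(out) == 500
        assert len(set(out)) == 500  # without replacement

    def test_seeded_determinism(self):
        from chpseg.cascade import sample_patch_locations

        cands = [PatchLocation((i, 0, 0)) for i in range(1000)]
        a = sample_patch_locations(cands, 100, np.random.default_rng(7))
        b = sample_patch_locations(cands, 100, np.random.default_rng(7))
        assert a == b


class TestExtract:
    def test_interior_center_definition(self):
        v = Volume.from_spacing(np.zeros((96, 96, 96), np.float32))
        p = extract_patch(v, PatchLocation((50, 60, 40)), 48)
        assert p.origin == (26, 36, 16)

    def test_corner_clamped_to_volume(self):
        rng = np.random.default_rng(1)
        g = rng.random((64, 64, 64)).astype(np.float32)
        v = Volume.from_spacing(g)
        p = extract_patch(v, PatchLocation((0, 0, 63)), 48)
        assert p.origin == (0, 0, 16)
        np.testing.assert_array_equal(p.data, g[0:48, 0:48, 16:64])

    def test_slicing_identity(self):
        rng = np.random.default_rng(2)
        g = rng.random((60, 60, 60)).astype(np.float32)
        p = extract_patch(Volume.from_spacing(g), PatchLocation((30, 30, 30)), 16)
        sl = tuple(slice(o, o + 16) for o in p.origin)
        np.testing.assert_array_equal(p.data, g[sl])

    def test_oversized_patch_rejected(self):
        v = Volume.from_spacing(np.zeros((16, 16, 16), np.float32))
        with pytest.raises(ValueError):
            extract_patch(v, PatchLocation((8, 8, 8)), 48)


class TestHannWindow:
    def test_interior_sampled_closed_form(self):
        for n in (2, 5, 48):
            w = hann_window(n)
            i = np.arange(n)
            expected = 0.5 * (1 - np.cos(2 * np.pi * (i + 1) / (n + 1)))
            c = n // 2
            # separable product: the profile along one axis is the 1D window
            # scaled by the fixed values on the other two axes
            np.testing.assert_allclose(
                w[:, c, c], expected * expected[c] ** 2, rtol=1e-6)
            np.testing.assert_allclose(w.max(), expected.max() ** 3, rtol=1e-6)

    def test_strictly_positive_and_peaked_at_center(self):
        w = hann_window(8)
        assert w.min() > 0
        assert np.unravel_index(np.argmax(w), w.shape) in {(3, 3, 3), (4, 4, 4)}

    def test_symmetric_under_axis_reflection(self):
        w = hann_window(7)
        for ax in range(3):
            np.testing.assert_allclose(w, np.flip(w, axis=ax), rtol=1e-7)


class TestMerge:
    def test_single_constant_patch_normalizes_to_constant(self):
        patch = Patch((4, 4, 4), np.full((8, 8, 8), 0.7, np.float32))
        out = merge_patches([patch], (20, 20, 20))
        sl = (slice(4, 12),) * 3
        np.testing.assert_allclose(out.grid[sl], 0.7, atol=1e-6)
        rest = out.grid.copy()
        rest[sl] = 0
        assert np.all(rest == 0)

    def test_two_overlapping_patches_average(self):
        a = Patch((0, 0, 0), np.full((8, 8, 8), 0.2, np.float32))
        b = Patch((0, 0, 0), np.full((8, 8, 8), 0.6, np.float32))
        out = merge_patches([a, b], (8, 8, 8))
        np.testing.assert_allclose(out.grid, 0.4, atol=1e-6)

    def test_partition_of_unity_reproduces_source(self):
        rng = np.random.default_rng(3)
        src = rng.random((32, 32, 32)).astype(np.float32)
        patches = []
        for ox in range(0, 32, 8):
            for oy in range(0, 32, 8):
                for oz in range(0, 32, 8):
                    o = (ox, oy, oz)
                    patches.append(Patch(o, src[ox:ox + 8, oy:oy + 8, oz:oz + 8]))
        # add overlapping extras; they carry the same source values
        for _ in range(10):
            o = tuple(int(i) for i in rng.integers(0, 24, 3))
            sl = tuple(slice(i, i + 8) for i in o)
            patches.append(Patch(o, src[sl]))
        out = merge_patches(patches, (32, 32, 32))
        assert np.abs(out.grid - src).max() < 1e-5

    def test_empty_patch_list_returns_zero_map(self, caplog):
        with caplog.at_level(logging.WARNING):
            out = merge_patches([], (8, 8, 8))
        assert np.all(out.grid == 0)


class TestBinarize:
    def test_above_threshold_all_ones(self):
        p = ProbabilityMap(np.full((4, 4, 4), 0.6, np.float32), np.eye(4))
        assert np.all(binarize(p, 0.5).grid == 1)

    def test_exactly_at_threshold_is_background(self):
        p = ProbabilityMap(np.full((4, 4, 4), 0.5, np.float32), np.eye(4))
        assert np.all(binarize(p, 0.5).grid == 0)

    def test_mask_volume_non_increasing_in_threshold(self):
        rng = np.random.default_rng(4)
        p = ProbabilityMap(rng.random((10, 10, 10)).astype(np.float32), np.eye(4))
        sizes = [binarize(p, t).grid.sum() for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_threshold_rejected(self):
        p = ProbabilityMap(np.zeros((2, 2, 2), np.float32), np.eye(4))
        with pytest.raises(ValueError):
            binarize(p, 1.0)


class TestPipeline:
    CFG = CascadeConfig(lowres_shape=(12, 12, 12), patch_size=16)

    def test_no_seed_branch_warns_and_returns_empty(self, small_phantom, caplog):
        v, _ = small_phantom
        with caplog.at_level(logging.WARNING):
            prob, mask = predict_two_step(
                v, lambda g: np.zeros_like(g), lambda g: g, self.CFG,
                np.random.default_rng(0),
            )
        assert np.all(mask.grid == 0)
        assert any("no voxel above" in r.message for r in caplog.records)

    def test_oracle_networks_reproduce_ground_truth(self, small_phantom):
        """With ground-truth oracles in both stages, only interpolation and

        blending error remains and Dice stays near 1."""
        _, gt = small_phantom
        gt_vol = Volume(gt.grid.astype(np.float32), gt.affine)
        seed_map = make_step1_target(gt, self.CFG.lowres_shape)
        prob, mask = predict_two_step(
            gt_vol, lambda g: seed_map, lambda g: g, self.CFG,
            np.random.default_rng(0),
        )
        assert dice_score(mask, gt) > 0.95

    def test_end_to_end_determinism(self, small_phantom):
        v, gt = small_phantom
        gt_vol = Volume(gt.grid.astype(np.float32), gt.affine)
        seed_map = make_step1_target(gt, self.CFG.lowres_shape)
        masks = []
        for _ in range(2):
            _, mask = predict_two_step(
                gt_vol, lambda g: seed_map, lambda g: g, self.CFG,
                np.random.default_rng(11),
            )
            masks.append(mask.grid)
        np.testing.assert_array_equal(masks[0], masks[1])

    def test_one_step_oracle_and_shapes(self, small_phantom):
        v, gt = small_phantom
        prob, mask = predict_one_step(
            Volume(gt.grid.astype(np.float32), gt.affine), lambda g: g
        )
        assert prob.shape == v.shape
        np.testing.assert_array_equal(mask.grid, gt.grid)
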