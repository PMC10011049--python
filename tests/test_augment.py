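"""Augmentation battery: identities, invariants, trigger statistics."""

import numpy as np
import pytest

from chpseg.augment import (
    AugmentConfig,
    augment_pair,
    intensity_transforms,
    kspace_artifacts,
    spatial_transforms,
)
from chpseg.io_preproc import LabelMask, Volume

ALL_OFF = AugmentConfig(
    flip_p=0, affine_p=0, aniso_p=0, motion_p=0, ghost_p=0, spike_p=0,
    bias_p=0, noise_p=0, contrast_p=0,
)


def _pair(shape=(16, 16, 16), seed=0):
    rng = np.random.default_rng(seed)
    v = Volume.from_spacing(rng.random(shape).astype(np.float32))
    m = LabelMask((rng.random(shape) > 0.9).astype(np.uint8), v.affine.copy())
    return v, m


class TestSpatial:
    def test_all_off_is_bit_identical(self):
        v, m = _pair()
        v2, m2 = spatial_transforms(v, m, ALL_OFF, np.random.default_rng(0))
        np.testing.assert_array_equal(v2.grid, v.grid)
        np.testing.assert_array_equal(m2.grid, m.grid)

    def test_flip_is_an_involution(self):
        v, m = _pair()
        cfg = AugmentConfig(flip_p=1, affine_p=0, aniso_p=0, motion_p=0,
                            ghost_p=0, spike_p=0, bias_p=0, noise_p=0,
                            contrast_p=0)
        v1, m1 = spatial_transforms(v, m, cfg, np.random.default_rng(0))
        v2, m2 = spatial_transforms(v1, m1, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(v2.grid, v.grid)
        np.testing.assert_array_equal(m2.grid, m.grid)

    def test_zero_magnitude_affine_is_identity(self):
        v, m = _pair()
        cfg = AugmentConfig(flip_p=0, affine_p=1, affine_max_scale=0.0,
                            affine_max_rotation=0.0, aniso_p=0, motion_p=0,
                            ghost_p=0, spike_p=0, bias_p=0, noise_p=0,
                            contrast_p=0)
        v2, m2 = spatial_transforms(v, m, cfg, np.random.default_rng(0))
        assert np.abs(v2.grid - v.grid).max() < 1e-5
        np.testing.assert_array_equal(m2.grid, m.grid)

    def test_unit_anisotropy_is_identity(self):
        v, m = _pair()
        cfg = AugmentConfig(flip_p=0, affine_p=0, aniso_p=1,
                            aniso_max_downsampling=1.0, motion_p=0, ghost_p=0,
                            spike_p=0, bias_p=0, noise_p=0, contrast_p=0)
        v2, _ = spatial_transforms(v, m, cfg, np.random.default_rng(0))
        assert np.abs(v2.grid - v.grid).max() < 1e-5

    def test_misaligned_pair_rejected(self):
        v, _ = _pair()
        m = LabelMask(np.zeros((8, 8, 8), np.uint8))
        with pytest.raises(ValueError, match="aligned"):
            spatial_transforms(v, m, ALL_OFF, np.random.default_rng(0))


class TestKSpace:
    def test_all_off_identity(self):
        v, _ = _pair()
        v2 = kspace_artifacts(v, ALL_OFF, np.random.default_rng(0))
        np.testing.assert_array_equal(v2.grid, v.grid)

    @pytest.mark.parametrize("kwargs", [
        dict(motion_p=1, motion_max_rotation=0.0, motion_max_translation=0.0),
        dict(ghost_p=1, ghost_max_intensity=0.0),
        dict(spike_p=1, spike_max_intensity=0.0),
    ])
    def test_zero_magnitude_is_identity(self, kwargs):
        v, _ = _pair()
        base = dict(flip_p=0, affine_p=0, aniso_p=0, motion_p=0, ghost_p=0,
                    spike_p=0, bias_p=0, noise_p=0, contrast_p=0)
        base.update(kwargs)
        v2 = kspace_artifacts(v, AugmentConfig(**base), np.random.default_rng(0))
        assert np.abs(v2.grid - v.grid).max() < 1e-5

    def test_spike_produces_plane_wave(self):
        """A single k-space spike on a constant image adds a sinusoid whose

        frequency matches the spike position (Fourier identity oracle)."""
        n = 16
        v = Volume.from_spacing(np.ones((n, n, n), np.float32))
        cfg = AugmentConfig(flip_p=0, affine_p=0, aniso_p=0, motion_p=0,
                            ghost_p=0, spike_p=1, spike_max_intensity=1.0,
                            bias_p=0, noise_p=0, contrast_p=0)
        rng = np.random.default_rng(5)
        # reproduce the draws the implementation makes
        probe = np.random.default_rng(5)
        for _ in range(3):  # motion, ghost and spike trigger draws
            probe.random()
        pos = tuple(int(probe.integers(1, n)) for _ in range(3))
        intensity = probe.uniform(0.0, 1.0)
        phase = probe.uniform(0.0, 2 * np.pi)
        out = kspace_artifacts(v, cfg, rng).grid
        x, y, z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        arg = 2 * np.pi * (pos[0] * x + pos[1] * y + pos[2] * z) / n
        scale = float(n ** 3)  # |DC| of the constant-1 image
        expected = 1.0 + intensity * scale * np.cos(arg + phase) / n ** 3
        np.testing.assert_allclose(out, expected, atol=1e-4)


class TestIntensity:
    def test_all_off_identity(self):
        v, _ = _pair()
        v2 = intensity_transforms(v, ALL_OFF, np.random.default_rng(0))
        np.testing.assert_array_equal(v2.grid, v.grid)

    def test_unit_gamma_is_identity(self):
        v, _ = _pair()
        cfg = AugmentConfig(flip_p=0, affine_p=0, aniso_p=0, motion_p=0,
                            ghost_p=0, spike_p=0, bias_p=0, noise_p=0,
                            contrast_p=1, contrast_max_log_gamma=0.0)
        v2 = intensity_transforms(v, cfg, np.random.default_rng(0))
        assert np.abs(v2.grid - v.grid).max() < 1e-5

    def test_zero_magnitude_bias_is_identity(self):
        v, _ = _pair()
        cfg = AugmentConfig(flip_p=0, affine_p=0, aniso_p=0, motion_p=0,
                            ghost_p=0, spike_p=0, bias_p=1, bias_max_magnitude=0.0,
                            noise_p=0, contrast_p=0)
        v2 = intensity_transforms(v, cfg, np.random.default_rng(0))
        assert np.abs(v2.grid - v.grid).max() < 1e-5

    def test_noise_moments_match_law_of_large_numbers(self):
        n = 32
        v = Volume.from_spacing(np.zeros((n, n, n), np.float32))
        cfg = AugmentConfig(flip_p=0, affine_p=0, aniso_p=0, motion_p=0,
                            ghost_p=0, spike_p=0, bias_p=0, noise_p=1,
                            contrast_p=0)
        out = intensity_transforms(v, cfg, np.random.default_rng(9)).grid
        tol = 3 / np.sqrt(n ** 3)
        assert abs(out.mean()) < tol
        assert abs(out.std() - 1.0) < tol


class TestAugmentPair:
    def test_all_off_identity_pair(self):
        v, m = _pair()
        v2, m2 = augment_pair(v, m, ALL_OFF, np.random.default_rng(0))
        np.testing.assert_array_equal(v2.grid, v.grid)
        np.testing.assert_array_equal(m2.grid, m.grid)

    def test_mask_stays_binary_under_everything(self):
        v, m = _pair()
        cfg = AugmentConfig(flip_p=1, affine_p=1, aniso_p=1, motion_p=1,
                            ghost_p=1, spike_p=1, bias_p=1, noise_p=1,
                            contrast_p=1)
        for seed in range(3):
            _, m2 = augment_pair(v, m, cfg, np.random.default_rng(seed))
            assert set(np.unique(m2.grid)) <= {0, 1}
            assert m2.grid.shape == m.grid.shape

    def test_fixed_seed_reproducible(self):
        v, m = _pair()
        a = augment_pair(v, m, AugmentConfig(), np.random.default_rng(123))
        b = augment_pair(v, m, AugmentConfig(), np.random.default_rng(123))
        np.testing.assert_array_equal(a[0].grid, b[0].grid)
        np.testing.assert_array_equal(a[1].grid, b[1].grid)

    def test_trigger_frequencies_match_configured_probabilities(self):
        """Over many seeded draws every transform fires at its configured

        probability, within 4 standard errors."""
        v, m = _pair(shape=(8, 8, 8))
        cfg = AugmentConfig()
        expected = {
            "flip": cfg.flip_p, "affine": cfg.affine_p, "aniso": cfg.aniso_p,
            "motion": cfg.motion_p, "ghost": cfg.ghost_p, "spike": cfg.spike_p,
            "bias": cfg.bias_p, "noise": cfg.noise_p, "contrast": cfg.contrast_p,
        }
        n = 1000
        counts = dict.fromkeys(expected, 0)
        rng = np.random.default_rng(2024)
        for _ in range(n):
            rec = {}
            augment_pair(v, m, cfg, rng, record=rec)
            for k in expected:
                counts[k] += rec[k]
        for k, p in expected.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[k] / n - p) < 4 * se, f"{k}: {counts[k] / n} vs {p}"
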