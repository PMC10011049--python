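"""Synthetic brain-like phantoms with thin bright targets in dark cavities.

The generator emulates the geometry that makes choroid-plexus segmentation
hard: an ellipsoidal "brain" of mid-grey tissue on a dark background, two
dark lateral cavities standing in for the CSF-filled ventricles, and inside
each cavity a thin, curvilinear, *bright* structure occupying a fraction of
a percent of the volume — built as a momentum-driven random walk dilated to
a 1-2 voxel radius tube and clipped to the cavity.  The image is Gaussian
smoothed (partial-volume effect) and corrupted with additive noise; the
ground-truth mask is the pre-smoothing tube.  Everything is reproducible
from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from chpseg.io_preproc import LabelMask, Volume


@dataclass(frozen=True)
class PhantomParams:
    """Phantom geometry, contrast and noise.

    Intensities are arbitrary units with the ordering cavity < brain < target
    (the target is the brightest tissue, as ChP is on T1).  The default
    target fraction of 0.2 % of all voxels matches the sparsity regime of the
    real structure; 96-cube grids keep desk-scale training fast while
    remaining divisible by 8 (4 network levels).
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    cavity_count: int = 2
    target_volume_fraction: float = 0.002
    background_level: float = 0.0
    brain_level: float = 0.5
    cavity_level: float = 0.12
    target_level: float = 1.0
    tube_radius: int = 1
    smoothing_mm: float = 0.6
    noise_std: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_volume_fraction < 0.05:
            raise ValueError("target_volume_fraction must be in (0, 5%)")
        if not self.cavity_level < self.brain_level < self.target_level:
            raise ValueError("contrast ordering must be cavity < brain < target")
        if self.cavity_count < 1:
            raise ValueError("cavity_count must be >= 1")
        if any(n < 16 for n in self.shape):
            raise ValueError("phantom shape must be at least 16 voxels per axis")


def _ellipsoid(shape, center, radii) -> np.ndarray:
    coords = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    acc = np.zeros(shape, dtype=float)
    for c, c0, r in zip(coords, center, radii):
        acc += ((c - c0) / r) ** 2
    return acc <= 1.0


def _tube_walk(region: np.ndarray, quota: int, radius: int,
               rng: np.random.Generator) -> np.ndarray:
    """Momentum-driven random walk inside ``region``, dilated to a tube.

    Grows until ``quota`` voxels are marked or a step budget is exhausted.
    """
    ball = _ellipsoid(
        (2 * radius + 1,) * 3, (radius,) * 3, (radius + 0.5,) * 3
    )
    interior = ndimage.binary_erosion(region, iterations=max(1, radius))
    if not interior.any():
        raise ValueError(
            "target structure does not fit: cavity too small for the tube "
            "radius; use larger cavities or a smaller tube"
        )
    idx = np.argwhere(interior)
    pos = idx[int(rng.integers(len(idx)))].astype(float)
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    mask = np.zeros(region.shape, dtype=bool)
    shape = np.asarray(region.shape)
    max_steps = quota * 30
    for _ in range(max_steps):
        vox = np.clip(np.rint(pos).astype(int), 0, shape - 1)
        if interior[tuple(vox)]:
            lo = vox - radius
            hi = vox + radius + 1
            blo = np.maximum(-lo, 0)
            lo = np.maximum(lo, 0)
            bhi = ball.shape[0] - np.maximum(hi - shape, 0)
            hi = np.minimum(hi, shape)
            sl = tuple(slice(a, b) for a, b in zip(lo, hi))
            bsl = tuple(slice(a, b) for a, b in zip(blo, bhi))
            mask[sl] |= ball[bsl]
            if mask.sum() >= quota:
                break
            step = 0.8 * direction + 0.6 * rng.standard_normal(3)
            step /= max(np.linalg.norm(step), 1e-9)
            direction = step
            pos = pos + step
        else:
            # bounced off the cavity wall: restart direction from inside
            pos = np.clip(pos, 0, shape - 1)
            nearest = idx[np.argmin(((idx - pos) ** 2).sum(axis=1))]
            pos = nearest.astype(float)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
    return mask & region


def generate_phantom(p: PhantomParams = PhantomParams()) -> tuple[Volume, LabelMask]:
    """One phantom volume plus its ground-truth target mask."""
    rng = np.random.default_rng(p.seed)
    shape = np.asarray(p.shape)
    total = int(np.prod(shape))

    center = shape / 2.0 + rng.uniform(-0.02, 0.02, 3) * shape
    brain = _ellipsoid(p.shape, center, shape * rng.uniform(0.40, 0.44, 3))

    cavities = np.zeros(p.shape, dtype=bool)
    cavity_list = []
    offsets = np.linspace(-0.17, 0.17, p.cavity_count) if p.cavity_count > 1 else [0.0]
    for off in offsets:
        c = center + np.array([off * shape[0], 0.0, 0.0])
        c += rng.uniform(-0.02, 0.02, 3) * shape
        radii = shape * (np.array([0.10, 0.20, 0.14]) * rng.uniform(0.9, 1.1, 3))
        cav = _ellipsoid(p.shape, c, radii) & brain
        cavity_list.append(cav)
        cavities |= cav

    quota_total = int(round(p.target_volume_fraction * total))
    quota_each = max(1, quota_total // len(cavity_list))
    capacity = int(cavities.sum())
    if quota_total > 0.5 * capacity:
        raise ValueError(
            f"requested target fraction {p.target_volume_fraction:.4f} needs "
            f"{quota_total} voxels but the cavities hold only {capacity}; "
            "use larger cavities or a smaller fraction"
        )
    mask = np.zeros(p.shape, dtype=bool)
    for cav in cavity_list:
        mask |= _tube_walk(cav, quota_each, p.tube_radius, rng)

    achieved = int(mask.sum())
    if not 0.5 * quota_total <= achieved <= 1.5 * quota_total:
        raise ValueError(
            f"achieved target volume {achieved} outside +-50% of the requested "
            f"{quota_total}; use larger cavities"
        )

    img = np.full(p.shape, p.background_level, dtype=np.float32)
    img[brain] = p.brain_level
    img[cavities] = p.cavity_level
    img[mask] = p.target_level
    if p.smoothing_mm > 0:
        img = ndimage.gaussian_filter(img, sigma=p.smoothing_mm)
    if p.noise_std > 0:
        img = img + rng.normal(0.0, p.noise_std, p.shape).astype(np.float32)

    vol = Volume.from_spacing(img.astype(np.float32))
    gt = LabelMask(mask.astype(np.uint8), vol.affine.copy())
    return vol, gt


def generate_cohort(
    n: int, base: PhantomParams = PhantomParams(), seed: int = 0
) -> list[tuple[Volume, LabelMask]]:
    """``n`` phantoms with heterogeneous target volumes.

    Target fractions are drawn uniformly in [0.5x, 1.5x] of the base value so
    ground-truth volumes vary across subjects (needed for volume-correlation
    statistics); per-subject seeds derive deterministically from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    fractions = base.target_volume_fraction * rng.uniform(0.5, 1.5, n)
    seeds = rng.integers(0, 2 ** 31, n)
    out = []
    for f, s in zip(fractions, seeds):
        out.append(
            generate_phantom(
                replace(base, target_volume_fraction=float(f), seed=int(s))
            )
        )
    return out
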