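"""The two-step coarse-to-fine inference pipeline.

Step 1 segments the whole volume down-sampled to a coarse grid
(72 x 96 x 104 by default).  Every coarse voxel whose foreground probability
exceeds 0.8 becomes a candidate patch centre at full resolution; at most 500
centres are kept (a uniform random subset when there are more, so nearby
patches may overlap).  Step 2 segments each 48-cube patch, and the patch
probabilities are blended back into a whole-volume map: each patch is
multiplied by a separable 3D Hann window and accumulated, the windows are
accumulated in a parallel weight mask, and the accumulator is divided by the
weights.  Binarizing the blended map at 0.5 gives the final mask.

A 1-step baseline (one whole-volume forward pass, then binarize) is provided
for comparison.  The networks are passed as callables from a 3D grid to a
3D probability grid, so ground-truth oracles can stand in for trained
networks in pipeline-fidelity tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter as _gaussian_filter
from scipy.signal.windows import hann as _hann1d

from chpseg.io_preproc import LabelMask, Volume, _zoom_to_shape

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CascadeConfig:
    """Cascade hyperparameters (defaults are the method's operating point)."""

    lowres_shape: tuple[int, int, int] = (72, 96, 104)
    patch_size: int = 48
    seed_threshold: float = 0.8
    max_patches: int = 500
    binarize_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.seed_threshold < 1:
            raise ValueError("seed_threshold must be in (0, 1)")
        if self.max_patches < 1:
            raise ValueError("max_patches must be >= 1")
        if self.patch_size < 2:
            raise ValueError("patch_size must be >= 2")


@dataclass
class ProbabilityMap:
    """A rank-3 grid of foreground probabilities in [0, 1] with geometry."""

    grid: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise ValueError(f"probability map must be rank 3, got {self.grid.ndim}")
        if self.grid.size and (self.grid.min() < 0 or self.grid.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def shape(self):
        return self.grid.shape


@dataclass(frozen=True)
class PatchLocation:
    """A candidate patch centre, as a voxel index in the full-resolution grid."""

    center: tuple[int, int, int]


@dataclass
class Patch:
    """A cubic sub-grid plus its low-corner origin in the full grid."""

    origin: tuple[int, int, int]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        s = self.data.shape
        if len(s) != 3 or len(set(s)) != 1:
            raise ValueError(f"patch data must be a cube, got shape {s}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def downsample(v: Volume, lowres_shape=(72, 96, 104)) -> Volume:
    """Anti-aliased linear down-sampling of a preprocessed volume.

    A Gaussian pre-filter at sigma = (factor - 1) / 2 per axis keeps thin
    structures visible in the coarse grid instead of being aliased away by
    point sampling; the subsequent interpolation is linear.
    """
    lowres_shape = tuple(int(n) for n in lowres_shape)
    for ax, (lo, n) in enumerate(zip(lowres_shape, v.shape)):
        if lo > n:
            raise ValueError(
                f"lowres_shape exceeds input shape on axis {ax} ({lo} > {n})"
            )
    factors = np.asarray(v.shape, dtype=float) / np.asarray(lowres_shape)
    sigma = np.maximum(0.0, (factors - 1.0) / 2.0)
    grid = v.grid
    if np.any(sigma > 0):
        grid = _gaussian_filter(grid, sigma)
    grid = _zoom_to_shape(grid, lowres_shape, order=1)
    scale = np.asarray(v.shape) / np.asarray(lowres_shape)
    affine = v.affine.copy()
    affine[:3, :3] = affine[:3, :3] * scale[None, :]
    return Volume(grid, affine)


def find_seed_voxels(p, threshold: float, highres_shape) -> list[PatchLocation]:
    """Coarse voxels with probability strictly above threshold, mapped to

    full resolution by scaling each index by (highres extent / lowres extent)
    and rounding to nearest.  Order is lexicographic by coarse index.
    """
    grid = p.grid if isinstance(p, ProbabilityMap) else np.asarray(p)
    idx = np.argwhere(grid > threshold)  # argwhere is lexicographic
    if idx.size == 0:
        return []
    scale = np.asarray(highres_shape, dtype=float) / np.asarray(grid.shape)
    full = np.rint(idx * scale[None, :]).astype(int)
    full = np.clip(full, 0, np.asarray(highres_shape) - 1)
    return [PatchLocation(tuple(int(c) for c in row)) for row in full]


def sample_patch_locations(
    candidates: list[PatchLocation], max_patches: int, rng: np.random.Generator
) -> list[PatchLocation]:
    """All candidates if within the cap, else a uniform subset (no replacement)."""
    if len(candidates) <= max_patches:
        return list(candidates)
    pick = rng.choice(len(candidates), size=max_patches, replace=False)
    return [candidates[int(i)] for i in pick]


def extract_patch(v, loc: PatchLocation, patch_size: int = 48) -> Patch:
    """A patch_size cube nominally centred on ``loc``; near a border the

    origin is clamped so the patch lies fully inside the grid.
    """
    grid = v.grid if hasattr(v, "grid") else np.asarray(v)
    for ax, n in enumerate(grid.shape):
        if patch_size > n:
            raise ValueError(
                f"patch_size {patch_size} exceeds volume extent {n} on axis {ax}"
            )
    origin = []
    for c, n in zip(loc.center, grid.shape):
        o = int(c) - patch_size // 2
        origin.append(int(np.clip(o, 0, n - patch_size)))
    sl = tuple(slice(o, o + patch_size) for o in origin)
    return Patch(tuple(origin), np.asarray(grid[sl], dtype=np.float32))


def hann_window(patch_size: int = 48) -> np.ndarray:
    """Separable 3D raised-cosine blending weight, strictly positive.

    The 1D profile is the Hann window sampled at interior points,
    ``0.5 * (1 - cos(2*pi*(i+1)/(n+1)))`` for ``i = 0..n-1``, so edge voxels
    of an isolated patch keep nonzero weight and the divide-by-weight
    normalization is defined everywhere a patch covers.
    """
    if patch_size < 2:
        raise ValueError("patch_size must be >= 2")
    w1 = _hann1d(patch_size + 2, sym=True)[1:-1].astype(np.float32)
    return (w1[:, None, None] * w1[None, :, None] * w1[None, None, :]).astype(np.float32)


def merge_patches(patches: list[Patch], output_shape) -> ProbabilityMap:
    """Hann-weighted blending of (possibly overlapping) patch probabilities.

    accumulator = sum(window * patch), weights = sum(window); the output is
    accumulator / weights where covered and 0 elsewhere, so at every covered
    voxel the result is a convex combination of the contributing patches.
    """
    acc = np.zeros(tuple(output_shape), dtype=np.float64)
    wgt = np.zeros(tuple(output_shape), dtype=np.float64)
    if not patches:
        log.warning("merge_patches called with no patches: returning all-zero map")
        return ProbabilityMap(acc.astype(np.float32), np.eye(4))
    win_cache: dict[int, np.ndarray] = {}
    for p in patches:
        ps = p.data.shape[0]
        win = win_cache.setdefault(ps, hann_window(ps).astype(np.float64))
        sl = tuple(slice(o, o + ps) for o in p.origin)
        for s, n in zip(sl, acc.shape):
            if s.stop > n or s.start < 0:
                raise ValueError(f"patch at origin {p.origin} exceeds output shape")
        acc[sl] += win * p.data
        wgt[sl] += win
    out = np.where(wgt > 0, acc / np.where(wgt > 0, wgt, 1.0), 0.0)
    return ProbabilityMap(np.clip(out, 0.0, 1.0).astype(np.float32), np.eye(4))


def binarize(p: ProbabilityMap, threshold: float = 0.5) -> LabelMask:
    """Threshold a probability map: voxel -> 1 iff probability > threshold."""
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    grid = p.grid if isinstance(p, ProbabilityMap) else np.asarray(p)
    affine = p.affine if isinstance(p, ProbabilityMap) else np.eye(4)
    return LabelMask((grid > threshold).astype(np.uint8), affine)


def predict_two_step(
    v: Volume,
    net1,
    net2,
    cfg: CascadeConfig = CascadeConfig(),
    rng: np.random.Generator | None = None,
    batch_size: int = 4,
) -> tuple[ProbabilityMap, LabelMask]:
    """Full coarse-to-fine inference on a preprocessed volume.

    ``net1`` and ``net2`` are callables from a 3D grid to a 3D probability
    grid (trained networks or oracles).  When step 1 finds no seed voxel, an
    all-zero map and empty mask are returned with a logged warning.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    low = downsample(v, cfg.lowres_shape)
    prob_low = np.asarray(net1(low.grid), dtype=np.float32)
    candidates = find_seed_voxels(prob_low, cfg.seed_threshold, v.shape)
    if not candidates:
        log.warning(
            "step1 produced no voxel above %.2f: returning empty segmentation",
            cfg.seed_threshold,
        )
        zero = ProbabilityMap(np.zeros(v.shape, dtype=np.float32), v.affine.copy())
        return zero, LabelMask(np.zeros(v.shape, dtype=np.uint8), v.affine.copy())
    locs = sample_patch_locations(candidates, cfg.max_patches, rng)
    patches_in = [extract_patch(v, loc, cfg.patch_size) for loc in locs]
    preds: list[Patch] = []
    forward_batch = getattr(net2, "forward", None)
    for i in range(0, len(patches_in), batch_size):
        chunk = patches_in[i:i + batch_size]
        if forward_batch is not None:
            batch = np.stack([p.data for p in chunk])[:, None]
            probs = forward_batch(batch)[:, 0]
            preds.extend(Patch(p.origin, pr) for p, pr in zip(chunk, probs))
        else:
            preds.extend(Patch(p.origin, np.asarray(net2(p.data))) for p in chunk)
    merged = merge_patches(preds, v.shape)
    merged.affine = v.affine.copy()
    return merged, binarize(merged, cfg.binarize_threshold)


def predict_one_step(
    v: Volume, net, cfg: CascadeConfig = CascadeConfig()
) -> tuple[ProbabilityMap, LabelMask]:
    """Single whole-volume forward pass, then binarize (the 1-step baseline)."""
    prob = ProbabilityMap(np.asarray(net(v.grid), dtype=np.float32), v.affine.copy())
    return prob, binarize(prob, cfg.binarize_threshold)
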