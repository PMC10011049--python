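"""NIfTI I/O and the deterministic preprocessing chain.

Every input volume is brought into a fixed analysis space before any network
sees it: reorientation to canonical (RAS+) axes so that left-right is the
first array dimension, resampling to isotropic 1 mm voxels, centered
cropping/padding to a fixed grid of (176, 240, 256), and a robust linear
intensity rescale to [-1, 1] that ignores the extreme 0.5 % tails.  Each
spatial step writes what it did into a :class:`PreprocessRecord` so that
predictions can be mapped back into the scanner-native voxel grid.

Masks travel through the same spatial chain with nearest-neighbour
interpolation and skip the intensity rescale, so they stay strictly binary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from nibabel import orientations as nio
from scipy import ndimage

log = logging.getLogger(__name__)

_CANONICAL_ORNT = np.array([[0, 1], [1, 1], [2, 1]], dtype=float)  # RAS+


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Volume:
    """A 3D intensity grid with physical geometry.

    Parameters
    ----------
    grid : ndarray, shape (X, Y, Z)
        Scalar intensities, stored as float32.
    affine : ndarray, shape (4, 4)
        Voxel-to-world map in the NIfTI convention; spacing, anatomical axis
        codes and origin are all derived from it.
    """

    grid: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise ValueError(
                f"Volume grid must be rank 3, got rank {self.grid.ndim}"
            )
        if min(self.grid.shape) < 1:
            raise ValueError(f"every axis must have length >= 1, got {self.grid.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(np.asarray(self.spacing) <= 0):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.spacing}")

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))

    @property
    def axis_codes(self) -> tuple[str, str, str]:
        """Anatomical direction label per axis, e.g. ('R', 'A', 'S')."""
        return nib.aff2axcodes(self.affine)

    @property
    def origin(self) -> tuple[float, float, float]:
        return tuple(self.affine[:3, 3])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @classmethod
    def from_spacing(cls, grid: np.ndarray, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
        """Build an RAS+ volume from a grid and per-axis spacing."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(spacing)
        aff[:3, 3] = origin
        return cls(grid, aff)


@dataclass
class LabelMask(Volume):
    """A binary mask aligned with a :class:`Volume`; values are exactly 0 or 1."""

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        vals = np.unique(g)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be exactly 0 or 1, found {vals[:10]}")
        # Volume.__post_init__ casts to float32; re-cast to uint8 after.
        super().__post_init__()
        self.grid = self.grid.astype(np.uint8)

    def matches(self, other: Volume, atol: float = 1e-4) -> bool:
        """True if shape and spacing agree with a paired volume."""
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing, atol=atol
        )


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain."""

    target_spacing: float = 1.0
    target_shape: tuple[int, int, int] = (176, 240, 256)
    rescale_interval: tuple[float, float] = (-1.0, 1.0)
    percentile_exclusion: float = 0.005  # fraction clipped at each tail

    def __post_init__(self) -> None:
        if self.target_spacing <= 0:
            raise ValueError("target_spacing must be > 0")
        if any(s < 1 for s in self.target_shape):
            raise ValueError("target_shape entries must be >= 1")
        lo, hi = self.rescale_interval
        if not lo < hi:
            raise ValueError("rescale_interval lower bound must be < upper bound")
        if not 0 <= self.percentile_exclusion < 0.5:
            raise ValueError("percentile_exclusion must be in [0, 0.5)")


@dataclass
class PreprocessRecord:
    """What the spatial preprocessing steps did, so they can be undone.

    ``crop_pad_low/high`` are signed per-axis voxel counts: positive means
    voxels were *padded* on that side, negative means voxels were cropped.
    """

    original_shape: tuple[int, int, int] | None = None
    original_spacing: tuple[float, float, float] | None = None
    original_axis_codes: tuple[str, str, str] | None = None
    ornt_transform: np.ndarray | None = None  # (3, 2) nibabel orientation transform
    pre_resample_shape: tuple[int, int, int] | None = None
    resample_factors: tuple[float, float, float] | None = None
    pre_croppad_shape: tuple[int, int, int] | None = None
    crop_pad_low: tuple[int, int, int] | None = None
    crop_pad_high: tuple[int, int, int] | None = None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_volume(path) -> Volume:
    """Read a NIfTI-1 file as a :class:`Volume`.

    4D images with a trailing singleton dimension (a common NIfTI dialect)
    are squeezed to 3D with a logged note; any other rank is rejected.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        log.info("squeezing trailing singleton dimension of 4D image %s", path)
        warnings.warn(f"4D image with trailing singleton axis squeezed to 3D: {path}")
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"expected a 3D image, got rank {data.ndim} with shape {data.shape}"
        )
    return Volume(np.asarray(data, dtype=np.float32), img.affine)


def read_mask(path) -> LabelMask:
    """Read a NIfTI-1 file as a binary :class:`LabelMask`."""
    v = read_volume(path)
    return LabelMask(v.grid.astype(np.uint8), v.affine)


def write_volume(v: Volume, path) -> None:
    """Write a Volume (float32) or LabelMask (uint8) as NIfTI-1."""
    if isinstance(v, LabelMask):
        data = v.grid.astype(np.uint8)
    else:
        data = v.grid.astype(np.float32)
    img = nib.Nifti1Image(data, v.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# preprocessing steps
# ---------------------------------------------------------------------------


def to_canonical(v: Volume) -> tuple[Volume, PreprocessRecord]:
    """Reorient to canonical RAS+ axes (left-right first, then A-P, then I-S)."""
    try:
        ornt = nio.io_orientation(v.affine)
    except Exception as e:  # pragma: no cover - nibabel raises on degenerate affines
        raise ValueError(f"unrecognized axis orientation: {e}") from e
    if np.any(np.isnan(ornt)):
        raise ValueError("unrecognized axis orientation (degenerate affine)")
    transform = nio.ornt_transform(ornt, _CANONICAL_ORNT)
    grid = nio.apply_orientation(v.grid, transform)
    affine = v.affine @ nio.inv_ornt_aff(transform, v.shape)
    rec = PreprocessRecord(
        original_shape=v.shape,
        original_spacing=v.spacing,
        original_axis_codes=v.axis_codes,
        ornt_transform=transform,
    )
    out = LabelMask(grid, affine) if isinstance(v, LabelMask) else Volume(grid, affine)
    return out, rec


def _zoom_to_shape(grid: np.ndarray, out_shape, order: int) -> np.ndarray:
    factors = [o / i for o, i in zip(out_shape, grid.shape)]
    out = ndimage.zoom(
        np.asarray(grid, dtype=np.float32), factors, order=order,
        mode="nearest", grid_mode=True, prefilter=False,
    )
    # ndimage.zoom rounds its output shape; force the exact target.
    if out.shape != tuple(out_shape):  # pragma: no cover - guard
        pads = [(0, max(0, o - s)) for o, s in zip(out_shape, out.shape)]
        out = np.pad(out, pads, mode="edge")[tuple(slice(0, o) for o in out_shape)]
    return out


def resample_isotropic(v: Volume, spacing: float = 1.0) -> Volume:
    """Resample to isotropic voxels of the given size (mm).

    The output shape per axis is ``round(shape * in_spacing / spacing)``.
    Intensities are linearly interpolated; masks use nearest neighbour.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    in_spacing = v.spacing
    out_shape = tuple(
        max(1, int(round(n * s / spacing))) for n, s in zip(v.shape, in_spacing)
    )
    order = 0 if isinstance(v, LabelMask) else 1
    grid = _zoom_to_shape(v.grid, out_shape, order)
    dirs = v.affine[:3, :3] / np.asarray(in_spacing)[None, :]
    affine = np.eye(4)
    affine[:3, :3] = dirs * spacing
    affine[:3, 3] = v.affine[:3, 3]
    if isinstance(v, LabelMask):
        return LabelMask(np.rint(grid).astype(np.uint8), affine)
    return Volume(grid, affine)


def crop_or_pad(v: Volume, target_shape=(176, 240, 256)) -> tuple[Volume, PreprocessRecord]:
    """Center-crop or center-pad each axis to the target shape.

    Odd remainders put the extra voxel on the high-index side.  The pad fill
    is the grid minimum (background) for volumes and 0 for masks.
    """
    target_shape = tuple(int(t) for t in target_shape)
    low, high = [], []
    for n, t in zip(v.shape, target_shape):
        d = t - n
        # signed: + pad, - crop; odd remainders go to the high-index side
        lo = d // 2 if d >= 0 else -((-d) // 2)
        low.append(lo)
        high.append(d - lo)
    grid = v.grid
    fill = 0 if isinstance(v, LabelMask) else float(grid.min())
    slices, pads = [], []
    for n, lo, hi in zip(v.shape, low, high):
        c_lo = max(0, -lo)
        c_hi = max(0, -hi)
        slices.append(slice(c_lo, n - c_hi))
        pads.append((max(0, lo), max(0, hi)))
    grid = grid[tuple(slices)]
    if any(p != (0, 0) for p in pads):
        grid = np.pad(grid, pads, mode="constant", constant_values=fill)
    affine = v.affine.copy()
    # shift the origin so retained voxels keep their world coordinates
    affine[:3, 3] = affine[:3, 3] - affine[:3, :3] @ np.asarray(low, dtype=float)
    rec = PreprocessRecord(
        pre_croppad_shape=v.shape,
        crop_pad_low=tuple(low),
        crop_pad_high=tuple(high),
    )
    out = LabelMask(grid, affine) if isinstance(v, LabelMask) else Volume(grid, affine)
    return out, rec


def rescale_intensity(v: Volume, cfg: PreprocessConfig = PreprocessConfig()) -> Volume:
    """Robust linear rescale to ``cfg.rescale_interval``.

    The lower/upper ``percentile_exclusion`` intensity quantiles map to the
    interval ends; values beyond them are clipped.  The map restricted to the
    inter-percentile band is strictly monotone increasing.
    """
    g = v.grid.astype(np.float64)
    p = cfg.percentile_exclusion * 100.0
    lo, hi = np.percentile(g, [p, 100.0 - p])
    if hi <= lo:
        raise ValueError(
            "degenerate intensity distribution: percentile bounds coincide "
            f"(both {lo:g}); cannot rescale a constant grid"
        )
    a, b = cfg.rescale_interval
    out = (np.clip(g, lo, hi) - lo) / (hi - lo) * (b - a) + a
    return Volume(out.astype(np.float32), v.affine.copy())


def preprocess(v: Volume, cfg: PreprocessConfig = PreprocessConfig()) -> tuple[Volume, PreprocessRecord]:
    """Full chain: reorient -> resample -> crop/pad -> rescale.

    Masks take the same spatial path (nearest-neighbour) and skip the rescale.
    """
    can, rec = to_canonical(v)
    res = resample_isotropic(can, cfg.target_spacing)
    rec.pre_resample_shape = can.shape
    rec.resample_factors = tuple(o / i for o, i in zip(res.shape, can.shape))
    out, rec2 = crop_or_pad(res, cfg.target_shape)
    rec = replace(
        rec,
        pre_croppad_shape=rec2.pre_croppad_shape,
        crop_pad_low=rec2.crop_pad_low,
        crop_pad_high=rec2.crop_pad_high,
    )
    if not isinstance(v, LabelMask):
        out = rescale_intensity(out, cfg)
    return out, rec


def invert_preprocess(grid: np.ndarray, rec: PreprocessRecord, order: int = 1) -> np.ndarray:
    """Map a grid from preprocessed space back to the native voxel grid.

    Undoes crop/pad, resampling and reorientation (in that order).  Intended
    for probability maps (``order=1``) and masks (``order=0``); the intensity
    rescale is not inverted.
    """
    g = np.asarray(grid, dtype=np.float32)
    if rec.crop_pad_low is not None:
        slices, pads = [], []
        for lo, hi in zip(rec.crop_pad_low, rec.crop_pad_high):
            slices.append(slice(max(0, lo), g.shape[len(slices)] - max(0, hi)))
            pads.append((max(0, -lo), max(0, -hi)))
        g = g[tuple(slices)]
        if any(p != (0, 0) for p in pads):
            g = np.pad(g, pads, mode="constant")
    if rec.pre_resample_shape is not None and g.shape != tuple(rec.pre_resample_shape):
        g = _zoom_to_shape(g, rec.pre_resample_shape, order)
    if rec.ornt_transform is not None:
        # apply the inverse orientation transform
        back = np.empty_like(rec.ornt_transform)
        for i, (ax, flip) in enumerate(rec.ornt_transform):
            back[int(ax)] = [i, flip]
        g = nio.apply_orientation(g, back)
    return g
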