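"""MRI-flavoured data augmentation battery.

Nine transforms, each triggered independently with its own probability:
left-right flip (p = 0.5); random affine (scale within +-0.3, rotation within
+-15 deg) ; simulated anisotropy (down-sample one axis by a factor up to 2,
then back); k-space motion (a composite of up to 2 rigidly displaced copies,
mixed in the frequency domain), ghosting (periodic modulation of every n-th
frequency plane) and spike (one high-magnitude frequency-domain point);
multiplicative polynomial bias field (order 3, coefficient magnitude up to
0.5); additive Gaussian noise (mean 0, std 1); and a power-law contrast remap
with |log gamma| <= 0.3 (all at p = 0.3).  Spatial transforms are applied
jointly to the volume and its mask (nearest-neighbour for the mask, so it
stays binary); k-space and intensity transforms touch the volume only.
Composition order is spatial -> k-space -> intensity, mirroring acquisition
physics.  Magnitudes are drawn uniformly within the stated bounds.

Elastic deformation is deliberately not part of the battery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from chpseg.io_preproc import LabelMask, Volume


@dataclass(frozen=True)
class AugmentConfig:
    flip_p: float = 0.5
    affine_p: float = 0.3
    affine_max_scale: float = 0.3
    affine_max_rotation: float = 15.0  # degrees, per axis
    aniso_p: float = 0.3
    aniso_max_downsampling: float = 2.0
    motion_p: float = 0.3
    motion_max_rotation: float = 15.0  # degrees
    motion_max_translation: float = 15.0  # mm
    motion_max_movements: int = 2
    ghost_p: float = 0.3
    ghost_n: int = 2
    ghost_max_intensity: float = 1.0
    spike_p: float = 0.3
    spike_n: int = 1
    spike_max_intensity: float = 1.0
    bias_p: float = 0.3
    bias_max_magnitude: float = 0.5
    bias_order: int = 3
    noise_p: float = 0.3
    noise_mean: float = 0.0
    noise_std: float = 1.0
    contrast_p: float = 0.3
    contrast_max_log_gamma: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "flip_p", "affine_p", "aniso_p", "motion_p", "ghost_p",
            "spike_p", "bias_p", "noise_p", "contrast_p",
        ):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in (
            "affine_max_scale", "affine_max_rotation", "aniso_max_downsampling",
            "motion_max_rotation", "motion_max_translation", "ghost_max_intensity",
            "spike_max_intensity", "bias_max_magnitude", "noise_std",
            "contrast_max_log_gamma",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _apply_rigid(grid, angles_deg, translation_vox, order, cval):
    """Resample grid under a rotation about its centre plus a translation."""
    R = _rotation_matrix(np.asarray(angles_deg, dtype=float))
    M = np.linalg.inv(R)  # output -> input map
    center = (np.asarray(grid.shape) - 1) / 2.0
    offset = center - M @ (center + np.asarray(translation_vox, dtype=float))
    return ndimage.affine_transform(
        grid, M, offset=offset, order=order, mode="constant", cval=cval,
        prefilter=False,
    )


# ---------------------------------------------------------------------------
# transform groups
# ---------------------------------------------------------------------------


def spatial_transforms(
    v: Volume, m: LabelMask, cfg: AugmentConfig, rng: np.random.Generator,
    record: dict | None = None,
) -> tuple[Volume, LabelMask]:
    """Flip / affine / anisotropy, identically applied to volume and mask.

    When ``record`` is given, a boolean per transform name is written into it
    saying whether that transform fired on this draw.
    """
    if not m.matches(v):
        raise ValueError("volume and mask are not aligned")
    g = v.grid.copy()
    gm = m.grid.copy()
    cval = float(g.min())

    _f = rng.random() < cfg.flip_p
    if record is not None:
        record["flip"] = bool(_f)
    if _f:  # left-right is the first canonical axis
        g = g[::-1].copy()
        gm = gm[::-1].copy()

    _f = rng.random() < cfg.affine_p
    if record is not None:
        record["affine"] = bool(_f)
    if _f:
        scale = 1.0 + rng.uniform(-cfg.affine_max_scale, cfg.affine_max_scale)
        angles = rng.uniform(-cfg.affine_max_rotation, cfg.affine_max_rotation, 3)
        R = _rotation_matrix(angles) * scale
        M = np.linalg.inv(R)
        center = (np.asarray(g.shape) - 1) / 2.0
        offset = center - M @ center
        g = ndimage.affine_transform(
            g, M, offset=offset, order=1, mode="constant", cval=cval, prefilter=False
        )
        gm = ndimage.affine_transform(
            gm.astype(np.float32), M, offset=offset, order=0,
            mode="constant", cval=0.0, prefilter=False,
        )

    _f = rng.random() < cfg.aniso_p
    if record is not None:
        record["aniso"] = bool(_f)
    if _f:
        axis = int(rng.integers(3))
        factor = rng.uniform(1.0, cfg.aniso_max_downsampling)
        if factor > 1.0:
            n = g.shape[axis]
            small = max(1, int(round(n / factor)))
            zoom_dn = [1.0, 1.0, 1.0]
            zoom_dn[axis] = small / n
            zoom_up = [1.0, 1.0, 1.0]
            gg = ndimage.zoom(g, zoom_dn, order=1, mode="nearest", prefilter=False,
                              grid_mode=True)
            zoom_up[axis] = n / gg.shape[axis]
            g = ndimage.zoom(gg, zoom_up, order=1, mode="nearest", prefilter=False,
                             grid_mode=True)[:v.shape[0], :v.shape[1], :v.shape[2]]
            mm = ndimage.zoom(gm.astype(np.float32), zoom_dn, order=0, mode="nearest",
                              prefilter=False, grid_mode=True)
            gm = ndimage.zoom(mm, zoom_up, order=0, mode="nearest", prefilter=False,
                              grid_mode=True)[:v.shape[0], :v.shape[1], :v.shape[2]]

    return (
        Volume(g, v.affine.copy()),
        LabelMask(np.rint(gm).astype(np.uint8), m.affine.copy()),
    )


def kspace_artifacts(
    v: Volume, cfg: AugmentConfig, rng: np.random.Generator,
    record: dict | None = None,
) -> Volume:
    """Motion / ghosting / spike artifacts simulated in the frequency domain."""
    g = v.grid.astype(np.float64)

    _f = rng.random() < cfg.motion_p
    if record is not None:
        record["motion"] = bool(_f)
    if _f:
        n_mov = int(rng.integers(1, cfg.motion_max_movements + 1))
        spacing = np.asarray(v.spacing)
        copies = [g]
        for _ in range(n_mov):
            angles = rng.uniform(-cfg.motion_max_rotation, cfg.motion_max_rotation, 3)
            trans_mm = rng.uniform(
                -cfg.motion_max_translation, cfg.motion_max_translation, 3
            )
            copies.append(
                _apply_rigid(g, angles, trans_mm / spacing, order=1, cval=g.min())
            )
        axis = int(rng.integers(3))
        ks = [np.fft.fftn(c) for c in copies]
        k = np.empty_like(ks[0])
        n = g.shape[axis]
        bounds = np.linspace(0, n, len(copies) + 1).astype(int)
        sl = [slice(None)] * 3
        for ci, (b0, b1) in enumerate(zip(bounds[:-1], bounds[1:])):
            sl[axis] = slice(b0, b1)
            k[tuple(sl)] = ks[ci][tuple(sl)]
        g = np.fft.ifftn(k).real

    _f = rng.random() < cfg.ghost_p
    if record is not None:
        record["ghost"] = bool(_f)
    if _f and cfg.ghost_n > 0:
        axis = int(rng.integers(3))
        intensity = rng.uniform(0.0, cfg.ghost_max_intensity)
        k = np.fft.fftn(g)
        sl = [slice(None)] * 3
        idx = np.arange(g.shape[axis])
        planes = idx[(idx % cfg.ghost_n == 0) & (idx != 0)]  # keep the DC plane
        sl[axis] = planes
        k[tuple(sl)] *= 1.0 - intensity
        g = np.fft.ifftn(k).real

    _f = rng.random() < cfg.spike_p
    if record is not None:
        record["spike"] = bool(_f)
    if _f and cfg.spike_n > 0:
        k = np.fft.fftn(g)
        scale = np.abs(k).max()
        for _ in range(cfg.spike_n):
            pos = tuple(int(rng.integers(1, max(2, s))) for s in g.shape)
            intensity = rng.uniform(0.0, cfg.spike_max_intensity)
            phase = rng.uniform(0.0, 2 * np.pi)
            k[pos] += intensity * scale * np.exp(1j * phase)
        g = np.fft.ifftn(k).real

    return Volume(g.astype(np.float32), v.affine.copy())


def intensity_transforms(
    v: Volume, cfg: AugmentConfig, rng: np.random.Generator,
    record: dict | None = None,
) -> Volume:
    """Bias field / Gaussian noise / gamma contrast on the volume only."""
    g = v.grid.astype(np.float64)

    _f = rng.random() < cfg.bias_p
    if record is not None:
        record["bias"] = bool(_f)
    if _f:
        coords = [np.linspace(-1.0, 1.0, n) for n in g.shape]
        X, Y, Z = np.meshgrid(*coords, indexing="ij")
        field = np.zeros_like(g)
        for i in range(cfg.bias_order + 1):
            for j in range(cfg.bias_order + 1 - i):
                for k in range(cfg.bias_order + 1 - i - j):
                    if i == j == k == 0:
                        continue  # constant term would be a global gain, not shading
                    c = rng.uniform(-cfg.bias_max_magnitude, cfg.bias_max_magnitude)
                    field += c * X ** i * Y ** j * Z ** k
        g = g * np.exp(field)

    _f = rng.random() < cfg.noise_p
    if record is not None:
        record["noise"] = bool(_f)
    if _f:
        g = g + rng.normal(cfg.noise_mean, cfg.noise_std, g.shape)

    _f = rng.random() < cfg.contrast_p
    if record is not None:
        record["contrast"] = bool(_f)
    if _f:
        gamma = np.exp(
            rng.uniform(-cfg.contrast_max_log_gamma, cfg.contrast_max_log_gamma)
        )
        lo, hi = g.min(), g.max()
        if hi > lo:
            t = (g - lo) / (hi - lo)
            g = lo + np.power(t, gamma) * (hi - lo)

    return Volume(g.astype(np.float32), v.affine.copy())


def augment_pair(
    v: Volume,
    m: LabelMask,
    cfg: AugmentConfig = AugmentConfig(),
    rng: np.random.Generator | None = None,
    record: dict | None = None,
) -> tuple[Volume, LabelMask]:
    """One independent Bernoulli draw per transform, composed

    spatial -> k-space -> intensity.  Reproducible under a seeded ``rng``.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    v2, m2 = spatial_transforms(v, m, cfg, rng, record)
    v2 = kspace_artifacts(v2, cfg, rng, record)
    v2 = intensity_transforms(v2, cfg, rng, record)
    return v2, m2
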