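"""Compound loss, learning-rate schedule and the cascade training loop.

The loss is the sum of the soft Sørensen-Dice loss and binary cross entropy:

    Dice = 2 * sum_i min(x_i, y_i) / (sum_i x_i + sum_i y_i)
    DL   = 1 - Dice
    Loss = DL + BCE

For the two-step cascade the total is Loss_step1 when step 1 yields no patch
location (N = 0), and Loss_step1 + Loss_step2 otherwise, with Loss_step2
computed over the batch of patches.  Training uses Adam at an initial rate of
1e-3; the rate is halved whenever the validation loss changes by less than
1e-3 between two consecutive epochs.  During training, patch locations are
seeded from the *current* step-1 output (strict 0.8 threshold) and the patch
targets are ground-truth mask crops at the sampled locations, so step 2 only
starts learning once step 1 becomes confident — exactly the behaviour the
N = 0 branch of the loss encodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from chpseg._nn import F32, Adam
from chpseg.cascade import (
    CascadeConfig,
    downsample,
    extract_patch,
    find_seed_voxels,
    sample_patch_locations,
)
from chpseg.io_preproc import LabelMask, Volume, _zoom_to_shape
from chpseg.network import Network, NetworkSpec, build_network

log = logging.getLogger(__name__)

_BCE_EPS = 1e-7  # probability clamp, avoids log(0)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LossBreakdown:
    """Loss components; ``total = dice_loss + bce`` (summed over cascade steps)."""

    dice_loss: float
    bce: float
    total: float
    n_patches: int = 0


def soft_dice(x: np.ndarray, y: np.ndarray) -> float:
    """Soft Dice in the min formulation, 2*sum(min(x,y)) / (sum x + sum y).

    Coincides with the classic overlap Dice 2|X&Y|/(|X|+|Y|) on binary
    inputs.  Two empty inputs score 1 by convention (an empty prediction of
    an empty target is perfect).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    denom = x.sum() + y.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.minimum(x, y).sum() / denom)


def dice_loss(x: np.ndarray, y: np.ndarray) -> float:
    """DL = 1 - Dice; in [0, 1]."""
    return 1.0 - soft_dice(x, y)


def bce(x: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross entropy, with probabilities clamped to

    [1e-7, 1 - 1e-7] so perfectly confident predictions stay finite."""
    x = np.clip(np.asarray(x, dtype=np.float64), _BCE_EPS, 1.0 - _BCE_EPS)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    return float(-(y * np.log(x) + (1.0 - y) * np.log(1.0 - x)).mean())


def combined_loss(x: np.ndarray, y: np.ndarray) -> LossBreakdown:
    """Loss = DL + BCE, with the components reported separately."""
    dl = dice_loss(x, y)
    b = bce(x, y)
    return LossBreakdown(dice_loss=dl, bce=b, total=dl + b)


def cascade_loss(
    step1_pred: np.ndarray,
    step1_target: np.ndarray,
    patch_preds: list[np.ndarray],
    patch_targets: list[np.ndarray],
    n_patches: int,
) -> LossBreakdown:
    """Conditional two-step loss.

    total = Loss_step1 if N = 0, else Loss_step1 + Loss_step2, where
    Loss_step2 is the combined loss over the whole patch batch (the patch
    voxels pooled into one index set).
    """
    if len(patch_preds) != n_patches or len(patch_targets) != n_patches:
        raise ValueError(
            f"patch list lengths ({len(patch_preds)}, {len(patch_targets)}) "
            f"do not match N = {n_patches}"
        )
    l1 = combined_loss(step1_pred, step1_target)
    if n_patches == 0:
        return replace(l1, n_patches=0)
    xp = np.stack([np.asarray(p) for p in patch_preds])
    yp = np.stack([np.asarray(t) for t in patch_targets])
    l2 = combined_loss(xp, yp)
    return LossBreakdown(
        dice_loss=l1.dice_loss + l2.dice_loss,
        bce=l1.bce + l2.bce,
        total=l1.total + l2.total,
        n_patches=n_patches,
    )


def _combined_loss_grad(p: np.ndarray, y: np.ndarray) -> tuple[LossBreakdown, np.ndarray]:
    """Loss value plus d(total)/d(probability), for the training loop.

    The Dice term is differentiated with the subgradient 1[p < y] of
    min(p, y); the BCE gradient is written so that, chained through the
    sigmoid derivative, it reduces to (p - y) / n_voxels.
    """
    p64 = np.asarray(p, dtype=np.float64)
    y64 = np.asarray(y, dtype=np.float64)
    lb = combined_loss(p64, y64)
    n = p64.size
    S = p64.sum() + y64.sum()
    M = np.minimum(p64, y64).sum()
    if S > 0:
        ddice = 2.0 * ((p64 < y64).astype(np.float64) * S - M) / (S * S)
    else:
        ddice = np.zeros_like(p64)
    pc = np.clip(p64, _BCE_EPS, 1.0 - _BCE_EPS)
    dbce = (pc - y64) / (pc * (1.0 - pc)) / n
    return lb, (-ddice + dbce).astype(F32)


def lr_on_plateau(
    history: list[float], lr: float, factor: float = 0.5, delta: float = 1e-3
) -> float:
    """Halve the rate when the validation loss plateaus.

    A plateau is a change smaller than ``delta`` between the last two
    consecutive epochs.
    """
    if len(history) == 0:
        raise ValueError("history must contain at least one epoch")
    if len(history) >= 2 and abs(history[-1] - history[-2]) < delta:
        return lr * factor
    return lr


def make_step1_target(m: LabelMask, lowres_shape) -> np.ndarray:
    """Coarse binary target: nearest-neighbour down-sampling of the mask."""
    g = _zoom_to_shape(m.grid.astype(np.float32), tuple(lowres_shape), order=0)
    return np.rint(g).astype(F32)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Defaults are the method's operating point: Adam at 1e-3, plateau halving,
    200 epochs for the cascade (100 for the 1-step baseline), batches of 4
    coarse volumes and at most 16 patches per volume (so at most 64 patches
    per step-2 update).
    """

    mode: str = "2step"
    initial_lr: float = 1e-3
    plateau_factor: float = 0.5
    plateau_delta: float = 1e-3
    epochs: int = 200
    batch_lowres: int = 4
    max_patches_per_image: int = 16
    batch_patches: int = 64
    augment: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("1step", "2step"):
            raise ValueError(f"mode must be '1step' or '2step', got {self.mode!r}")
        for name in ("initial_lr", "plateau_factor", "plateau_delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epochs < 1 or self.batch_lowres < 1 or self.max_patches_per_image < 1:
            raise ValueError("epochs and batch sizes must be >= 1")


def _loss_to_dict(lb: LossBreakdown) -> dict:
    return {
        "dice_loss": lb.dice_loss,
        "bce": lb.bce,
        "total": lb.total,
        "n_patches": lb.n_patches,
    }


def _two_step_losses(net1, net2, vol, msk, cascade_cfg, rng, max_per_image):
    """Forward-only cascade loss for one validation pair."""
    low = downsample(vol, cascade_cfg.lowres_shape)
    y1 = make_step1_target(msk, cascade_cfg.lowres_shape)
    p1 = net1(low.grid)
    cands = find_seed_voxels(p1, cascade_cfg.seed_threshold, vol.shape)
    locs = sample_patch_locations(cands, max_per_image, rng)
    pp, pt = [], []
    for loc in locs:
        pp.append(net2(extract_patch(vol, loc, cascade_cfg.patch_size).data))
        pt.append(extract_patch(msk, loc, cascade_cfg.patch_size).data)
    return cascade_loss(p1, y1, pp, pt, len(locs))


def train(
    pairs: list[tuple[Volume, LabelMask]],
    cfg: TrainConfig = TrainConfig(),
    cascade_cfg: CascadeConfig = CascadeConfig(),
    val_pairs: list[tuple[Volume, LabelMask]] | None = None,
    net_spec: NetworkSpec = NetworkSpec(),
    augment_cfg=None,
) -> tuple[dict[str, Network], list[dict]]:
    """Train the cascade (or the 1-step baseline) on preprocessed pairs.

    Returns the trained networks (``{"step1", "step2"}`` or ``{"net"}``) and
    a per-epoch log of training/validation loss breakdowns and learning rate.
    Fully reproducible under ``cfg.seed`` (with augmentation off, two runs
    with the same seed produce identical logs).
    """
    if not pairs:
        raise ValueError("training set is empty")
    for v, m in pairs:
        if not m.matches(v):
            raise ValueError("volume/mask geometry mismatch in training pair")
    if cfg.augment:
        from chpseg.augment import AugmentConfig, augment_pair
        aug_cfg = augment_cfg if augment_cfg is not None else AugmentConfig()

    rng = np.random.default_rng(cfg.seed)
    lr = cfg.initial_lr
    log_rows: list[dict] = []
    val_history: list[float] = []

    if cfg.mode == "1step":
        net = build_network(net_spec, seed=int(rng.integers(2 ** 31)))
        opt = Adam(net.parameters(), lr=lr)
        nets = {"net": net}
    else:
        net1 = build_network(net_spec, seed=int(rng.integers(2 ** 31)))
        net2 = build_network(net_spec, seed=int(rng.integers(2 ** 31)))
        opt1 = Adam(net1.parameters(), lr=lr)
        opt2 = Adam(net2.parameters(), lr=lr)
        nets = {"step1": net1, "step2": net2}

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(pairs))
        epoch_losses: list[LossBreakdown] = []
        for start in range(0, len(pairs), cfg.batch_lowres):
            batch_idx = order[start:start + cfg.batch_lowres]
            batch = [pairs[i] for i in batch_idx]
            if cfg.augment:
                batch = [augment_pair(v, m, aug_cfg, rng) for v, m in batch]

            if cfg.mode == "1step":
                x = np.stack([v.grid for v, _ in batch])[:, None]
                y = np.stack([m.grid.astype(F32) for _, m in batch])[:, None]
                p = net.forward(x)
                lb, dgrad = _combined_loss_grad(p, y)
                net.backward(dgrad)
                opt.lr = lr
                opt.step(net.gradients())
                epoch_losses.append(lb)
                continue

            # ---- step 1: coarse whole-volume update -----------------------
            lows = [downsample(v, cascade_cfg.lowres_shape) for v, _ in batch]
            x1 = np.stack([lo.grid for lo in lows])[:, None]
            y1 = np.stack(
                [make_step1_target(m, cascade_cfg.lowres_shape) for _, m in batch]
            )[:, None]
            p1 = net1.forward(x1)
            lb1, dgrad1 = _combined_loss_grad(p1, y1)
            net1.backward(dgrad1)
            opt1.lr = lr
            opt1.step(net1.gradients())

            # ---- seed patches from the current step-1 output --------------
            patches_x, patches_y = [], []
            for bi, (v, m) in enumerate(batch):
                cands = find_seed_voxels(
                    p1[bi, 0], cascade_cfg.seed_threshold, v.shape
                )
                locs = sample_patch_locations(cands, cfg.max_patches_per_image, rng)
                for loc in locs:
                    patches_x.append(extract_patch(v, loc, cascade_cfg.patch_size).data)
                    patches_y.append(
                        extract_patch(m, loc, cascade_cfg.patch_size).data.astype(F32)
                    )
            n = min(len(patches_x), cfg.batch_patches)
            if n == 0:
                # N = 0: the step-2 loss is ignored and step 2 is not updated
                epoch_losses.append(cascade_loss(p1, y1, [], [], 0))
                continue
            x2 = np.stack(patches_x[:n])[:, None]
            y2 = np.stack(patches_y[:n])[:, None]
            p2 = net2.forward(x2)
            lb2, dgrad2 = _combined_loss_grad(p2, y2)
            net2.backward(dgrad2)
            opt2.lr = lr
            opt2.step(net2.gradients())
            epoch_losses.append(
                LossBreakdown(
                    dice_loss=lb1.dice_loss + lb2.dice_loss,
                    bce=lb1.bce + lb2.bce,
                    total=lb1.total + lb2.total,
                    n_patches=n,
                )
            )

        train_total = float(np.mean([l.total for l in epoch_losses]))
        row = {
            "epoch": epoch,
            "lr": lr,
            "train": {
                "dice_loss": float(np.mean([l.dice_loss for l in epoch_losses])),
                "bce": float(np.mean([l.bce for l in epoch_losses])),
                "total": train_total,
                "n_patches": int(sum(l.n_patches for l in epoch_losses)),
            },
        }

        if val_pairs:
            vrng = np.random.default_rng(cfg.seed + 100_003 + epoch)
            vls = []
            for v, m in val_pairs:
                if cfg.mode == "1step":
                    p = net(v.grid)
                    vls.append(combined_loss(p, m.grid.astype(F32)))
                else:
                    vls.append(
                        _two_step_losses(
                            net1, net2, v, m, cascade_cfg, vrng,
                            cfg.max_patches_per_image,
                        )
                    )
            val_total = float(np.mean([l.total for l in vls]))
            row["val"] = {
                "dice_loss": float(np.mean([l.dice_loss for l in vls])),
                "bce": float(np.mean([l.bce for l in vls])),
                "total": val_total,
                "n_patches": int(sum(l.n_patches for l in vls)),
            }
            val_history.append(val_total)
            lr = lr_on_plateau(val_history, lr, cfg.plateau_factor, cfg.plateau_delta)
        log_rows.append(row)
        log.info(
            "epoch %d: train %.4f%s lr %.2e", epoch, train_total,
            f" val {row['val']['total']:.4f}" if "val" in row else "", lr,
        )
    return nets, log_rows


def save_models(nets: dict[str, Network], out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, net in nets.items():
        net.save(out / f"{name}.npz")


def load_models(model_dir) -> dict[str, Network]:
    from pathlib import Path

    out = {}
    for p in sorted(Path(model_dir).glob("*.npz")):
        out[p.stem] = Network.load(p)
    if not out:
        raise FileNotFoundError(f"no model checkpoints (*.npz) in {model_dir}")
    return out
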