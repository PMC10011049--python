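"""The modified 3D U-Net shared by both cascade stages and the 1-step baseline.

Relative to the classic 3D U-Net, the convolution blocks use group
normalization (reliable at the small batch sizes 3D segmentation forces) and
a leaky ReLU, and the decoder's learned up-convolutions are replaced by
parameter-free nearest-neighbour upsampling followed by convolutions, which
removes trainable parameters.  The first convolution block produces 16
feature channels and the encoder has 4 resolution levels by default, doubling
channels at each level.  A final 1-channel convolution plus sigmoid yields a
voxelwise probability map the same shape as the input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from chpseg import _nn
from chpseg._nn import F32


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters.

    ``norm_groups`` must divide every per-block channel count (the smallest
    is ``base_filters``).  ``upsample_mode`` is ``"nearest"`` (parameter-free,
    the default) or ``"transposed"`` (learned 2x up-convolution, kept for
    parameter-count comparisons).
    """

    levels: int = 4
    base_filters: int = 16
    norm_groups: int = 8
    activation_slope: float = 0.01
    upsample_mode: str = "nearest"
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.base_filters % self.norm_groups:
            raise ValueError(
                f"norm_groups ({self.norm_groups}) must divide base_filters "
                f"({self.base_filters})"
            )
        if self.upsample_mode not in ("nearest", "transposed"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")

    @property
    def divisor(self) -> int:
        """Every input spatial extent must be divisible by this."""
        return 2 ** (self.levels - 1)


def _conv_block(c_in, c_out, spec, rng):
    return [
        _nn.Conv3d(c_in, c_out, 3, rng),
        _nn.GroupNorm(c_out, spec.norm_groups),
        _nn.LeakyReLU(spec.activation_slope),
        _nn.Conv3d(c_out, c_out, 3, rng),
        _nn.GroupNorm(c_out, spec.norm_groups),
        _nn.LeakyReLU(spec.activation_slope),
    ]


class Network:
    """A built, seeded U-Net: a callable from a 3D grid to a probability grid.

    ``forward``/``backward`` operate on batched 5D arrays (N, C, D, H, W);
    calling the network with a bare 3D grid handles the batch/channel axes
    and returns a 3D probability grid, which is the contract the cascade
    uses.
    """

    def __init__(self, spec: NetworkSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        ch = [spec.base_filters * 2 ** l for l in range(spec.levels)]
        self.enc_blocks = []
        c_prev = spec.in_channels
        for l in range(spec.levels):
            self.enc_blocks.append(_conv_block(c_prev, ch[l], spec, rng))
            c_prev = ch[l]
        self.pools = [_nn.MaxPool2() for _ in range(spec.levels - 1)]
        self.ups = []
        self.dec_blocks = []
        for l in range(spec.levels - 2, -1, -1):
            if spec.upsample_mode == "transposed":
                self.ups.append(_nn.ConvTranspose3d(ch[l + 1], ch[l + 1], rng))
            else:
                self.ups.append(_nn.UpsampleNearest2())
            self.dec_blocks.append(_conv_block(ch[l + 1] + ch[l], ch[l], spec, rng))
        self.final = _nn.Conv3d(ch[0], spec.out_channels, 1, rng)
        # sparse-foreground prior: start predictions near background so the
        # early optimization does not spend its first hundred updates just
        # pulling the whole output down
        self.final.b[...] = -2.0
        self.sigmoid = _nn.Sigmoid()

    # ------------------------------------------------------------------
    def _layers(self):
        for block in self.enc_blocks:
            yield from block
        yield from self.pools
        yield from self.ups
        for block in self.dec_blocks:
            yield from block
        yield self.final

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend(layer.params)
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend(layer.grads)
        return out

    # ------------------------------------------------------------------
    def _check_shape(self, shape) -> None:
        d = self.spec.divisor
        for ax, n in enumerate(shape):
            if n % d:
                raise ValueError(
                    f"spatial axis {ax} has extent {n}, not divisible by "
                    f"2^(levels-1) = {d}"
                )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Batched forward pass: (N, C, D, H, W) -> probabilities, same shape."""
        x = np.ascontiguousarray(x, dtype=F32)
        self._check_shape(x.shape[2:])
        skips = []
        h = x
        for l, block in enumerate(self.enc_blocks):
            for layer in block:
                h = layer.forward(h)
            if l < self.spec.levels - 1:
                skips.append(h)
                h = self.pools[l].forward(h)
        self._skip_channels = []
        for i, (up, block) in enumerate(zip(self.ups, self.dec_blocks)):
            h = up.forward(h)
            skip = skips.pop()
            self._skip_channels.append(skip.shape[1])
            h = np.concatenate([h, skip], axis=1)
            for layer in block:
                h = layer.forward(h)
        h = self.final.forward(h)
        return self.sigmoid.forward(h)

    def backward(self, dprob: np.ndarray) -> None:
        """Backpropagate d(loss)/d(probability); fills layer gradients."""
        d = self.sigmoid.backward(dprob)
        d = self.final.backward(d)
        # decoder stage i handled encoder level l = levels-2-i
        dskips: dict[int, np.ndarray] = {}
        for i in range(len(self.ups) - 1, -1, -1):
            for layer in reversed(self.dec_blocks[i]):
                d = layer.backward(d)
            c_skip = self._skip_channels[i]
            d, dskip = d[:, :-c_skip], d[:, -c_skip:]
            dskips[self.spec.levels - 2 - i] = dskip
            d = self.ups[i].backward(np.ascontiguousarray(d))
        self._skip_channels = []
        for l in range(self.spec.levels - 1, -1, -1):
            if l < self.spec.levels - 1:
                d = self.pools[l].backward(d)
                d = d + dskips.pop(l)
            for layer in reversed(self.enc_blocks[l]):
                d = layer.backward(d)

    def __call__(self, grid: np.ndarray) -> np.ndarray:
        """Predict a 3D probability grid from a 3D intensity grid."""
        g = np.asarray(grid, dtype=F32)
        if g.ndim != 3:
            raise ValueError(f"expected a 3D grid, got rank {g.ndim}")
        return self.forward(g[None, None])[0, 0]

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Serialize parameters (.npz) with the spec alongside as JSON."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, *self.parameters())
        path.with_suffix(".json").write_text(
            json.dumps({"spec": asdict(self.spec), "seed": self.seed}, indent=2)
        )

    @classmethod
    def load(cls, path) -> "Network":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        net = cls(NetworkSpec(**meta["spec"]), meta["seed"])
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
            arrays = [z[k] for k in z.files]
        for p, a in zip(net.parameters(), arrays, strict=True):
            p[...] = a
        return net


def build_network(spec: NetworkSpec = NetworkSpec(), seed: int = 0) -> Network:
    """Construct a seeded, deterministically initialized U-Net."""
    return Network(spec, seed)


def count_parameters(net: Network) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.size for p in net.parameters()))
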