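"""The 3D encoder-decoder segmentation backend (one binary model per
structure) and its checkpoint format.

The network is a symmetric U-shaped net: each encoder level halves the
resolution and doubles the channel count, the decoder mirrors it with
nearest-neighbour up-sampling and skip concatenations, and a 1x1x1 head
with a sigmoid yields a per-voxel foreground probability.  With
``residual_blocks`` enabled each level becomes a two-convolution block
with a shortcut connection (projected when channel counts differ).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ..errors import ValidationError
from ..volgrid import LabelMap, Volume
from .layers import Conv1, Conv3, Layer, MaxPool2, ReLU, Upsample2, sigmoid

CHECKPOINT_SCHEMA = "tbseg-segmodel-1"


@dataclass(frozen=True)
class NetConfig:
    depth: int = 3
    base_channels: int = 8
    residual_blocks: bool = False
    patch_shape: tuple[int, int, int] = (32, 32, 32)

    def __post_init__(self):
        if self.depth < 2:
            raise ValidationError(f"depth must be >= 2, got {self.depth}")
        if self.base_channels < 4:
            raise ValidationError(f"base_channels must be >= 4, got {self.base_channels}")
        factor = 2 ** (self.depth - 1)
        if any(n % factor != 0 or n < factor for n in self.patch_shape):
            raise ValidationError(
                f"patch_shape {self.patch_shape} must be divisible by 2^(depth-1)={factor}"
            )

    @property
    def pool_factor(self) -> int:
        return 2 ** (self.depth - 1)


class _Block:
    """One level: conv+relu, or a two-conv residual block with shortcut."""

    def __init__(self, c_in: int, c_out: int, residual: bool, rng: np.random.Generator):
        self.residual = residual
        self.conv1 = Conv3(c_in, c_out, rng)
        self.relu1 = ReLU()
        if residual:
            self.conv2 = Conv3(c_out, c_out, rng)
            self.proj = Conv1(c_in, c_out, rng) if c_in != c_out else None
            self.relu2 = ReLU()

    def layers(self) -> list[Layer]:
        out: list[Layer] = [self.conv1]
        if self.residual:
            out.append(self.conv2)
            if self.proj is not None:
                out.append(self.proj)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.relu1.forward(self.conv1.forward(x))
        if not self.residual:
            return h
        h2 = self.conv2.forward(h)
        short = x if self.proj is None else self.proj.forward(x)
        return self.relu2.forward(h2 + short)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if not self.residual:
            return self.conv1.backward(self.relu1.backward(gout))
        g = self.relu2.backward(gout)
        gx_short = g if self.proj is None else self.proj.backward(g)
        gh = self.conv2.backward(g)
        gx = self.conv1.backward(self.relu1.backward(gh))
        return gx + gx_short


class UNet3D:
    """Forward/backward network; parameters live in the layer objects."""

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(10,)))
        c = config.base_channels
        res = config.residual_blocks
        self.enc: list[_Block] = []
        self.pools: list[MaxPool2] = []
        c_prev = 1
        for i in range(config.depth - 1):
            self.enc.append(_Block(c_prev, c * 2**i, res, rng))
            self.pools.append(MaxPool2())
            c_prev = c * 2**i
        self.bottleneck = _Block(c_prev, c * 2 ** (config.depth - 1), res, rng)
        self.ups: list[Upsample2] = []
        self.dec: list[_Block] = []
        for i in reversed(range(config.depth - 1)):
            self.ups.append(Upsample2())
            skip_c = c * 2**i
            up_c = c * 2 ** (i + 1)
            self.dec.append(_Block(skip_c + up_c, skip_c, res, rng))
        self.head = Conv1(c, 1, rng)
        # start near the sparse-foreground prior; a 0.5 start makes the
        # Dice loss spend many epochs just suppressing background
        self.head.b[...] = -2.0

    # -- parameter plumbing -------------------------------------------------
    def _layers(self) -> list[Layer]:
        out: list[Layer] = []
        for b in self.enc:
            out.extend(b.layers())
        out.extend(self.bottleneck.layers())
        for b in self.dec:
            out.extend(b.layers())
        out.append(self.head)
        return out

    def params(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self._layers() for g in layer.grads()]

    def zero_grads(self) -> None:
        for layer in self._layers():
            layer.zero_grads()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (1, D, H, W) in [0,1]; returns per-voxel probability."""
        skips = []
        h = x.astype(np.float32, copy=False)
        for block, pool in zip(self.enc, self.pools):
            h = block.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        self._skip_channels = []
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([skip, h], axis=0)
            self._skip_channels.append(skip.shape[0])
            h = block.forward(h)
        z = self.head.forward(h)
        self._p = sigmoid(z)
        return self._p

    def backward(self, gp: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dProbability."""
        gz = gp * self._p * (1.0 - self._p)
        g = self.head.backward(gz.astype(np.float32))
        gskips = []
        for up, block, skip_c in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_channels)
        ):
            g = block.backward(g)
            gskips.append(g[:skip_c])
            g = up.backward(g[skip_c:])
        g = self.bottleneck.backward(g)
        for block, pool, gskip in zip(reversed(self.enc), reversed(self.pools), reversed(gskips)):
            g = pool.backward(g)
            g = block.backward(g + gskip)


@dataclass
class SegModel:
    """A (possibly trained) binary segmentation backend for one structure."""

    net_config: NetConfig
    structure_name: str
    net: UNet3D
    seed: int = 0
    training_curve: list[tuple[float, float]] = field(default_factory=list)  # (loss, dsc)


def build_model(net_config: NetConfig, seed: int = 0, structure_name: str = "inner_ear") -> SegModel:
    """An untrained model with seed-reproducible initialization."""
    return SegModel(
        net_config=net_config,
        structure_name=structure_name,
        net=UNet3D(net_config, seed=seed),
        seed=int(seed),
    )


def predict(model: SegModel, volume: Volume) -> Volume:
    """Per-voxel foreground probability on the input grid.

    The grid is zero-padded up to the network's pooling divisibility and
    cropped back, so arbitrary shapes work.
    """
    x = np.asarray(volume.values, dtype=np.float32)[None]
    factor = model.net_config.pool_factor
    shape = x.shape[1:]
    pad = [(0, (-n) % factor) for n in shape]
    x = np.pad(x, [(0, 0)] + pad)
    p = model.net.forward(x)
    p = p[0, : shape[0], : shape[1], : shape[2]]
    return volume.with_values(p.astype(np.float32))


def binarize(probabilities: Volume, threshold: float = 0.5) -> LabelMap:
    """Threshold a probability volume into a LabelMap (p >= threshold)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError(f"threshold must be in [0,1], got {threshold}")
    p = np.asarray(probabilities.values)
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValidationError("probability volume has values outside [0,1]")
    return LabelMap.like(probabilities, (p >= threshold).astype(np.uint8))


# -- checkpoint I/O ---------------------------------------------------------

def save_model(model: SegModel, path) -> None:
    """Single-file checkpoint: JSON manifest + weight arrays (npz)."""
    manifest = {
        "schema": CHECKPOINT_SCHEMA,
        "structure_name": model.structure_name,
        "seed": model.seed,
        "net_config": {
            "depth": model.net_config.depth,
            "base_channels": model.net_config.base_channels,
            "residual_blocks": model.net_config.residual_blocks,
            "patch_shape": list(model.net_config.patch_shape),
        },
        "training_curve": [[float(a), float(b)] for a, b in model.training_curve],
    }
    arrays = {f"param_{i:04d}": p for i, p in enumerate(model.net.params())}
    np.savez(path, manifest=json.dumps(manifest), **arrays)


def load_model(path) -> SegModel:
    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(str(data["manifest"]))
        if manifest.get("schema") != CHECKPOINT_SCHEMA:
            raise ValidationError(f"unknown checkpoint schema {manifest.get('schema')!r}")
        nc = manifest["net_config"]
        net_config = NetConfig(
            depth=nc["depth"],
            base_channels=nc["base_channels"],
            residual_blocks=nc["residual_blocks"],
            patch_shape=tuple(nc["patch_shape"]),
        )
        model = build_model(net_config, seed=manifest["seed"], structure_name=manifest["structure_name"])
        params = model.net.params()
        keys = sorted(k for k in data.files if k.startswith("param_"))
        if len(keys) != len(params):
            raise ValidationError("checkpoint parameter count does not match architecture")
        for p, k in zip(params, keys):
            arr = data[k]
            if arr.shape != p.shape:
                raise ValidationError("checkpoint parameter shape mismatch")
            p[...] = arr
        model.training_curve = [tuple(x) for x in manifest["training_curve"]]
    return model
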