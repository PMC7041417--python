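"""Three-level 3D U-Net for intra-tumor segmentation of gliomas.

The network follows the encoder/decoder layout used for multi-channel MR
patches: a contracting path with 48/96/192 feature maps at the three levels,
a symmetric expanding path with skip concatenations, same-size zero padding
everywhere, and a final 1x1x1 convolution producing four per-voxel class
probability maps (background, necrosis/non-enhancing, edema, enhancing
tumor) fused by argmax.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .io_preprocess import LabelVolume, MultiChannelVolume, contiguous_to_brats


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters; defaults are the reference configuration."""

    levels: int = 3
    features: tuple[int, ...] = (48, 96, 192)
    convs_per_block: int = 2
    kernel: int = 3
    in_channels: int = 4
    out_classes: int = 4
    dropout: float = 0.25
    batch_norm: bool = False

    def __post_init__(self):
        if len(self.features) != self.levels:
            raise ValueError(
                f"features must list one width per level: "
                f"{len(self.features)} widths for {self.levels} levels"
            )
        if any(b <= a for a, b in zip(self.features, self.features[1:])):
            raise ValueError(f"features must be strictly increasing, got {self.features}")
        if self.out_classes != 4:
            raise ValueError("the segmentation task has exactly 4 classes")
        if self.convs_per_block < 1 or self.kernel % 2 == 0:
            raise ValueError("convs_per_block >= 1 and an odd kernel are required")

    @property
    def divisor(self) -> int:
        """Input patch edges must be divisible by this (one pooling per level)."""
        return 2 ** (self.levels - 1)


class UNet3D:
    """U-Net with explicit forward/backward wiring over the nn layer primitives."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        f = config.features
        k = config.kernel
        L = config.levels

        def block(in_ch: int, out_ch: int) -> list:
            layers: list = []
            for j in range(config.convs_per_block):
                layers.append(nn.Conv3d(in_ch if j == 0 else out_ch, out_ch, k, rng))
                if config.batch_norm:
                    layers.append(nn.BatchNorm3d(out_ch))
                layers.append(nn.ReLU())
            return layers

        self.enc = []
        for lvl in range(L):
            in_ch = config.in_channels if lvl == 0 else f[lvl - 1]
            layers = block(in_ch, f[lvl])
            layers.append(nn.Dropout(config.dropout))
            self.enc.append(layers)
        self.pools = [nn.MaxPool3d() for _ in range(L - 1)]

        # decoder step i upsamples from level L-1-i to level L-2-i
        self.ups, self.upconvs, self.uprelus, self.dec = [], [], [], []
        for i in range(L - 1):
            lvl = L - 2 - i
            self.ups.append(nn.Upsample3d())
            self.upconvs.append(nn.Conv3d(f[lvl + 1], f[lvl], k, rng))
            self.uprelus.append(nn.ReLU())
            self.dec.append(block(2 * f[lvl], f[lvl]))

        self.final = nn.Conv3d(f[0], config.out_classes, 1, rng)
        self._p = None

    # -- plumbing ---------------------------------------------------------

    def _layers(self):
        for blk in self.enc:
            yield from blk
        yield from self.pools
        for i in range(len(self.dec)):
            yield self.ups[i]
            yield self.upconvs[i]
            yield self.uprelus[i]
            yield from self.dec[i]
        yield self.final

    def param_layers(self):
        """Layers holding trainable parameters, in a fixed deterministic order."""
        return [l for l in self._layers() if hasattr(l, "params_and_grads")]

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.param_layers())

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.param_layers()):
            for name, p, _ in layer.params_and_grads():
                out[f"layer{i:03d}.{name}"] = p
        return out

    # -- forward / backward ----------------------------------------------

    def _check_input(self, x: np.ndarray):
        if x.ndim != 5 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected input of shape (N, {self.config.in_channels}, D, H, W), "
                f"got {x.shape}"
            )
        d = self.config.divisor
        if any(s % d for s in x.shape[2:]):
            raise ValueError(
                f"patch edges {x.shape[2:]} must each be divisible by {d} "
                f"for a {self.config.levels}-level network"
            )

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Return per-voxel class probabilities, shape (N, 4, D, H, W)."""
        self._check_input(x)
        # layers run channels-last internally; the public contract is channels-first
        x = np.ascontiguousarray(np.asarray(x, np.float32).transpose(0, 2, 3, 4, 1))
        for blk in self.enc:
            for layer in blk:
                if isinstance(layer, nn.Dropout):
                    layer.rng = rng
        L = self.config.levels
        skips = []
        for lvl in range(L):
            for layer in self.enc[lvl]:
                x = layer.forward(x, train)
            if lvl < L - 1:
                skips.append(x)
                x = self.pools[lvl].forward(x, train)
        for i in range(L - 1):
            x = self.ups[i].forward(x, train)
            x = self.upconvs[i].forward(x, train)
            x = self.uprelus[i].forward(x, train)
            x = np.concatenate([skips.pop(), x], axis=-1)
            for layer in self.dec[i]:
                x = layer.forward(x, train)
        z = self.final.forward(x, train)
        p = nn.softmax_channels(z, axis=-1)
        if train:
            self._p = p
        return np.ascontiguousarray(p.transpose(0, 4, 1, 2, 3))

    def backward(self, gp: np.ndarray) -> None:
        """Backpropagate dL/dprobabilities; fills every layer's gradients."""
        p, self._p = self._p, None
        if p is None:
            raise RuntimeError("backward requires a preceding forward(train=True)")
        gp = np.ascontiguousarray(np.asarray(gp, np.float32).transpose(0, 2, 3, 4, 1))
        g = nn.softmax_backward(p, gp, axis=-1)
        g = self.final.backward(g)
        L = self.config.levels
        skip_grads: dict[int, np.ndarray] = {}
        for i in range(L - 2, -1, -1):
            lvl = L - 2 - i
            for layer in reversed(self.dec[i]):
                g = layer.backward(g)
            fwidth = self.config.features[lvl]
            skip_grads[lvl] = g[..., :fwidth]
            g = np.ascontiguousarray(g[..., fwidth:])
            g = self.uprelus[i].backward(g)
            g = self.upconvs[i].backward(g)
            g = self.ups[i].backward(g)
        for lvl in range(L - 1, -1, -1):
            if lvl < L - 1:
                g = self.pools[lvl].backward(g) + skip_grads[lvl]
            for layer in reversed(self.enc[lvl]):
                g = layer.backward(g)


def build_unet(config: UNetConfig | None = None, seed: int = 0) -> UNet3D:
    """Construct a U-Net with seeded weight initialisation."""
    return UNet3D(config or UNetConfig(), seed=seed)


def predict_patch(model: UNet3D, patch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict one 4-channel patch.

    Returns ``(probabilities, labels)`` where probabilities has shape
    (4, D, H, W) and labels is the per-voxel argmax over the four maps in
    the contiguous class convention (0..3); exact probability ties resolve
    to the lowest class index.
    """
    if patch.ndim != 4:
        raise ValueError(f"expected a (C, D, H, W) patch, got shape {patch.shape}")
    p = model.forward(patch[None], train=False)[0]
    return p, p.argmax(axis=0).astype(np.int16)


def predict_volume(model: UNet3D, volume: MultiChannelVolume,
                   patch_size: int = 64, batch_size: int = 4) -> LabelVolume:
    """Tile a normalized volume, predict each tile, and reassemble.

    The volume is zero-padded to the next multiple of ``patch_size`` per
    axis, covered with non-overlapping tiles, and the predicted label
    patches are concatenated back and cropped to the original shape.
    """
    from .patch_sampler import assemble_prediction, extract_patches, seed_grid

    specs = seed_grid(volume.shape, patch_size, origin="inference-tile")
    pset = extract_patches(volume, None, specs)
    tiles = []
    for i in range(0, len(specs), batch_size):
        probs = model.forward(pset.images[i:i + batch_size], train=False)
        labs = probs.argmax(axis=1).astype(np.int16)
        tiles.extend(zip(specs[i:i + batch_size], labs))
    assembled = assemble_prediction(tiles, volume.shape)
    return LabelVolume(
        contiguous_to_brats(assembled), scheme="brats",
        spacing=volume.spacing, affine=volume.affine,
    )


def save_checkpoint(model: UNet3D, path: str | Path) -> None:
    """Persist weights (.npz) with a JSON sidecar recording the architecture."""
    path = Path(path)
    np.savez(path, **model.state_arrays())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(asdict(model.config), indent=2))


def load_checkpoint(path: str | Path) -> UNet3D:
    """Rebuild a model from a checkpoint, validating the sidecar config."""
    path = Path(path)
    if not path.suffix == ".npz":
        path = path.with_suffix(".npz")
    sidecar = path.with_suffix(".json")
    cfg_dict = json.loads(sidecar.read_text())
    cfg_dict["features"] = tuple(cfg_dict["features"])
    model = UNet3D(UNetConfig(**cfg_dict))
    with np.load(path) as data:
        state = model.state_arrays()
        if set(data.files) != set(state):
            raise ValueError(f"checkpoint {path} does not match its config sidecar")
        for key, arr in state.items():
            arr[...] = data[key]
    return model
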