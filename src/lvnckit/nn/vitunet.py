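"""Hybrid CNN-transformer segmentation network (ViTUNet-style).

The encoder is a U-Net-style hierarchy of double conv/batch-norm/ReLU blocks
with 2x max-pooling, halving resolution and doubling channels per level.
The bottleneck feature map is patchified, linearly embedded with learned
positional encodings and processed by a stack of pre-norm transformer
encoder layers, injecting global context before decoding.  The decoder
mirrors the encoder with nearest-neighbour upsampling, concatenates the
same-level encoder skip, and ends in a 1x1 projection to four classes with
a per-pixel softmax (background, compact layer, inner cavity, trabeculae).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    GELU,
    Layer,
    LayerNorm,
    Linear,
    MaxPool2x2,
    MultiHeadSelfAttention,
    Parameter,
    ReLU,
    Sequential,
    UpsampleNearest2x,
)

__all__ = ["ModelConfig", "ViTUNet", "build_model", "predict_mask"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``input_size`` must be divisible by ``2**encoder_levels`` and the
    resulting bottleneck grid by ``vit_patch``.  Defaults target full-scale
    use; tests run much smaller instances (64 px, 2 levels, depth 2).
    """

    input_size: int = 800
    n_classes: int = 4
    encoder_levels: int = 4
    base_channels: int = 16
    vit_patch: int = 1
    vit_dim: int = 256
    vit_depth: int = 4
    vit_heads: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != 4:
            raise ValueError("the segmentation head is four-class")
        if self.input_size % (2**self.encoder_levels) != 0:
            raise ValueError("input_size must be divisible by 2**encoder_levels")
        grid = self.input_size // (2**self.encoder_levels)
        if grid % self.vit_patch != 0:
            raise ValueError("bottleneck grid must be divisible by vit_patch")
        if self.vit_dim % self.vit_heads != 0:
            raise ValueError("vit_dim must be divisible by vit_heads")

    @property
    def bottleneck_grid(self) -> int:
        return self.input_size // (2**self.encoder_levels)

    @property
    def n_tokens(self) -> int:
        return (self.bottleneck_grid // self.vit_patch) ** 2


def _conv_block(in_ch: int, out_ch: int, rng: np.random.Generator) -> Sequential:
    return Sequential(
        Conv2d(in_ch, out_ch, 3, rng),
        BatchNorm2d(out_ch),
        ReLU(),
        Conv2d(out_ch, out_ch, 3, rng),
        BatchNorm2d(out_ch),
        ReLU(),
    )


class _TransformerBlock(Layer):
    """Pre-norm transformer encoder layer: MHSA and MLP, both residual."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator) -> None:
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Sequential(
            Linear(dim, 4 * dim, rng), GELU(), Linear(4 * dim, dim, rng)
        )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = x + self.attn.forward(self.norm1.forward(x, train), train)
        return x + self.mlp.forward(self.norm2.forward(x, train), train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = dout + self.norm2.backward(self.mlp.backward(dout))
        return dout + self.norm1.backward(self.attn.backward(dout))


def _as_batch(x: np.ndarray, size: int) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[:, None]
    if x.shape[1] != 1 or x.shape[2] != size or x.shape[3] != size:
        raise ValueError(f"expected single-channel {size}px inputs, got {x.shape}")
    return x


class ViTUNet:
    """The assembled network; forward yields per-pixel class probabilities."""

    def __init__(self, cfg: ModelConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.base_channels
        self.enc_blocks: list[Sequential] = []
        self.pools: list[MaxPool2x2] = []
        in_ch = 1
        enc_channels = []
        for _ in range(cfg.encoder_levels):
            self.enc_blocks.append(_conv_block(in_ch, ch, rng))
            self.pools.append(MaxPool2x2())
            enc_channels.append(ch)
            in_ch, ch = ch, ch * 2
        self.bottleneck = _conv_block(in_ch, ch, rng)
        self.bottleneck_ch = ch

        p = cfg.vit_patch
        token_dim = ch * p * p
        self.embed = Linear(token_dim, cfg.vit_dim, rng)
        self.pos = Parameter(
            rng.normal(0.0, 0.02, (1, cfg.n_tokens, cfg.vit_dim)), "vit.pos"
        )
        self.vit_blocks = [
            _TransformerBlock(cfg.vit_dim, cfg.vit_heads, rng)
            for _ in range(cfg.vit_depth)
        ]
        self.vit_norm = LayerNorm(cfg.vit_dim)
        self.unembed = Linear(cfg.vit_dim, token_dim, rng)

        self.dec_blocks: list[Sequential] = []
        self.ups: list[UpsampleNearest2x] = []
        dch = ch
        self._skip_channels = list(reversed(enc_channels))
        for skip_ch in self._skip_channels:
            self.ups.append(UpsampleNearest2x())
            self.dec_blocks.append(_conv_block(dch + skip_ch, skip_ch, rng))
            dch = skip_ch
        self.head = Conv2d(dch, cfg.n_classes, 1, rng)

    # -- parameter plumbing --------------------------------------------------
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for block in self.enc_blocks:
            params.extend(block.parameters())
        params.extend(self.bottleneck.parameters())
        params.extend(self.embed.parameters())
        params.append(self.pos)
        for block in self.vit_blocks:
            params.extend(block.parameters())
        params.extend(self.vit_norm.parameters())
        params.extend(self.unembed.parameters())
        for block in self.dec_blocks:
            params.extend(block.parameters())
        params.extend(self.head.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- patchify helpers ----------------------------------------------------
    def _tokens_from_grid(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        p = self.cfg.vit_patch
        x = x.reshape(b, c, h // p, p, w // p, p)
        return x.transpose(0, 2, 4, 1, 3, 5).reshape(
            b, (h // p) * (w // p), c * p * p
        )

    def _grid_from_tokens(self, t: np.ndarray, c: int, h: int, w: int) -> np.ndarray:
        b = t.shape[0]
        p = self.cfg.vit_patch
        t = t.reshape(b, h // p, w // p, c, p, p)
        return t.transpose(0, 3, 1, 4, 2, 5).reshape(b, c, h, w)

    # -- forward / backward --------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Per-pixel class probabilities of shape (B, 4, S, S)."""
        x = _as_batch(x, self.cfg.input_size)
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            x = block.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        _, c, h, w = x.shape
        self._grid_shape = (c, h, w)
        t = self.embed.forward(self._tokens_from_grid(x), train) + self.pos.data
        for block in self.vit_blocks:
            t = block.forward(t, train)
        t = self.unembed.forward(self.vit_norm.forward(t, train), train)
        x = self._grid_from_tokens(t, c, h, w)
        for up, dec, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x, train)
            x = dec.forward(np.concatenate([x, skip], axis=1), train)
        logits = self.head.forward(x, train)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        self._probs = e / e.sum(axis=1, keepdims=True)
        return self._probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output probabilities."""
        probs = self._probs
        dlogits = probs * (dprobs - (dprobs * probs).sum(axis=1, keepdims=True))
        dx = self.head.backward(dlogits)
        # Decoder stage i (0 = deepest) consumed the skip of encoder level
        # (levels-1-i); walking the stages in reverse therefore yields the
        # skip gradients ordered by encoder level, shallow first.
        dskips = []
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            dcat = self.dec_blocks[i].backward(dx)
            skip_ch = self._skip_channels[i]
            up_ch = dcat.shape[1] - skip_ch
            dskips.append(dcat[:, up_ch:])
            dx = self.ups[i].backward(dcat[:, :up_ch])
        c, h, w = self._grid_shape
        dt = self._tokens_from_grid(dx)
        dt = self.vit_norm.backward(self.unembed.backward(dt))
        for block in reversed(self.vit_blocks):
            dt = block.backward(dt)
        self.pos.grad += dt.sum(axis=0, keepdims=True)
        dx = self._grid_from_tokens(self.embed.backward(dt), c, h, w)
        dx = self.bottleneck.backward(dx)
        for level in range(len(self.enc_blocks) - 1, -1, -1):
            dx = self.enc_blocks[level].backward(
                self.pools[level].backward(dx) + dskips[level]
            )

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Save weights as npz with a JSON sidecar of the configuration."""
        path = Path(path)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        for i, layer in enumerate(self._bn_layers()):
            arrays[f"bn{i}_mean"] = layer.running_mean
            arrays[f"bn{i}_var"] = layer.running_var
        np.savez(path, **arrays)
        sidecar = Path(str(path) + ".json")
        sidecar.write_text(json.dumps({"model_config": asdict(self.cfg)}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ViTUNet":
        path = Path(path)
        cfg = ModelConfig(
            **json.loads(Path(str(path) + ".json").read_text())["model_config"]
        )
        model = cls(cfg)
        with np.load(path) as data:
            for i, p in enumerate(model.parameters()):
                p.data = data[f"p{i}"]
            for i, layer in enumerate(model._bn_layers()):
                layer.running_mean = data[f"bn{i}_mean"]
                layer.running_var = data[f"bn{i}_var"]
        return model

    def _bn_layers(self) -> list[BatchNorm2d]:
        out = []
        for block in self.enc_blocks + [self.bottleneck] + self.dec_blocks:
            out.extend(l for l in block.layers if isinstance(l, BatchNorm2d))
        return out


def build_model(cfg: ModelConfig) -> ViTUNet:
    """Construct a randomly initialised network from its configuration."""
    return ViTUNet(cfg)


def predict_mask(model: ViTUNet, image: np.ndarray) -> np.ndarray:
    """Segment one slice: argmax class per pixel (ties -> lowest index)."""
    probs = model.forward(image, train=False)
    return probs.argmax(axis=1)[0].astype(np.uint8)
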