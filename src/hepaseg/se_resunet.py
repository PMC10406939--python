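"""SE-ResUnet: squeeze-and-excitation gated residual U-shaped network.

The segmentation model is a 4-stage encoder-decoder.  Each stage is an
SE-residual block: the input is first recalibrated channel-wise by a
squeeze-and-excitation (SE) gate, the gated features feed a residual body
(two 3x3 convolutions, or a 1x1/3x3/1x1 bottleneck), and the block output
is the additive composition

    Y = body(SE(X)) + shortcut(X) + attn(SE(X))

where ``shortcut`` is the identity (or a 1x1 projection when widths
change) and ``attn`` is an additive 1x1 attention branch.  Forcing every
SE gate to one and zeroing the attention branch reduces each block to a
plain residual block y = f(x) + x, and the whole network to a plain
Res-Unet.  Convolutions are normalized then activated (conv -> batch norm
-> ReLU) inside the branches; the block output itself is the raw sum, so a
block with all branch weights zeroed is an exact identity on its input
features.

Encoder stages are followed by 2x2 max pooling; decoder stages upsample by
bilinear interpolation, fuse with the matching encoder feature (channel
concatenation by default) and apply another SE-residual block.  A 1x1
convolution with a sigmoid gate yields the per-pixel foreground
probability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigurationError, InputError
from .nn import (
    AdamW,  # noqa: F401  (re-exported for callers building training loops)
    BatchNorm2d,
    Conv2d,
    Linear,
    Module,
    Tensor,
    concat,
    global_avg_pool,
    maxpool2x2,
    no_grad,
    relu,
    sigmoid,
    upsample_bilinear2x,
)

__all__ = [
    "ModelConfig",
    "SEBlock",
    "ResidualBlock",
    "SEResBlock",
    "SEResUNet",
    "se_scale",
    "residual_forward",
    "se_res_block",
    "build_model",
    "forward",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters defining one SE-ResUnet instance.

    ``depth`` encoder/decoder stages (4), ``base_width`` channels at the
    first stage (doubling per stage), ``se_ratio`` the SE bottleneck
    reduction r, ``block`` the residual-body variant, ``skip_fusion``
    concatenation or addition of encoder features on the decoder path.
    """

    in_channels: int = 3
    out_channels: int = 1
    depth: int = 4
    base_width: int = 32
    se_ratio: int = 8
    block: str = "basic"  # "basic" | "bottleneck"
    skip_fusion: str = "concat"  # "concat" | "add"
    se_enabled: bool = True
    se_heads: int = 1  # parallel SE attention branches, averaged

    def stage_widths(self) -> list[int]:
        return [self.base_width * (2 ** i) for i in range(self.depth)]

    def validate(self) -> None:
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if self.se_ratio < 1:
            raise ConfigurationError("se_ratio must be >= 1")
        for w in self.stage_widths():
            if w % self.se_ratio:
                raise ConfigurationError(
                    f"se_ratio {self.se_ratio} does not divide stage width {w}"
                )
        if self.block not in ("basic", "bottleneck"):
            raise ConfigurationError(f"unknown block variant {self.block!r}")
        if self.skip_fusion not in ("concat", "add"):
            raise ConfigurationError(f"unknown skip_fusion {self.skip_fusion!r}")
        if self.se_heads < 1:
            raise ConfigurationError("se_heads must be >= 1")
        if self.out_channels != 1:
            raise ConfigurationError("only single-channel probability output is supported")


class SEBlock(Module):
    """Squeeze (global average pool) -> excite (C -> C/r -> C) -> scale.

    The excitation MLP ends in a sigmoid, so the per-channel weights lie in
    (0, 1) for finite inputs.  With ``identity=True`` the gate is skipped
    entirely (weights identically 1) — the degenerate configuration that
    recovers a plain residual network bit-exactly.
    """

    def __init__(self, channels: int, ratio: int, rng: np.random.Generator):
        super().__init__()
        if channels % ratio:
            raise ConfigurationError(f"se ratio {ratio} does not divide {channels} channels")
        self.fc1 = Linear(channels, channels // ratio, rng=rng)
        self.fc2 = Linear(channels // ratio, channels, rng=rng)
        self.identity = False

    def weights(self, x: Tensor) -> Tensor:
        squeezed = global_avg_pool(x)                   # (N, C)
        return sigmoid(self.fc2(relu(self.fc1(squeezed))))

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (per-channel weights, rescaled feature map)."""
        if self.identity:
            w = Tensor(np.ones((x.shape[0], x.shape[1]), dtype=np.float32))
            return w, x
        w = self.weights(x)
        n, c = w.shape
        return w, x * w.reshape(n, c, 1, 1)


class _ConvBNAct(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng, act: bool = True):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, rng=rng)
        self.bn = BatchNorm2d(out_ch)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.conv(x))
        return relu(y) if self.act else y


class ResidualBlock(Module):
    """y = f(x) + x with an optional 1x1 projection shortcut.

    ``basic``: two 3x3 convolutions.  ``bottleneck``: 1x1 reduce -> 3x3 ->
    1x1 restore (reduction factor 4), the deeper-network variant.  Each
    convolution is normalized then activated; the output is the raw sum.
    """

    def __init__(self, in_ch: int, out_ch: int, variant: str, rng: np.random.Generator):
        super().__init__()
        if variant == "basic":
            self.body = [
                _ConvBNAct(in_ch, out_ch, 3, rng),
                _ConvBNAct(out_ch, out_ch, 3, rng, act=False),
            ]
        elif variant == "bottleneck":
            mid = max(1, out_ch // 4)
            self.body = [
                _ConvBNAct(in_ch, mid, 1, rng),
                _ConvBNAct(mid, mid, 3, rng),
                _ConvBNAct(mid, out_ch, 1, rng, act=False),
            ]
        else:
            raise ConfigurationError(f"unknown residual variant {variant!r}")
        # projection shortcut is normalized so stacked raw sums stay O(1)
        self.project = (_ConvBNAct(in_ch, out_ch, 1, rng, act=False)
                        if in_ch != out_ch else None)

    def transform(self, x: Tensor) -> Tensor:
        y = x
        for layer in self.body:
            y = layer(y)
        return y

    def shortcut(self, x: Tensor) -> Tensor:
        return self.project(x) if self.project is not None else x

    def forward(self, x: Tensor) -> Tensor:
        return self.transform(x) + self.shortcut(x)


class SEResBlock(Module):
    """SE gate at the block input, residual body, additive attention branch.

    With ``se_heads > 1`` the input is recalibrated by that many parallel
    SE branches and their outputs averaged before the residual body.
    """

    def __init__(self, in_ch: int, out_ch: int, config: "ModelConfig",
                 rng: np.random.Generator):
        super().__init__()
        heads = [SEBlock(in_ch, min(config.se_ratio, in_ch), rng)
                 for _ in range(config.se_heads)]
        for h in heads:
            h.identity = not config.se_enabled
        self.se = heads[0]
        self.se_extra = heads[1:]
        self.res = ResidualBlock(in_ch, out_ch, config.block, rng)
        self.attn = _ConvBNAct(in_ch, out_ch, 1, rng, act=False)

    def _gate(self, x: Tensor) -> Tensor:
        _, gated = self.se(x)
        if not self.se_extra:
            return gated
        for head in self.se_extra:
            gated = gated + head(x)[1]
        return gated * (1.0 / (1 + len(self.se_extra)))

    def forward(self, x: Tensor) -> Tensor:
        gated = self._gate(x)
        return self.res.transform(gated) + self.res.shortcut(x) + self.attn(gated)

    def zero_branches(self) -> None:
        """Zero every body/attention parameter; the block becomes an identity
        when in_ch == out_ch (the shortcut is then the bare input)."""
        for layer in list(self.res.body) + [self.attn]:
            layer.conv.weight.data[...] = 0.0
            if layer.conv.bias is not None:
                layer.conv.bias.data[...] = 0.0
            layer.bn.gamma.data[...] = 0.0
            layer.bn.beta.data[...] = 0.0


class SEResUNet(Module):
    """4-stage (by default) SE-residual encoder-decoder with skip fusion."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        widths = config.stage_widths()

        enc = []
        in_ch = config.in_channels
        for w in widths:
            enc.append(SEResBlock(in_ch, w, config, rng))
            in_ch = w
        self.encoder_stages = enc

        dec = []
        bottom = widths[-1]
        skip_widths = widths[::-1]           # deepest skip first
        in_ch = bottom
        for i, sw in enumerate(skip_widths):
            fused = in_ch + sw if config.skip_fusion == "concat" else in_ch
            out_w = skip_widths[i + 1] if i + 1 < len(skip_widths) else widths[0]
            dec.append(SEResBlock(fused, out_w, config, rng))
            in_ch = out_w
        self.decoder_stages = dec

        self.head = Conv2d(widths[0], config.out_channels, 1, rng=rng)

    # -- forward ---------------------------------------------------------
    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        n, c, h, w = x.shape
        div = 2 ** cfg.depth
        if c != cfg.in_channels:
            raise InputError(f"expected {cfg.in_channels} input channels, got {c}")
        if h % div or w % div:
            raise InputError(
                f"input spatial dims {h}x{w} must be divisible by 2^depth = {div}"
            )
        skips = []
        for block in self.encoder_stages:
            x = block(x)
            skips.append(x)
            x = maxpool2x2(x)
        for block, skip in zip(self.decoder_stages, reversed(skips)):
            x = upsample_bilinear2x(x)
            if cfg.skip_fusion == "concat":
                x = concat([x, skip], axis=1)
            else:
                x = x + skip
            x = block(x)
        return sigmoid(self.head(x))

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Inference on a float batch (N, C, H, W) -> probabilities (N, H, W)."""
        self.eval()
        with no_grad():
            out = self.forward(Tensor(images))
        return out.data[:, 0]

    def set_se_identity(self, identity: bool = True) -> None:
        """Force every SE gate to 1 (or restore learned gating)."""
        for m in self.modules():
            if isinstance(m, SEBlock):
                m.identity = identity

    def parameter_checksum(self) -> float:
        return float(sum(float(np.abs(p.data).sum()) for p in self.parameters()))


# -- functional surface ---------------------------------------------------

def se_scale(x: np.ndarray, ratio: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Standalone squeeze-excite-scale on a feature map (N, C, H, W).

    Returns (per-channel weights (N, C), rescaled features); output shape
    always equals the input shape.
    """
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 4:
        raise InputError(f"expected (N, C, H, W) features, got shape {x.shape}")
    if x.shape[1] % ratio:
        raise ConfigurationError(f"ratio {ratio} does not divide {x.shape[1]} channels")
    block = SEBlock(x.shape[1], ratio, np.random.default_rng(seed))
    with no_grad():
        w, y = block(Tensor(x))
    return w.data, y.data


def residual_forward(x: np.ndarray, block: str = "basic", out_channels: int | None = None,
                     seed: int = 0) -> np.ndarray:
    """Standalone residual block y = f(x) + x on a feature map."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 4:
        raise InputError(f"expected (N, C, H, W) features, got shape {x.shape}")
    out_ch = out_channels or x.shape[1]
    mod = ResidualBlock(x.shape[1], out_ch, block, np.random.default_rng(seed))
    mod.eval()
    with no_grad():
        return mod(Tensor(x)).data


def se_res_block(x: np.ndarray, config: ModelConfig = ModelConfig(),
                 out_channels: int | None = None, seed: int = 0) -> np.ndarray:
    """Standalone SE-residual block forward on a feature map (N, C, H, W)."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 4:
        raise InputError(f"expected (N, C, H, W) features, got shape {x.shape}")
    config.validate()
    block = SEResBlock(x.shape[1], out_channels or x.shape[1], config,
                       np.random.default_rng(seed))
    block.eval()
    with no_grad():
        return block(Tensor(x)).data


def build_model(config: ModelConfig = ModelConfig(), seed: int = 0) -> SEResUNet:
    """Construct a seeded SE-ResUnet; same (config, seed) -> same weights."""
    return SEResUNet(config, seed=seed)


def forward(model: SEResUNet, images: np.ndarray) -> np.ndarray:
    """Batch inference: (N, C, H, W) or (C, H, W) -> probability maps."""
    images = np.asarray(images, dtype=np.float32)
    single = images.ndim == 3
    if single:
        images = images[None]
    out = model.predict_proba(images)
    return out[0] if single else out


# -- checkpointing --------------------------------------------------------

def save_checkpoint(model: SEResUNet, path, extra: dict | None = None) -> None:
    """Single-file .npz archive: weights + JSON-encoded config (self-describing)."""
    state = model.state_dict()
    meta = {"config": asdict(model.config), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> tuple[SEResUNet, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = SEResUNet(ModelConfig(**{k: tuple(v) if isinstance(v, list) else v
                                         for k, v in meta["config"].items()}))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model.load_state_dict(state)
    return model, meta["extra"]
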