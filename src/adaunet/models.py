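"""Segmentation architectures: U-Net backbone, duplex heads, position attention.

``build_segmentor`` assembles one of six variants:

=========  ================  =================
variant    attention blocks  adversarial heads
=========  ================  =================
unet       0                 0
au_net     0                 1
dau_net    0                 2
adau_a1    1                 2
adau_a2    2                 2
adau_a3    3                 2
=========  ================  =================

Variants with two adversarial heads are duplex: besides the final 1x1
prediction head they carry an auxiliary 1x1 head on the penultimate
decoder stage, emitting a half-resolution probability map. Attention
blocks sit after the convolution pair of the last k decoder stages,
before the prediction heads.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._nn import (
    Adam,  # noqa: F401  (re-exported for callers wiring optimizers)
    Conv2d,
    ConvTranspose2x2,
    DoubleConv,
    LeakyConv,
    Module,
    Tensor,
    concat_channels,
    matmul,
    maxpool2x2,
    mean,
    reshape,
    sigmoid,
    softmax_rows,
    transpose2d,
)

# variant -> (n_attention_blocks, n_adversarial_heads)
VARIANTS = {
    "unet": (0, 0),
    "au_net": (0, 1),
    "dau_net": (0, 2),
    "adau_a1": (1, 2),
    "adau_a2": (2, 2),
    "adau_a3": (3, 2),
}


@dataclass(frozen=True)
class SegmentorConfig:
    variant: str = "adau_a2"
    depth: int = 4
    base_channels: int = 64
    in_channels: int = 1
    attention_channel_factor: int = 1
    fixed_delta: float | None = None  # None -> learnable scalar, init 0
    head_bias_init: float = -2.0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {sorted(VARIANTS)}"
            )
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.attention_channel_factor < 1:
            raise ValueError("attention_channel_factor must be >= 1")

    @property
    def n_attention(self) -> int:
        return VARIANTS[self.variant][0]

    @property
    def n_heads(self) -> int:
        return VARIANTS[self.variant][1]

    @property
    def duplex(self) -> bool:
        return self.n_heads == 2


@dataclass
class SegmentorOutput:
    """Probability maps from the prediction heads.

    ``main_map`` comes from the last decoder stage at full resolution;
    ``aux_map`` (duplex variants only) from the penultimate stage at half
    resolution.
    """

    main_map: np.ndarray
    aux_map: np.ndarray | None = None


def position_attention(x: Tensor, delta, proj=None):
    """Spatial self-attention: softmaxed pairwise affinities, delta-residual.

    For features I of shape (C,H,W) flattened to N = H*W columns, the
    affinity of position m to position n is the channel dot product of the
    (1x1-projected) feature vectors; each row of the resulting N x N map is
    softmax-normalized, used to aggregate the projected features, and added
    back as ``delta * aggregate + I``.

    Returns ``(output, attention)`` where attention is the row-stochastic
    N x N Tensor.
    """
    c, h, w = x.shape
    n = h * w
    p = proj(x) if proj is not None else x
    pm = reshape(p, (p.shape[0], n))              # (C', N) -- columns are positions
    energy = matmul(transpose2d(pm), pm)          # (N, N): E[m, n] = I'_n . I'_m
    attn = softmax_rows(energy)                   # rows sum to 1
    agg = transpose2d(matmul(attn, transpose2d(pm)))  # (C', N): sum_n A[m,n] I'_n
    agg = reshape(agg, (p.shape[0], h, w))
    out = x + delta * agg
    return out, attn


def attention_block(feature_map: np.ndarray, delta: float) -> np.ndarray:
    """Functional attention block with identity projection on a raw array."""
    arr = np.asarray(feature_map, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise ValueError("attention_block requires finite input")
    out, _ = position_attention(Tensor(arr), float(delta))
    return out.data


def attention_map(feature_map: np.ndarray) -> np.ndarray:
    """Row-stochastic N x N affinity matrix of a (C,H,W) feature map."""
    arr = np.asarray(feature_map, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise ValueError("attention_map requires finite input")
    _, attn = position_attention(Tensor(arr), 0.0)
    return attn.data


class AttentionBlock(Module):
    def __init__(self, channels, rng, factor=1, fixed_delta=None):
        cp = max(1, channels // factor)
        self.proj = Conv2d(channels, cp, 1, rng, gain="linear")
        self.back = Conv2d(cp, channels, 1, rng, gain="linear") if cp != channels else None
        if fixed_delta is None:
            self.delta = Tensor(np.zeros((), dtype=np.float32), requires_grad=True)
        else:
            self.delta = Tensor(np.asarray(fixed_delta, dtype=np.float32))

    def __call__(self, x):
        c, h, w = x.shape
        n = h * w
        p = self.proj(x)
        pm = reshape(p, (p.shape[0], n))
        energy = matmul(transpose2d(pm), pm)
        attn = softmax_rows(energy)
        agg = transpose2d(matmul(attn, transpose2d(pm)))
        agg = reshape(agg, (p.shape[0], h, w))
        if self.back is not None:
            agg = self.back(agg)
        return x + self.delta * agg


class Segmentor(Module):
    """Encoder-decoder with skip connections and optional duplex/attention."""

    def __init__(self, config: SegmentorConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0xFFFFFFFF, 31337]))
        d, c = config.depth, config.base_channels

        self.enc = []
        cin = config.in_channels
        for i in range(d):
            self.enc.append(DoubleConv(cin, c * 2 ** i, rng))
            cin = c * 2 ** i
        self.bottleneck = DoubleConv(cin, c * 2 ** d, rng)

        self.ups, self.dec, self.att = [], [], []
        ch = c * 2 ** d
        for j in range(d):
            skip = c * 2 ** (d - 1 - j)
            self.ups.append(ConvTranspose2x2(ch, skip, rng))
            self.dec.append(DoubleConv(2 * skip, skip, rng))
            # attention on the last n_attention decoder stages
            if d - 1 - j < config.n_attention:
                self.att.append(
                    AttentionBlock(skip, rng, config.attention_channel_factor,
                                   config.fixed_delta)
                )
            else:
                self.att.append(None)
            ch = skip
        # prediction-head bias starts at the logit of a small foreground
        # prior so initial maps are not 0.5 everywhere (speeds up dice
        # convergence on small targets)
        self.head = Conv2d(c, 1, 1, rng, gain="linear")
        self.head.b.data[:] = config.head_bias_init
        if config.duplex:
            self.aux_head = Conv2d(2 * c, 1, 1, rng, gain="linear")
            self.aux_head.b.data[:] = config.head_bias_init
        else:
            self.aux_head = None

    @property
    def attention_blocks(self):
        return [a for a in self.att if a is not None]

    def forward_t(self, x: Tensor):
        """Graph-building forward; returns (main, aux) probability Tensors."""
        c, h, w = x.shape
        mult = 2 ** self.config.depth
        if h % mult or w % mult:
            raise ValueError(
                f"input size {h}x{w} must be a multiple of {mult} "
                f"(2**depth with depth={self.config.depth})"
            )
        skips = []
        t = x
        for block in self.enc:
            t = block(t)
            skips.append(t)
            t = maxpool2x2(t)
        t = self.bottleneck(t)
        aux = None
        for j, (up, dec, att) in enumerate(zip(self.ups, self.dec, self.att)):
            t = dec(concat_channels(skips[-1 - j], up(t)))
            if att is not None:
                t = att(t)
            if self.aux_head is not None and j == self.config.depth - 2:
                a = sigmoid(self.aux_head(t))
                aux = reshape(a, a.shape[1:])
        m = sigmoid(self.head(t))
        main = reshape(m, m.shape[1:])
        return main, aux

    def predict(self, image: np.ndarray) -> SegmentorOutput:
        """Inference on a 2D image; deterministic, no graph retained."""
        x = Tensor(np.asarray(image, dtype=np.float32)[None])
        main, aux = self.forward_t(x)
        return SegmentorOutput(
            main_map=main.data.copy(),
            aux_map=None if aux is None else aux.data.copy(),
        )


@dataclass(frozen=True)
class DiscriminatorConfig:
    kernel_sizes: tuple[int, ...] = (4, 4, 4, 5, 7)
    channels: tuple[int, ...] = (64, 128, 256, 512, 1)
    strides: tuple[int, ...] = (2, 2, 2, 2, 2)

    def __post_init__(self):
        if not (len(self.kernel_sizes) == len(self.channels) == len(self.strides)):
            raise ValueError("kernel_sizes, channels and strides must have equal length")


class Discriminator(Module):
    """Patch-to-scalar critic: strided convolutions, mean pool, sigmoid."""

    def __init__(self, config: DiscriminatorConfig = DiscriminatorConfig(),
                 in_channels: int = 1, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0xFFFFFFFF, 424242]))
        self.layers = []
        cin = in_channels
        ks, cs = config.kernel_sizes, config.channels
        for i, (k, cout) in enumerate(zip(ks, cs)):
            if i < len(ks) - 1:
                self.layers.append(LeakyConv(cin, cout, k, rng))
            else:
                self.layers.append(Conv2d(cin, cout, k, rng, stride=config.strides[i],
                                          gain="linear"))
            cin = cout

    @property
    def n_conv_layers(self) -> int:
        return len(self.layers)

    def forward_t(self, x: Tensor) -> Tensor:
        t = x
        for layer in self.layers:
            t = layer(t)
        return sigmoid(mean(t))

    def predict(self, prob_map: np.ndarray) -> float:
        x = Tensor(np.asarray(prob_map, dtype=np.float32)[None])
        return float(self.forward_t(x).data)


def build_segmentor(config: SegmentorConfig, seed: int = 0) -> Segmentor:
    return Segmentor(config, seed=seed)


def build_discriminator(config: DiscriminatorConfig = DiscriminatorConfig(),
                        in_channels: int = 1, seed: int = 0) -> Discriminator:
    return Discriminator(config, in_channels=in_channels, seed=seed)


def n_parameters(model: Module) -> int:
    return sum(p.data.size for p in model.parameters())


def save_checkpoint(model: Segmentor, path):
    """Weights as .npz with a JSON sidecar recording the config."""
    path = Path(path)
    np.savez(path, *model.state_arrays())
    sidecar = path.with_suffix(path.suffix + ".json") if path.suffix != ".npz" \
        else path.with_suffix(".json")
    sidecar.write_text(json.dumps(asdict(model.config), indent=2))


def load_checkpoint(path) -> Segmentor:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = path.with_suffix(".json")
    cfg = SegmentorConfig(**json.loads(sidecar.read_text()))
    model = Segmentor(cfg)
    with np.load(path) as data:
        model.load_state_arrays([data[k] for k in data.files])
    return model
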