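"""The four network architectures, built at configurable (desk) scale.

* SR generator: residual-block trunk plus two sub-pixel (x2) upsampling
  stages mapping a stacked pair of LR frames (H x W x 2) to one HR image
  (4H x 4W x 1), with a global nearest-upsample skip so the net learns the
  residual on top of a plain interpolation (standard residual-learning SR).
* SR discriminator: eight convolutional layers, channels doubling with
  depth, strided shrinking, single linear critic output, no sigmoid.
* Deblur generator: five-layer convolutional encoder, mirrored transposed-
  convolution decoder, optional identity skip.
* Denoise pair: 3-D conv/deconv generator with symmetric short connections
  (filter sequence 32-64-128-256-128-64-32, 1 at width multiplier 1, all
  kernels 3x3x3, conv -> Leaky-ReLU -> batch-norm except the last stage) and
  a three-conv critic (32/64/128) with a fully connected scalar output.
* Perceptual feature extractor: a fixed-seed random convolution stack by
  default, with a hook for externally supplied pretrained weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    BatchNorm,
    ConvNd,
    ConvTransposeNd,
    GlobalAvgPool,
    LeakyReLU,
    Linear,
    Module,
    Sequential,
    Tensor,
)
from .nn import functional as F
from .nn.autograd import add, cast, leaky_relu, mean, reshape

_ROLES = ("sr_gen", "sr_disc", "deblur_gen", "denoise_gen", "denoise_disc", "feature_extractor")


@dataclass
class NetSpec:
    role: str
    width_multiplier: float = 1.0
    upscale_factor: int = 4
    input_shape: tuple | None = None
    seed: int = 0
    n_res_blocks: int = 8
    residual_skip: bool = True
    allow_nonstandard_upscale: bool = False

    def __post_init__(self):
        if self.role not in _ROLES:
            raise ValueError(f"unknown network role {self.role!r}")
        if self.role == "sr_gen" and self.upscale_factor != 4 and not self.allow_nonstandard_upscale:
            raise ValueError("upscale_factor is 4 (two x2 sub-pixel stages); override explicitly")


def _w(base: int, mult: float) -> int:
    return max(1, int(round(base * mult)))


# ---------------------------------------------------------------------------
# SR generator
# ---------------------------------------------------------------------------


class _ResBlock(Module):
    def __init__(self, rng, ch):
        super().__init__()
        self.c1 = ConvNd(rng, ch, ch, 3, nd=2)
        self.b1 = BatchNorm(ch, nd=2)
        self.c2 = ConvNd(rng, ch, ch, 3, nd=2, init_scale=0.1)
        self.b2 = BatchNorm(ch, nd=2)

    def forward(self, x):
        y = self.b1(self.c1(x))
        y = leaky_relu(y, 0.2)
        y = self.b2(self.c2(y))
        return add(x, y)


class SRGenerator(Module):
    """Residual trunk + two x2 sub-pixel stages; (N,2,H,W) -> (N,1,4H,4W)."""

    def __init__(self, spec: NetSpec):
        super().__init__()
        rng = np.random.default_rng(spec.seed)
        ch = _w(64, spec.width_multiplier)
        self.spec = spec
        self.head = ConvNd(rng, 2, ch, 9, nd=2)
        self.blocks = Sequential(*[_ResBlock(rng, ch) for _ in range(spec.n_res_blocks)])
        self.post = ConvNd(rng, ch, ch, 3, nd=2)
        self.up1 = ConvNd(rng, ch, ch * 4, 3, nd=2)
        self.up2 = ConvNd(rng, ch, ch * 4, 3, nd=2)
        self.tail = ConvNd(rng, ch, 1, 9, nd=2, init_scale=0.05)

    def forward(self, x):
        x = cast(x, np.float32)
        h = leaky_relu(self.head(x), 0.2)
        t = self.blocks(h)
        t = add(self.post(t), h)  # trunk-level skip
        t = leaky_relu(F.pixel_shuffle(self.up1(t), 2), 0.2)
        t = leaky_relu(F.pixel_shuffle(self.up2(t), 2), 0.2)
        out = self.tail(t)
        if self.spec.residual_skip:
            base = mean(x, axis=1, keepdims=True)  # average of the stacked LR frames
            out = add(out, F.upsample_nearest(base, 4))
        return out


def build_sr_generator(spec: NetSpec) -> SRGenerator:
    if spec.role != "sr_gen":
        raise ValueError("spec.role must be 'sr_gen'")
    return SRGenerator(spec)


# ---------------------------------------------------------------------------
# SR discriminator (critic)
# ---------------------------------------------------------------------------


class SRDiscriminator(Module):
    """Eight conv layers, doubling channels, strided shrinking, linear critic."""

    n_conv_layers = 8

    def __init__(self, spec: NetSpec):
        super().__init__()
        rng = np.random.default_rng(spec.seed)
        w0 = _w(32, spec.width_multiplier)
        chans = [w0, w0, 2 * w0, 2 * w0, 4 * w0, 4 * w0, 8 * w0, 8 * w0]
        strides = [1, 2, 1, 2, 1, 2, 1, 2]
        mods = []
        cin = 1
        for c, s in zip(chans, strides):
            mods += [ConvNd(rng, cin, c, 3, nd=2, stride=s), LeakyReLU(0.2)]
            cin = c
        self.convs = Sequential(*mods)
        self.pool = GlobalAvgPool()
        self.fc = Linear(rng, cin, 1)

    def forward(self, x):
        return self.fc(self.pool(self.convs(cast(x, np.float32))))


def build_sr_discriminator(spec: NetSpec) -> SRDiscriminator:
    if spec.role != "sr_disc":
        raise ValueError("spec.role must be 'sr_disc'")
    return SRDiscriminator(spec)


# ---------------------------------------------------------------------------
# deblur generator
# ---------------------------------------------------------------------------


class DeblurGenerator(Module):
    """5-conv encoder, mirrored transposed-conv decoder, same-shape output."""

    encoder_layers = 5

    def __init__(self, spec: NetSpec):
        super().__init__()
        rng = np.random.default_rng(spec.seed)
        w0 = _w(64, spec.width_multiplier)
        self.spec = spec
        enc_ch = [w0, w0, 2 * w0, 2 * w0, 4 * w0]
        enc_st = [1, 2, 1, 2, 1]
        self.total_stride = int(np.prod(enc_st))
        mods = []
        cin = 1
        for c, s in zip(enc_ch, enc_st):
            mods += [ConvNd(rng, cin, c, 3, nd=2, stride=s), LeakyReLU(0.2)]
            cin = c
        self.encoder = Sequential(*mods)
        dec = []
        dec_ch = [2 * w0, 2 * w0, w0, w0, 1]
        dec_st = [1, 2, 1, 2, 1]
        for i, (c, s) in enumerate(zip(dec_ch, dec_st)):
            last = i == len(dec_ch) - 1
            scale = 0.05 if last else 1.0
            if s == 1:
                dec.append(ConvNd(rng, cin, c, 3, nd=2, init_scale=scale))
            else:
                dec.append(ConvTransposeNd(rng, cin, c, 3, nd=2, stride=s, padding=1,
                                           output_padding=1, init_scale=scale))
            if not last:
                dec.append(LeakyReLU(0.2))
            cin = c
        self.decoder = Sequential(*dec)

    def forward(self, x):
        if x.shape[-1] % self.total_stride or x.shape[-2] % self.total_stride:
            raise ValueError(f"input size must be divisible by {self.total_stride}")
        x = cast(x, np.float32)
        y = self.decoder(self.encoder(x))
        if self.spec.residual_skip:
            y = add(y, x)
        return y


def build_deblur_generator(spec: NetSpec) -> DeblurGenerator:
    if spec.role != "deblur_gen":
        raise ValueError("spec.role must be 'deblur_gen'")
    return DeblurGenerator(spec)


# ---------------------------------------------------------------------------
# denoising pair (3-D)
# ---------------------------------------------------------------------------

DENOISE_CHANNEL_SEQUENCE = (32, 64, 128, 256, 128, 64, 32, 1)


class DenoiseGenerator(Module):
    """8-stage 3-D conv/deconv net with symmetric short connections."""

    def __init__(self, spec: NetSpec):
        super().__init__()
        rng = np.random.default_rng(spec.seed)
        m = spec.width_multiplier
        self.spec = spec
        seq = [c if c == 1 else _w(c, m) for c in DENOISE_CHANNEL_SEQUENCE]
        self.channel_sequence = tuple(seq)
        self.convs = []
        self.bns = []
        cin = 1
        for i, c in enumerate(seq):
            last = i == len(seq) - 1
            conv = ConvNd(rng, cin, c, 3, nd=3, init_scale=0.05 if last else 1.0)
            self._modules[f"conv{i}"] = conv
            self.convs.append(conv)
            if not last:
                bn = BatchNorm(c, nd=3)
                self._modules[f"bn{i}"] = bn
                self.bns.append(bn)
            cin = c

    def forward(self, x):
        x = cast(x, np.float32)
        feats = []
        h = x
        n = len(self.convs)
        for i, conv in enumerate(self.convs):
            h = conv(h)
            h = leaky_relu(h, 0.2)
            if i < n - 1:
                h = self.bns[i](h)
            # short connections pair stage i with stage n-2-i (matching widths)
            j = n - 2 - i
            if i < j:
                feats.append(h)
            elif 0 <= j < len(feats) and i < n - 1:
                h = add(h, feats[j])
        if self.spec.residual_skip:
            h = add(h, x)
        return h


class DenoiseDiscriminator(Module):
    """Three 3-D conv layers (32/64/128 at multiplier 1) + linear output."""

    n_conv_layers = 3

    def __init__(self, spec: NetSpec):
        super().__init__()
        rng = np.random.default_rng(spec.seed)
        m = spec.width_multiplier
        chans = [_w(32, m), _w(64, m), _w(128, m)]
        mods = []
        cin = 1
        for c in chans:
            mods += [ConvNd(rng, cin, c, 3, nd=3, stride=2), LeakyReLU(0.2)]
            cin = c
        self.convs = Sequential(*mods)
        self.pool = GlobalAvgPool()
        self.fc = Linear(rng, cin, 1)

    def forward(self, x):
        if x.ndim != 5:
            raise ValueError("denoise critic expects (N, 1, D, H, W) volumes")
        return self.fc(self.pool(self.convs(cast(x, np.float32))))


def build_denoise_gan(spec: NetSpec):
    if spec.role not in ("denoise_gen", "denoise_disc"):
        raise ValueError("spec.role must be denoise_gen/denoise_disc")
    g = DenoiseGenerator(spec)
    d = DenoiseDiscriminator(spec)
    return g, d


# ---------------------------------------------------------------------------
# perceptual feature extractor
# ---------------------------------------------------------------------------


class FeatureExtractor(Module):
    """Fixed-seed random convolution stack used as a perceptual metric.

    ``kind='random'`` (default) builds a frozen random conv stack; a
    surrogate with the key property of perceptual losses (distances measured
    in a fixed nonlinear feature space).  ``kind='identity'`` is a single
    1x1 identity convolution, under which the perceptual loss reduces to a
    pixel MSE.  External pretrained weights can be loaded with
    ``load_state_arrays``.
    """

    def __init__(self, n_layers: int = 4, channels: int = 16, seed: int = 0,
                 kind: str = "random"):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.kind = kind
        self.n_layers = 1 if kind == "identity" else n_layers
        mods = []
        if kind == "identity":
            conv = ConvNd(rng, 1, 1, 1, nd=2, bias=False)
            conv.weight.data = np.ones((1, 1, 1, 1))
            mods.append(conv)
        else:
            cin = 1
            for _ in range(n_layers):
                mods += [ConvNd(rng, cin, channels, 3, nd=2), LeakyReLU(0.2)]
                cin = channels
        self.stack = Sequential(*mods)
        # the extractor is a frozen metric, never trained
        for p in self.parameters():
            p.requires_grad = False

    def __call__(self, x, layer: int | None = None):
        return self.forward(x, layer=layer)

    def forward(self, x, layer: int | None = None):
        """Feature maps after the requested layer (default: the last)."""
        layer = self.n_layers if layer is None else layer
        if layer > self.n_layers or layer < 1:
            raise ValueError(f"layer {layer} beyond extractor depth {self.n_layers}")
        x = cast(x, np.float32)
        if x.ndim == 5:  # volumes: slice-wise 2-D application
            n, c, d, h, w = x.shape
            x = reshape(x, (n * d, c, h, w)) if c == 1 else x
        h_ = x
        done = 0
        for m in self.stack.mods:
            h_ = m(h_)
            if isinstance(m, (ConvNd,)):
                done += 1
                if done == layer:
                    break
        return h_


def feature_extract(image, extractor: FeatureExtractor, layer: int | None = None):
    """Feature maps plus their dimensions (for loss normalization)."""
    t = image if isinstance(image, Tensor) else Tensor(np.asarray(image, float))
    if t.ndim == 2:
        t = reshape(t, (1, 1) + t.shape)
    f = extractor(t, layer=layer)
    return f, f.shape
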