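"""Configurable U-Net family with an exact kernel-weight counting algebra.

The family is parameterized by an :class:`ArchitectureSpec`: number of
resolution levels ``L``, initial filter count ``F0`` (doubling after each
down-sampling), convolutions per block ``C``, concatenation skip
connections, activation choice, batch normalization, and a block variant
(vanilla / residual / dense encoder / dilated bottleneck / side output).

Counting convention
-------------------
``kernel_weight_count`` counts convolution kernel elements only: all
convolutions are bias-free (the batch-normalization shift supplies the
offset) and normalization scale/shift parameters are excluded.  Under this
convention — with a 1x1 channel-halving convolution after each nearest-
neighbour up-pooling and a bias-free 3x3 two-channel output head — the
closed form is

    encoder level l:   9*c_in*f_l + (C-1)*9*f_l^2          (f_l = F0*2^(l-1))
    decoder level l:   f_{l+1}*f_l + 9*(1+s)*f_l^2 + (C-1)*9*f_l^2
    head:              9*F0*out_classes
    side outputs:      sum_l out_classes*f_l  over decoder levels

Dilation, activation and normalization flags never change the count.
Residual and dense blocks are built and trainable, but their counts are
not covered by the algebra and counting them raises
:class:`UnsupportedCountingError`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from . import nn as _nn
from .nn import (
    Adam,
    BatchNorm,
    BilinearResize,
    Conv2D,
    MaxPool2,
    Param,
    ReLU,
    UpNearest2,
    softmax_backward,
    softmax_channels,
)

__all__ = [
    "ArchitectureSpec",
    "DEFAULT_SPEC",
    "NetworkModel",
    "UnsupportedCountingError",
    "kernel_weight_count",
    "build_network",
    "build_variant_block",
    "predict_image",
]

BlockVariant = Literal["vanilla", "residual", "dense_encoder",
                       "dilated_bottleneck", "side_output"]


class UnsupportedCountingError(ValueError):
    """Raised for block variants whose printed counts the algebra does not cover."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """Complete description of one member of the U-Net family."""

    levels: int = 3
    init_filters: int = 16
    convs_per_block: int = 2
    skip_connections: bool = True
    activation: Literal["relu", "linear"] = "relu"
    batch_norm: bool = True
    block_variant: BlockVariant = "vanilla"
    dilation_rate: int = 2
    in_channels: int = 1
    out_classes: int = 2

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.init_filters < 1:
            raise ValueError("init_filters must be >= 1")
        if self.convs_per_block < 1:
            raise ValueError("convs_per_block must be >= 1")
        if self.dilation_rate < 1:
            raise ValueError("dilation_rate must be >= 1")
        if self.activation not in ("relu", "linear"):
            raise ValueError("activation must be 'relu' or 'linear'")

    def filters(self) -> list[int]:
        """Filter counts per level; doubles after each down-sampling."""
        return [self.init_filters * 2 ** l for l in range(self.levels)]

    def with_(self, **kw) -> "ArchitectureSpec":
        return replace(self, **kw)


DEFAULT_SPEC = ArchitectureSpec()


def kernel_weight_count(spec: ArchitectureSpec) -> int:
    """Closed-form kernel-element count of a family member.

    Raises
    ------
    UnsupportedCountingError
        For residual / dense-encoder variants.
    """
    if spec.block_variant in ("residual", "dense_encoder"):
        raise UnsupportedCountingError(
            f"counting convention does not cover '{spec.block_variant}' blocks")
    L, C, s = spec.levels, spec.convs_per_block, int(spec.skip_connections)
    f = spec.filters()
    total = 0
    cin = spec.in_channels
    for l in range(L):  # encoder path, level L is the bottleneck
        total += 9 * cin * f[l] + (C - 1) * 9 * f[l] ** 2
        cin = f[l]
    for l in range(L - 2, -1, -1):  # decoder path
        total += f[l + 1] * f[l]                 # 1x1 up-projection
        total += 9 * (1 + s) * f[l] ** 2         # first convolution
        total += (C - 1) * 9 * f[l] ** 2
    total += 9 * spec.init_filters * spec.out_classes  # 3x3 head
    if spec.block_variant == "side_output":
        total += sum(spec.out_classes * f[l] for l in range(L - 1))
    return total


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class _Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train=True):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, gy):
        for lay in reversed(self.layers):
            gy = lay.backward(gy)
        return gy

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def convs(self):
        return [lay for lay in self.layers if isinstance(lay, Conv2D)]


def _unit(rng, cin, f, relu, bn, dilation=1, with_bn=True):
    layers = [Conv2D(cin, f, 3, dilation, rng)]
    if relu:
        layers.append(ReLU())
    if bn and with_bn:
        layers.append(BatchNorm(f))
    return layers


class VanillaBlock(_Sequential):
    """C consecutive 3x3 convolutions, each followed by ReLU then batch norm.

    ``final_bn=False`` drops the normalization after the block's last
    activation — used for the network's very last block, where batch
    normalization is applied after all but the last activation.
    """

    def __init__(self, rng, cin, f, C, relu=True, bn=True, dilation=1,
                 final_bn=True):
        layers = []
        for ci in range(C):
            layers += _unit(rng, cin if ci == 0 else f, f, relu, bn, dilation,
                            with_bn=(ci < C - 1) or final_bn)
        super().__init__(layers)


class ResidualBlock:
    """Vanilla pair of convolutions plus two inserted ones with an additive
    shortcut from the first convolution's activations to the third's."""

    def __init__(self, rng, cin, f, relu=True, bn=True, final_bn=True):
        self.u1 = _Sequential(_unit(rng, cin, f, relu, bn))
        self.u2 = _Sequential(_unit(rng, f, f, relu, bn))
        self.c3 = Conv2D(f, f, 3, 1, rng)
        self.post3 = _Sequential(([ReLU()] if relu else []) +
                                 ([BatchNorm(f)] if bn else []))
        self.u4 = _Sequential(_unit(rng, f, f, relu, bn, with_bn=final_bn))

    def forward(self, x, train=True):
        a1 = self.u1.forward(x, train)
        a2 = self.u2.forward(a1, train)
        z3 = self.c3.forward(a2, train) + a1
        a3 = self.post3.forward(z3, train)
        return self.u4.forward(a3, train)

    def backward(self, gy):
        ga3 = self.u4.backward(gy)
        gz3 = self.post3.backward(ga3)
        ga2 = self.c3.backward(gz3)
        ga1 = self.u2.backward(ga2) + gz3  # shortcut branch
        return self.u1.backward(ga1)

    def params(self):
        return (self.u1.params() + self.u2.params() + self.c3.params() +
                self.post3.params() + self.u4.params())

    def convs(self):
        return (self.u1.convs() + self.u2.convs() + [self.c3] +
                self.u4.convs())


class DenseBlock:
    """Encoder block where every layer's activations are concatenated to all
    later layers; a 1x1 transition restores the level's channel width."""

    def __init__(self, rng, cin, f, C, relu=True, bn=True):
        self.C, self.cin, self.f = C, cin, f
        self.units = [
            _Sequential(_unit(rng, cin + ci * f, f, relu, bn))
            for ci in range(C)
        ]
        self.transition = _Sequential(
            [Conv2D(C * f, f, 1, 1, rng)] + ([ReLU()] if relu else []) +
            ([BatchNorm(f)] if bn else []))

    def forward(self, x, train=True):
        feats = [x]
        for unit in self.units:
            feats.append(unit.forward(np.concatenate(feats, axis=1), train))
        return self.transition.forward(np.concatenate(feats[1:], axis=1), train)

    def backward(self, gy):
        gcat = self.transition.backward(gy)
        pending = [None] * (self.C + 1)
        widths = [self.cin] + [self.f] * self.C
        for k in range(1, self.C + 1):
            pending[k] = gcat[:, (k - 1) * self.f:k * self.f]
        for ci in range(self.C - 1, -1, -1):
            ginp = self.units[ci].backward(pending[ci + 1])
            off = 0
            for k in range(ci + 1):
                chunk = ginp[:, off:off + widths[k]]
                pending[k] = chunk if pending[k] is None else pending[k] + chunk
                off += widths[k]
        return pending[0]

    def params(self):
        out = [p for u in self.units for p in u.params()]
        return out + self.transition.params()

    def convs(self):
        return [c for u in self.units for c in u.convs()] + self.transition.convs()


def build_variant_block(kind: str, width: int, *, cin: int | None = None,
                        convs_per_block: int = 2, dilation_rate: int = 2,
                        out_classes: int = 2, input_shape: tuple[int, int] = (64, 64),
                        placement: str | None = None, seed: int = 0):
    """Build one functional block of the requested kind at the given width.

    ``residual`` blocks may sit anywhere in the network; ``dense`` blocks are
    encoder-only; ``dilated`` blocks live in the bottleneck; ``side_output``
    returns the 1x1 projection plus bilinear upsampling tap placed on decoder
    blocks.  ``placement`` ('encoder' / 'bottleneck' / 'decoder') is checked
    against these constraints when given.
    """
    rng = np.random.default_rng(seed)
    cin = width if cin is None else cin
    if kind == "residual":
        return ResidualBlock(rng, cin, width)
    if kind == "dense":
        if placement == "decoder":
            raise ValueError("dense blocks are encoder-only")
        return DenseBlock(rng, cin, width, convs_per_block)
    if kind == "dilated":
        if placement is not None and placement != "bottleneck":
            raise ValueError("dilated blocks live in the bottleneck")
        if dilation_rate < 1:
            raise ValueError("dilation_rate must be >= 1")
        return VanillaBlock(rng, cin, width, convs_per_block,
                            dilation=dilation_rate)
    if kind == "side_output":
        if placement is not None and placement != "decoder":
            raise ValueError("side-output taps sit on decoder blocks")
        return _SideTap(rng, width, out_classes, input_shape)
    raise ValueError(f"unknown block kind '{kind}'")


class _SideTap:
    """1x1 projection to class maps, bilinearly upsampled to the input shape."""

    def __init__(self, rng, f, out_classes, input_shape):
        self.conv = Conv2D(f, out_classes, 1, 1, rng)
        self.resize = BilinearResize(input_shape)

    def forward(self, x, train=True):
        return self.resize.forward(self.conv.forward(x, train), train)

    def backward(self, gy):
        return self.conv.backward(self.resize.backward(gy))

    def params(self):
        return self.conv.params()

    def convs(self):
        return [self.conv]


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class UNet:
    """Encoder–decoder network assembled from an :class:`ArchitectureSpec`.

    Forward input is NCHW with spatial dimensions divisible by
    ``2**(levels-1)``; output is a softmax probability map over
    ``out_classes`` channels.  Side-output variants additionally return the
    raw per-level side maps upsampled to the input shape.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0,
                 input_shape: tuple[int, int] = (64, 64)):
        self.spec = spec
        self.input_shape = input_shape
        rng = np.random.default_rng(seed)
        L, C = spec.levels, spec.convs_per_block
        f = spec.filters()
        relu = spec.activation == "relu"
        bn = spec.batch_norm
        variant = spec.block_variant

        def make_block(cin, width, *, bottleneck=False, final=False):
            if variant == "residual":
                return ResidualBlock(rng, cin, width, relu, bn,
                                     final_bn=not final)
            dil = spec.dilation_rate if (
                variant == "dilated_bottleneck" and bottleneck) else 1
            return VanillaBlock(rng, cin, width, C, relu, bn, dilation=dil,
                                final_bn=not final)

        self.enc_blocks = []
        cin = spec.in_channels
        for l in range(L):
            bottom = l == L - 1
            if variant == "dense_encoder" and not bottom:
                blk = DenseBlock(rng, cin, f[l], C, relu, bn)
            else:
                blk = make_block(cin, f[l], bottleneck=bottom,
                                 final=(bottom and L == 1))
            self.enc_blocks.append(blk)
            cin = f[l]
        self.pools = [MaxPool2() for _ in range(L - 1)]

        self.ups, self.upconvs, self.dec_blocks = [], [], []
        self.side_taps = []
        for di, l in enumerate(range(L - 2, -1, -1)):
            self.ups.append(UpNearest2())
            self.upconvs.append(Conv2D(f[l + 1], f[l], 1, 1, rng))
            dec_in = (2 if spec.skip_connections else 1) * f[l]
            self.dec_blocks.append(
                make_block(dec_in, f[l], final=(l == 0)))
            if variant == "side_output":
                self.side_taps.append(_SideTap(rng, f[l], spec.out_classes,
                                               input_shape))
        self.head = Conv2D(spec.init_filters, spec.out_classes, 3, 1, rng)
        self._cache = None

    # -- structure ---------------------------------------------------------
    def _modules(self):
        mods = list(self.enc_blocks) + self.upconvs + list(self.dec_blocks)
        mods += self.side_taps + [self.head]
        return mods

    def parameters(self) -> list[Param]:
        out = []
        for m in self._modules():
            out.extend(m.params())
        return out

    def conv_layers(self) -> list[Conv2D]:
        out = []
        for m in self._modules():
            out.extend(m.convs() if hasattr(m, "convs") else [m])
        return out

    def kernel_parameters(self) -> list[Param]:
        return [c.weight for c in self.conv_layers()]

    def introspected_kernel_count(self) -> int:
        return int(sum(c.weight.value.size for c in self.conv_layers()))

    def total_trainable_count(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def state_dict(self) -> dict:
        bn_layers = self._bn_layers()
        return {"params": [p.value.copy() for p in self.parameters()],
                "bn": [(b.running_mean.copy(), b.running_var.copy())
                       for b in bn_layers]}

    def _bn_layers(self):
        out = [lay for blk in self._modules()
               for lay in getattr(blk, "layers", [])
               if isinstance(lay, BatchNorm)]
        return out + self._nested_bn()

    def _nested_bn(self):
        out = []
        for blk in self._modules():
            if isinstance(blk, ResidualBlock):
                for seq in (blk.u1, blk.u2, blk.post3, blk.u4):
                    out += [lay for lay in seq.layers if isinstance(lay, BatchNorm)]
            elif isinstance(blk, DenseBlock):
                for seq in blk.units + [blk.transition]:
                    out += [lay for lay in seq.layers if isinstance(lay, BatchNorm)]
        return out

    def load_state_dict(self, state: dict) -> None:
        for p, v in zip(self.parameters(), state["params"]):
            p.value[...] = v
        for b, (rm, rv) in zip(self._bn_layers(), state["bn"]):
            b.running_mean[...] = rm
            b.running_var[...] = rv

    # -- forward / backward --------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True):
        spec = self.spec
        L = spec.levels
        n, c, h, w = x.shape
        if c != spec.in_channels:
            raise ValueError(f"expected {spec.in_channels} channels, got {c}")
        div = 2 ** (L - 1)
        if h % div or w % div:
            raise ValueError(
                f"spatial shape {(h, w)} not divisible by 2^(L-1)={div}; "
                "use predict_image for automatic padding")
        acts = []
        hcur = x.astype(_nn.DTYPE)
        for l in range(L):
            if l > 0:
                hcur = self.pools[l - 1].forward(hcur, train)
            hcur = self.enc_blocks[l].forward(hcur, train)
            acts.append(hcur)
        sides = []
        skip_ch = []
        for di, l in enumerate(range(L - 2, -1, -1)):
            hcur = self.ups[di].forward(hcur, train)
            hcur = self.upconvs[di].forward(hcur, train)
            if spec.skip_connections:
                skip_ch.append(acts[l].shape[1])
                hcur = np.concatenate([acts[l], hcur], axis=1)
            hcur = self.dec_blocks[di].forward(hcur, train)
            if self.side_taps:
                sides.append(self.side_taps[di].forward(hcur, train))
        logits = self.head.forward(hcur, train)
        probs = softmax_channels(logits)
        self._cache = (probs, skip_ch)
        if self.side_taps:
            return probs, sides
        return probs

    def backward(self, gprobs: np.ndarray, gsides: list[np.ndarray] | None = None):
        probs, skip_ch = self._cache
        spec = self.spec
        L = spec.levels
        gz = softmax_backward(probs, gprobs)
        gh = self.head.backward(gz)
        enc_grads: list = [None] * L
        for di in range(L - 2, -1, -1):
            l = L - 2 - di
            if self.side_taps and gsides is not None:
                gh = gh + self.side_taps[di].backward(gsides[di])
            g = self.dec_blocks[di].backward(gh)
            if spec.skip_connections:
                ch = skip_ch[di]
                gskip, g = g[:, :ch], g[:, ch:]
                enc_grads[l] = gskip if enc_grads[l] is None else enc_grads[l] + gskip
            g = self.upconvs[di].backward(g)
            g = self.ups[di].backward(g)
            if di == 0:
                enc_grads[L - 1] = g if enc_grads[L - 1] is None else enc_grads[L - 1] + g
            else:
                gh = g
        if L == 1:
            enc_grads[0] = gh if enc_grads[0] is None else enc_grads[0] + gh
        g = None
        for l in range(L - 1, -1, -1):
            gin = enc_grads[l]
            g = self.enc_blocks[l].backward(gin)
            if l > 0:
                g = self.pools[l - 1].backward(g)
                enc_grads[l - 1] = g if enc_grads[l - 1] is None else enc_grads[l - 1] + g
        return g

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


@dataclass
class NetworkModel:
    """A built member of the family together with its exact weight counts."""

    net: UNet
    spec: ArchitectureSpec
    kernel_weight_count: int
    total_trainable_count: int
    seed: int = 0

    def forward(self, x, train=True):
        return self.net.forward(x, train)


def build_network(spec: ArchitectureSpec, seed: int = 0,
                  input_shape: tuple[int, int] = (64, 64)) -> NetworkModel:
    """Instantiate a family member with seeded, reproducible initialization.

    For variants covered by the counting algebra the introspected kernel
    count of the built network equals :func:`kernel_weight_count`.
    """
    net = UNet(spec, seed=seed, input_shape=input_shape)
    return NetworkModel(
        net=net,
        spec=spec,
        kernel_weight_count=net.introspected_kernel_count(),
        total_trainable_count=net.total_trainable_count(),
        seed=seed,
    )


def predict_image(model: NetworkModel, image: np.ndarray) -> np.ndarray:
    """Whole-image fully-convolutional inference.

    The preprocessed image (2-D, or CHW for multi-channel specs) is
    reflect-padded to the nearest multiple of ``2**(levels-1)``, passed
    through the network in inference mode, and the foreground-class
    probability map is cropped back to the input shape.
    """
    spec = model.spec
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = img[None]
    if img.shape[0] != spec.in_channels:
        raise ValueError(
            f"image has {img.shape[0]} channels, spec expects {spec.in_channels}")
    _, h, w = img.shape
    div = 2 ** (spec.levels - 1)
    ph = (-h) % div
    pw = (-w) % div
    if ph or pw:
        img = np.pad(img, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    out = model.net.forward(img[None], train=False)
    if isinstance(out, tuple):
        out = out[0]
    fg = out[0, 1] if spec.out_classes > 1 else out[0, 0]
    return fg[:h, :w]
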