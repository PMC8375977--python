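"""Segmentation network construction and parameter accounting.

Two families are built here:

* **MoNet** — a shallow U-Net-like encoder-decoder with only two stride-2
  down-sampling steps (bottleneck at 64x64 for a 256x256 input). At every
  stage a repeated decreasingly dilated convolution (RDDC) block extracts
  multi-scale features: four 3x3 conv blocks with dilation rates 4, 3, 2, 1,
  each followed by spatial dropout, wrapped in a residual short connection.
* **U-Net baselines** — the classic 4-down/4-up U-Net with channel doubling,
  two normalized 3x3 conv blocks per stage, 2x2 max pooling, 2x2 transposed
  convolutions (bias, no normalization) and concatenation skips, at 16 or 64
  base filters.

"Parameter count" throughout this package includes the batch-norm running
statistics (4 parameters per normalized channel: scale, shift, running mean,
running variance), which is the convention under which the baseline totals
U-Net-16 = 1,946,705 and U-Net-64 = 31,054,145 are exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    ELU,
    Layer,
    MaxPool2d,
    Sequential,
    Sigmoid,
    SpatialDropout2d,
)

CANONICAL_DILATIONS = (4, 3, 2, 1)


class InvalidSpecError(ValueError):
    """Raised when a declarative layer/architecture spec violates invariants."""


# ---------------------------------------------------------------------------
# Declarative specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvBlockSpec:
    """One conv block: 3x3 convolution + (optional) batch norm + ELU."""

    in_channels: int
    out_channels: int
    kernel: tuple[int, int] = (3, 3)
    stride: int = 1
    dilation: int = 1
    normalized: bool = True
    activation: str = "elu"
    transposed: bool = False

    def validate(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise InvalidSpecError("channel counts must be positive")
        if self.dilation < 1:
            raise InvalidSpecError("dilation must be >= 1")
        if self.stride not in (1, 2):
            raise InvalidSpecError("stride must be 1 or 2")
        return self

    @property
    def parameter_count(self) -> int:
        kh, kw = self.kernel
        n = kh * kw * self.in_channels * self.out_channels + self.out_channels
        if self.normalized:
            n += 4 * self.out_channels
        return n


@dataclass(frozen=True)
class RddcSpec:
    """Repeated decreasingly dilated convolution block."""

    channels: int
    dilation_schedule: tuple[int, ...] = CANONICAL_DILATIONS
    dropout_rate: float = 0.1
    residual: str = "identity"   # "identity" | "projection" | "none"
    allow_noncanonical: bool = False

    def validate(self):
        if self.channels < 1:
            raise InvalidSpecError("channels must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise InvalidSpecError("dropout rate must be in [0, 1)")
        if (tuple(self.dilation_schedule) != CANONICAL_DILATIONS
                and not self.allow_noncanonical):
            raise InvalidSpecError(
                f"dilation schedule {self.dilation_schedule} is not the "
                f"canonical {CANONICAL_DILATIONS}; pass "
                "allow_noncanonical=True to override")
        if self.residual not in ("identity", "projection", "none"):
            raise InvalidSpecError(f"unknown residual form {self.residual!r}")
        return self


@dataclass(frozen=True)
class MoNetConfig:
    """Structural knobs of the MoNet graph that affect parameter totals."""

    widths: tuple[int, int, int] = (20, 39, 66)
    up_kernel: int = 3
    extra_stem: bool = False
    residual: str = "projection"
    extra_fuse: bool = False
    normalized_up: bool = True
    dropout: float = 0.1
    dilations: tuple[int, ...] = CANONICAL_DILATIONS


#: Width/kernel configuration frozen by ``resolve_monet_widths``: the unique
#: configuration in the documented structural grammar with strictly
#: increasing, at-most-doubling stage widths whose parameter count equals the
#: published total of 403,556.
CANONICAL_MONET = MoNetConfig()


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of a full segmentation network."""

    name: str
    stage_widths: tuple[int, ...]
    n_downsamples: int
    input_shape: tuple[int, int, int] = (256, 256, 1)
    skip_mode: str = "concat"
    output_channels: int = 1
    output_activation: str = "sigmoid"
    monet: MoNetConfig | None = None
    base_filters: int | None = None

    def validate(self):
        h, w, _ = self.input_shape
        f = 2 ** self.n_downsamples
        if h % f or w % f:
            raise InvalidSpecError(
                f"input {h}x{w} not divisible by 2^{self.n_downsamples}")
        return self

    @property
    def bottleneck_size(self) -> tuple[int, int]:
        h, w, _ = self.input_shape
        f = 2 ** self.n_downsamples
        return h // f, w // f


def monet_spec(config: MoNetConfig = CANONICAL_MONET,
               input_size: int = 256) -> ArchitectureSpec:
    return ArchitectureSpec(
        name="monet", stage_widths=tuple(config.widths), n_downsamples=2,
        input_shape=(input_size, input_size, 1), monet=config).validate()


def unet_spec(base_filters: int, input_size: int = 256) -> ArchitectureSpec:
    widths = tuple(base_filters * 2 ** i for i in range(5))
    return ArchitectureSpec(
        name=f"unet{base_filters}", stage_widths=widths, n_downsamples=4,
        input_shape=(input_size, input_size, 1),
        base_filters=base_filters).validate()


# ---------------------------------------------------------------------------
# Layer construction
# ---------------------------------------------------------------------------

def make_conv_block(spec: ConvBlockSpec, dtype=np.float32) -> Sequential:
    """Build conv(+bias) -> batch norm -> ELU from a block spec."""
    spec.validate()
    layers, names = [], []
    if spec.transposed:
        layers.append(ConvTranspose2d(spec.in_channels, spec.out_channels,
                                      kernel=spec.kernel, stride=spec.stride,
                                      dtype=dtype))
    else:
        layers.append(Conv2d(spec.in_channels, spec.out_channels,
                             kernel=spec.kernel, stride=spec.stride,
                             dilation=spec.dilation, dtype=dtype))
    names.append("conv")
    if spec.normalized:
        layers.append(BatchNorm2d(spec.out_channels, dtype=dtype))
        names.append("norm")
    if spec.activation == "elu":
        layers.append(ELU())
        names.append("act")
    elif spec.activation not in (None, "none", "linear"):
        raise InvalidSpecError(f"unknown activation {spec.activation!r}")
    return Sequential(*layers, names=names)


class RddcBlock(Layer):
    """Four dilated conv blocks (rates 4,3,2,1) + spatial dropout + residual."""

    def __init__(self, spec: RddcSpec, dtype=np.float32):
        super().__init__()
        spec.validate()
        self.spec = spec
        c = spec.channels
        stack, names = [], []
        for i, d in enumerate(spec.dilation_schedule):
            stack.append(make_conv_block(
                ConvBlockSpec(c, c, dilation=d), dtype=dtype))
            names.append(f"conv{i}")
            stack.append(SpatialDropout2d(spec.dropout_rate))
            names.append(f"drop{i}")
        self.body = Sequential(*stack, names=names)
        self.projection = (Conv2d(c, c, kernel=1, dtype=dtype)
                           if spec.residual == "projection" else None)

    def children(self):
        out = [("body", self.body)]
        if self.projection is not None:
            out.append(("projection", self.projection))
        return out

    def forward(self, x, training=False, rng=None):
        y = self.body.forward(x, training=training, rng=rng)
        if self.spec.residual == "none":
            out = y
        elif self.projection is not None:
            out = y + self.projection.forward(x, training=training, rng=rng)
        else:
            out = y + x
        return self._record(out)

    def backward(self, grad):
        dx = self.body.backward(grad)
        if self.spec.residual == "none":
            return dx
        if self.projection is not None:
            return dx + self.projection.backward(grad)
        return dx + grad


def make_rddc_block(spec: RddcSpec, dtype=np.float32) -> RddcBlock:
    return RddcBlock(spec, dtype=dtype)


def _down_block(cin, cout, dtype):
    return make_conv_block(ConvBlockSpec(cin, cout, stride=2), dtype=dtype)


def _up_block(cin, cout, kernel, normalized, dtype):
    return make_conv_block(
        ConvBlockSpec(cin, cout, kernel=(kernel, kernel), stride=2,
                      normalized=normalized, transposed=True), dtype=dtype)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

class MoNet(Layer):
    """The MoNet graph: 2 down-samples, RDDC at every stage, concat skips."""

    def __init__(self, config: MoNetConfig = CANONICAL_MONET,
                 dtype=np.float32):
        super().__init__()
        self.config = config
        f1, f2, f3 = config.widths
        rd = dict(dilation_schedule=config.dilations,
                  dropout_rate=config.dropout, residual=config.residual)

        stem = [make_conv_block(ConvBlockSpec(1, f1), dtype=dtype)]
        if config.extra_stem:
            stem.append(make_conv_block(ConvBlockSpec(f1, f1), dtype=dtype))
        self.stem = Sequential(*stem)
        self.enc1 = RddcBlock(RddcSpec(f1, **rd), dtype=dtype)
        self.down1 = _down_block(f1, f2, dtype)
        self.enc2 = RddcBlock(RddcSpec(f2, **rd), dtype=dtype)
        self.down2 = _down_block(f2, f3, dtype)
        self.bottleneck = RddcBlock(RddcSpec(f3, **rd), dtype=dtype)
        self.up1 = _up_block(f3, f2, config.up_kernel, config.normalized_up,
                             dtype)
        fuse1 = [make_conv_block(ConvBlockSpec(2 * f2, f2), dtype=dtype)]
        if config.extra_fuse:
            fuse1.append(make_conv_block(ConvBlockSpec(f2, f2), dtype=dtype))
        self.fuse1 = Sequential(*fuse1)
        self.dec1 = RddcBlock(RddcSpec(f2, **rd), dtype=dtype)
        self.up2 = _up_block(f2, f1, config.up_kernel, config.normalized_up,
                             dtype)
        fuse2 = [make_conv_block(ConvBlockSpec(2 * f1, f1), dtype=dtype)]
        if config.extra_fuse:
            fuse2.append(make_conv_block(ConvBlockSpec(f1, f1), dtype=dtype))
        self.fuse2 = Sequential(*fuse2)
        self.dec2 = RddcBlock(RddcSpec(f1, **rd), dtype=dtype)
        self.head = Conv2d(f1, 1, kernel=1, dtype=dtype)
        self.out_act = Sigmoid()

    _order = ("stem", "enc1", "down1", "enc2", "down2", "bottleneck",
              "up1", "fuse1", "dec1", "up2", "fuse2", "dec2",
              "head", "out_act")

    def children(self):
        return [(n, getattr(self, n)) for n in self._order]

    def forward(self, x, training=False, rng=None):
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expected input of shape (B, 1, H, W)")
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise ValueError("input spatial size must be divisible by 4")
        kw = dict(training=training, rng=rng)
        e1 = self.enc1.forward(self.stem.forward(x, **kw), **kw)
        e2 = self.enc2.forward(self.down1.forward(e1, **kw), **kw)
        b = self.bottleneck.forward(self.down2.forward(e2, **kw), **kw)
        u1 = self.up1.forward(b, **kw)
        d1 = self.dec1.forward(
            self.fuse1.forward(np.concatenate([u1, e2], axis=1), **kw), **kw)
        u2 = self.up2.forward(d1, **kw)
        d2 = self.dec2.forward(
            self.fuse2.forward(np.concatenate([u2, e1], axis=1), **kw), **kw)
        out = self.out_act.forward(self.head.forward(d2, **kw), **kw)
        return self._record(out)

    def backward(self, grad):
        f1, f2, _ = self.config.widths
        g = self.head.backward(self.out_act.backward(grad))
        g = self.fuse2.backward(self.dec2.backward(g))
        gu2, ge1 = g[:, :f1], g[:, f1:]
        g = self.up2.backward(gu2)
        g = self.fuse1.backward(self.dec1.backward(g))
        gu1, ge2 = g[:, :f2], g[:, f2:]
        g = self.up1.backward(gu1)
        g = self.down2.backward(self.bottleneck.backward(g))
        g = self.down1.backward(self.enc2.backward(g + ge2))
        g = self.stem.backward(self.enc1.backward(g + ge1))
        return g


class UNet(Layer):
    """Classic 4-down/4-up U-Net with channel doubling and concat skips."""

    def __init__(self, base_filters=16, dtype=np.float32):
        super().__init__()
        if base_filters < 1:
            raise InvalidSpecError("base_filters must be positive")
        self.base_filters = base_filters
        f = [base_filters * 2 ** i for i in range(5)]
        self.widths = f

        def double_conv(cin, cout):
            return Sequential(
                make_conv_block(ConvBlockSpec(cin, cout), dtype=dtype),
                make_conv_block(ConvBlockSpec(cout, cout), dtype=dtype),
                names=["a", "b"])

        self.enc = [double_conv(1 if i == 0 else f[i - 1], f[i])
                    for i in range(4)]
        self.pools = [MaxPool2d(2) for _ in range(4)]
        self.mid = double_conv(f[3], f[4])
        self.ups = [ConvTranspose2d(f[i + 1], f[i], kernel=2, stride=2,
                                    dtype=dtype) for i in range(4)]
        self.dec = [double_conv(2 * f[i], f[i]) for i in range(4)]
        self.head = Conv2d(f[0], 1, kernel=1, dtype=dtype)
        self.out_act = Sigmoid()

    def children(self):
        out = []
        for i in range(4):
            out += [(f"enc{i}", self.enc[i]), (f"pool{i}", self.pools[i])]
        out.append(("mid", self.mid))
        for i in range(3, -1, -1):
            out += [(f"up{i}", self.ups[i]), (f"dec{i}", self.dec[i])]
        out += [("head", self.head), ("out_act", self.out_act)]
        return out

    def forward(self, x, training=False, rng=None):
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expected input of shape (B, 1, H, W)")
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError("input spatial size must be divisible by 16")
        kw = dict(training=training, rng=rng)
        skips = []
        for i in range(4):
            x = self.enc[i].forward(x, **kw)
            skips.append(x)
            x = self.pools[i].forward(x, **kw)
        x = self.mid.forward(x, **kw)
        for i in range(3, -1, -1):
            x = self.ups[i].forward(x, **kw)
            x = self.dec[i].forward(
                np.concatenate([x, skips[i]], axis=1), **kw)
        out = self.out_act.forward(self.head.forward(x, **kw), **kw)
        return self._record(out)

    def backward(self, grad):
        f = self.widths
        g = self.head.backward(self.out_act.backward(grad))
        gskips = [None] * 4
        for i in range(4):
            g = self.dec[i].backward(g)
            gu, gs = g[:, :f[i]], g[:, f[i]:]
            gskips[i] = gs
            g = self.ups[i].backward(gu)
        g = self.mid.backward(g)
        for i in range(3, -1, -1):
            g = self.pools[i].backward(g)
            g = self.enc[i].backward(g + gskips[i])
        return g


def build_monet(spec: ArchitectureSpec | MoNetConfig | None = None,
                dtype=np.float32) -> MoNet:
    """Build the MoNet network (canonical frozen configuration by default)."""
    if spec is None:
        config = CANONICAL_MONET
    elif isinstance(spec, MoNetConfig):
        config = spec
    else:
        spec.validate()
        if spec.n_downsamples != 2:
            raise InvalidSpecError("MoNet uses exactly 2 down-sampling steps")
        config = spec.monet or replace(CANONICAL_MONET,
                                       widths=tuple(spec.stage_widths))
    return MoNet(config, dtype=dtype)


def build_unet(base_filters: int = 16, dtype=np.float32) -> UNet:
    """Build a classic U-Net baseline (16 or 64 base filters in the paper)."""
    return UNet(base_filters, dtype=dtype)


def build_architecture(name: str, dtype=np.float32) -> Layer:
    """Registry lookup: 'monet', 'unet16' or 'unet64'."""
    key = name.lower().replace("-", "").replace("_", "")
    if key == "monet":
        return build_monet(dtype=dtype)
    if key.startswith("unet"):
        return build_unet(int(key[4:]), dtype=dtype)
    raise InvalidSpecError(f"unknown architecture {name!r}")


ARCHITECTURES = ("monet", "unet16", "unet64")


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------

def count_parameters(net: Layer, trainable_only: bool = False) -> int:
    """Total tensor elements registered by the network's layers.

    Includes batch-norm running statistics unless ``trainable_only``.
    """
    return sum(int(a.size) for _, a, tr in net.named_tensors()
               if tr or not trainable_only)


def parameter_table(net: Layer):
    """Per-tensor accounting: list of (name, shape, size, trainable)."""
    return [(n, tuple(a.shape), int(a.size), tr)
            for n, a, tr in net.named_tensors()]


def monet_parameter_count(config: MoNetConfig) -> int:
    """Closed-form parameter total of the MoNet graph for a configuration.

    Walks the same structural grammar as :class:`MoNet`; used by the width
    resolver so that the search does not have to materialise weights.
    """
    f1, f2, f3 = config.widths
    k = config.up_kernel

    def conv(i, o, kk=3, norm=True):
        return kk * kk * i * o + o + (4 * o if norm else 0)

    def rddc(c):
        t = 4 * conv(c, c)
        if config.residual == "projection":
            t += c * c + c
        return t

    total = conv(1, f1)
    if config.extra_stem:
        total += conv(f1, f1)
    total += rddc(f1) + conv(f1, f2) + rddc(f2) + conv(f2, f3) + rddc(f3)
    total += conv(f3, f2, k, config.normalized_up) + conv(2 * f2, f2)
    if config.extra_fuse:
        total += conv(f2, f2)
    total += rddc(f2)
    total += conv(f2, f1, k, config.normalized_up) + conv(2 * f1, f1)
    if config.extra_fuse:
        total += conv(f1, f1)
    total += rddc(f1) + f1 + 1
    return total


# ---------------------------------------------------------------------------
# Width resolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WidthSearchSpace:
    """Bounded enumeration of MoNet structural configurations.

    The default documented space ties stage widths together by ratios
    (f2/f1 and f3/f2 in ``ratios``); setting ``free_widths=True`` instead
    enumerates all integer triples f1 < f2 <= 2*f1, f2 < f3 <= 2*f2
    (standard at-most-doubling width growth).
    """

    f1_range: tuple[int, int] = (12, 32)
    ratios: tuple[float, ...] = (1.5, 2.0)
    up_kernels: tuple[int, ...] = (2, 3)
    extra_stem_options: tuple[bool, ...] = (False, True)
    residual_options: tuple[str, ...] = ("identity", "projection")
    extra_fuse_options: tuple[bool, ...] = (False, True)
    normalized_up_options: tuple[bool, ...] = (True, False)
    free_widths: bool = False

    def width_triples(self):
        lo, hi = self.f1_range
        if self.free_widths:
            for f1 in range(lo, hi + 1):
                for f2 in range(f1 + 1, 2 * f1 + 1):
                    for f3 in range(f2 + 1, 2 * f2 + 1):
                        yield f1, f2, f3
        else:
            for f1 in range(lo, hi + 1):
                for r2, r3 in itertools.product(self.ratios, repeat=2):
                    f2, f3 = f1 * r2, f1 * r2 * r3
                    if f2 == int(f2) and f3 == int(f3):
                        yield f1, int(f2), int(f3)

    def configurations(self):
        for widths in self.width_triples():
            for k, es, res, ef, nu in itertools.product(
                    self.up_kernels, self.extra_stem_options,
                    self.residual_options, self.extra_fuse_options,
                    self.normalized_up_options):
                yield MoNetConfig(widths=widths, up_kernel=k, extra_stem=es,
                                  residual=res, extra_fuse=ef,
                                  normalized_up=nu)


DOCUMENTED_SEARCH_SPACE = WidthSearchSpace()
EXTENDED_SEARCH_SPACE = WidthSearchSpace(free_widths=True)


@dataclass
class WidthResolution:
    """Outcome of a width search: exact matches and/or nearest misses."""

    target: int
    exact: list = field(default_factory=list)
    nearest: list = field(default_factory=list)   # (delta, count, config)

    @property
    def resolved(self) -> bool:
        return bool(self.exact)


def resolve_monet_widths(target_count: int,
                         search_space: WidthSearchSpace =
                         DOCUMENTED_SEARCH_SPACE,
                         n_nearest: int = 5) -> WidthResolution:
    """Search a configuration space for an exact parameter-count match.

    Returns every exact match plus the ``n_nearest`` closest configurations
    with their deltas; when no exact match exists the result reports the
    nearest misses rather than failing silently.
    """
    configs = list(search_space.configurations())
    if not configs:
        raise InvalidSpecError("empty search space")
    res = WidthResolution(target=target_count)
    scored = []
    for cfg in configs:
        n = monet_parameter_count(cfg)
        if n == target_count:
            res.exact.append(cfg)
        scored.append((abs(n - target_count), n, cfg))
    scored.sort(key=lambda t: (t[0], t[2].widths, t[2].up_kernel))
    res.nearest = scored[:n_nearest]
    return res


# ---------------------------------------------------------------------------
# Receptive-field arithmetic
# ---------------------------------------------------------------------------

def rddc_receptive_field(dilations=CANONICAL_DILATIONS, kernel=3) -> int:
    """Receptive field of the RDDC conv stack at unit stride.

    Each k x k convolution with dilation d grows the field by (k-1)*d, so
    the canonical 4-3-2-1 schedule of 3x3 convolutions spans
    1 + 2*(4+3+2+1) = 21 pixels.
    """
    return 1 + sum((kernel - 1) * d for d in dilations)


def monet_encoder_receptive_fields(config: MoNetConfig = CANONICAL_MONET):
    """Receptive field (in input pixels) after each encoder stage of MoNet."""
    rf, jump = 1, 1
    out = []

    def conv(kernel, dilation=1, stride=1):
        nonlocal rf, jump
        rf += (kernel - 1) * dilation * jump
        jump *= stride

    conv(3)                                   # stem
    if config.extra_stem:
        conv(3)
    for d in config.dilations:                # stage-1 RDDC
        conv(3, dilation=d)
    out.append(rf)
    conv(3, stride=2)                         # down 1
    for d in config.dilations:
        conv(3, dilation=d)
    out.append(rf)
    conv(3, stride=2)                         # down 2
    for d in config.dilations:                # bottleneck RDDC
        conv(3, dilation=d)
    out.append(rf)
    return out
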