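"""Declarative architecture specs and network construction.

Six variants are supported, matching the study design:

========================  =======================================================
variant                   inputs
========================  =======================================================
``cnn``                   single image stream (state-of-the-art CNN baseline)
``cnn_ts``                image stream + raw integer week timestamp
``xcnn_abs``              image + absolute-differencing map, cross-connected
``xcnn_rel``              image + relative-differencing map, cross-connected
``xcnn_abs_ts``           as ``xcnn_abs``, plus the timestamp
``xcnn_rel_ts``           as ``xcnn_rel``, plus the timestamp
========================  =======================================================

Every network stacks five *chains* — two 3x3 convolutions, 2x2/stride-2 max
pooling, batch normalisation and (except the last chain) dropout — then
flattens into dense layers of 64 and 32 units (batch norm only, no dropout)
and a softmax over the classes. Cross-modal variants run one chain per
stream and exchange feature maps after each chain through 1x1 convolutions
of 8 filters in both directions (I→D and D→I), merged by concatenation.
Convolutions use 'same' padding; weights are He-Gaussian initialised, ReLU
activated, and L2-penalised (kernels only).

The absolute/relative distinction changes only which difference maps are
fed in, never the architecture, so any performance gap is attributable to
the temporal descriptor itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, BatchNorm, Conv2D, Dense, Dropout, Flatten, MaxPool2x2, ReLU, SoftmaxCrossEntropy, softmax

VARIANTS = ("cnn", "cnn_ts", "xcnn_abs", "xcnn_rel", "xcnn_abs_ts", "xcnn_rel_ts")

#: fixed rescale of raw integer pixel intensities at the model input;
#: a constant (not data-dependent) factor: 16-bit full scale -> [0, 1]
INPUT_SCALE = 1.0 / 65535.0


@dataclass(frozen=True)
class HyperParams:
    batch_size: int = 32
    l2_lambda: float = 0.0003
    dropout_rate: float = 0.25
    #: Adam step size; the desk-scale datasets give only ~100 optimizer
    #: steps in 5 epochs, which needs a larger step than big-data regimes
    learning_rate: float = 3e-3
    dense_widths: tuple = (64, 32)


@dataclass(frozen=True)
class ChainSpec:
    """One chain: two 3x3 convolutions, 2x2 pool, BN, optional dropout."""

    conv_filters: tuple
    kernel: int = 3
    batch_norm: bool = True
    dropout: bool = True


@dataclass(frozen=True)
class CrossConnectSpec:
    """1x1 cross-connections exchanged between streams, merged by concat."""

    filters: int = 8
    kernel: int = 1


@dataclass(frozen=True)
class ArchitectureSpec:
    variant: str
    input_height: int
    input_width: int
    n_classes: int = 2
    hyper: HyperParams = field(default_factory=HyperParams)
    #: cross-connections taken after the BN/dropout block (the alternative,
    #: before regularisation, is architecturally open; this flag exposes it)
    cross_after_regularisation: bool = True

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")

    @property
    def has_diff_stream(self) -> bool:
        return self.variant.startswith("xcnn")

    @property
    def use_timestamp(self) -> bool:
        return self.variant.endswith("_ts")

    @property
    def diff_mode(self):
        if "abs" in self.variant:
            return "absolute"
        if "rel" in self.variant:
            return "relative"
        return None


def chain_specs(variant: str):
    """The five per-chain filter plans. Cross-modal streams use half the
    filters of the single-stream baseline except in the final chain."""
    if variant.startswith("xcnn"):
        widths = [(8, 8), (16, 16), (16, 16), (16, 16), (32, 32)]
    else:
        widths = [(16, 16), (32, 32), (32, 32), (32, 32), (32, 32)]
    return [
        ChainSpec(conv_filters=w, dropout=(i < 4))  # chain 5: BN only
        for i, w in enumerate(widths)
    ]


# ---------------------------------------------------------------------------
# network blocks


class ChainBlock:
    """conv-relu-conv-relu-pool (features) then BN(-dropout) (regularisation)."""

    def __init__(self, spec: ChainSpec, in_channels, hyper, rng, name="chain", reg_channels=None):
        f1, f2 = spec.conv_filters
        self.spec = spec
        self.out_channels = f2
        self.features = [
            Conv2D(in_channels, f1, spec.kernel, rng=rng, name=f"{name}.conv1"),
            ReLU(),
            Conv2D(f1, f2, spec.kernel, rng=rng, name=f"{name}.conv2"),
            ReLU(),
            MaxPool2x2(),
        ]
        self.reg = []
        reg_ch = f2 if reg_channels is None else reg_channels
        if spec.batch_norm:
            self.reg.append(BatchNorm(reg_ch, name=f"{name}.bn"))
        if spec.dropout:
            self.reg.append(Dropout(hyper.dropout_rate, rng))

    def params(self):
        out = []
        for layer in self.features + self.reg:
            out.extend(layer.params())
        return out

    def forward_features(self, x, training):
        for layer in self.features:
            x = layer.forward(x, training)
        return x

    def backward_features(self, g):
        for layer in reversed(self.features):
            g = layer.backward(g)
        return g

    def forward_reg(self, x, training):
        for layer in self.reg:
            x = layer.forward(x, training)
        return x

    def backward_reg(self, g):
        for layer in reversed(self.reg):
            g = layer.backward(g)
        return g

    def forward(self, x, training=False):
        return self.forward_reg(self.forward_features(x, training), training)

    def backward(self, g):
        return self.backward_features(self.backward_reg(g))


class XChainBlock:
    """Two parallel chains with bidirectional 1x1 cross-connections.

    After each stream's chain, an 8-filter 1x1 convolution of the opposite
    stream's output is concatenated on (channels grow by the cross width).
    With ``cross_after_regularisation=False`` the exchange instead happens
    between pooling and the BN/dropout block.
    """

    def __init__(self, spec, cross, in_channels_i, in_channels_d, hyper, rng, name="xchain", cross_after=True):
        self.cross_after = cross_after
        f2 = spec.conv_filters[1]
        reg_ch = None if cross_after else f2 + cross.filters
        self.chain_i = ChainBlock(spec, in_channels_i, hyper, rng, name=f"{name}.I", reg_channels=reg_ch)
        self.chain_d = ChainBlock(spec, in_channels_d, hyper, rng, name=f"{name}.D", reg_channels=reg_ch)
        self.cross_i2d = Conv2D(f2, cross.filters, cross.kernel, rng=rng, name=f"{name}.I2D")
        self.cross_d2i = Conv2D(f2, cross.filters, cross.kernel, rng=rng, name=f"{name}.D2I")
        self.relu_i2d = ReLU()
        self.relu_d2i = ReLU()
        self.cross_filters = cross.filters
        self.out_channels = f2 + cross.filters

    def params(self):
        out = self.chain_i.params() + self.chain_d.params()
        out += self.cross_i2d.params() + self.cross_d2i.params()
        return out

    def cross_parameter_count(self):
        return sum(p.size for p in self.cross_i2d.params() + self.cross_d2i.params())

    def _exchange(self, ci, cd, training):
        if ci.shape[:3] != cd.shape[:3]:
            raise ValueError("stream spatial dimensions do not match")
        xi2d = self.relu_i2d.forward(self.cross_i2d.forward(ci, training), training)
        xd2i = self.relu_d2i.forward(self.cross_d2i.forward(cd, training), training)
        return (
            np.concatenate([ci, xd2i], axis=-1),
            np.concatenate([cd, xi2d], axis=-1),
        )

    def _exchange_backward(self, gi, gd):
        k = self.cross_filters
        g_ci, g_xd2i = gi[..., :-k], gi[..., -k:]
        g_cd, g_xi2d = gd[..., :-k], gd[..., -k:]
        g_ci = g_ci + self.cross_i2d.backward(self.relu_i2d.backward(g_xi2d))
        g_cd = g_cd + self.cross_d2i.backward(self.relu_d2i.backward(g_xd2i))
        return g_ci, g_cd

    def forward(self, xi, xd, training=False):
        fi = self.chain_i.forward_features(xi, training)
        fd = self.chain_d.forward_features(xd, training)
        if self.cross_after:
            ci = self.chain_i.forward_reg(fi, training)
            cd = self.chain_d.forward_reg(fd, training)
            return self._exchange(ci, cd, training)
        oi, od = self._exchange(fi, fd, training)
        return self.chain_i.forward_reg(oi, training), self.chain_d.forward_reg(od, training)

    def backward(self, gi, gd):
        if self.cross_after:
            g_ci, g_cd = self._exchange_backward(gi, gd)
            g_fi = self.chain_i.backward_reg(g_ci)
            g_fd = self.chain_d.backward_reg(g_cd)
        else:
            g_oi = self.chain_i.backward_reg(gi)
            g_od = self.chain_d.backward_reg(gd)
            g_fi, g_fd = self._exchange_backward(g_oi, g_od)
        return self.chain_i.backward_features(g_fi), self.chain_d.backward_features(g_fd)


def build_chain(spec: ChainSpec, in_channels: int, hyper: HyperParams | None = None, rng=None) -> ChainBlock:
    """Standalone chain constructor (baseline building block)."""
    hyper = hyper or HyperParams()
    rng = rng if rng is not None else np.random.default_rng(0)
    return ChainBlock(spec, in_channels, hyper, rng)


def build_xchain(
    spec: ChainSpec,
    cross: CrossConnectSpec,
    in_channels_i: int,
    in_channels_d: int,
    hyper: HyperParams | None = None,
    rng=None,
    cross_after: bool = True,
) -> XChainBlock:
    """Standalone cross-connected chain constructor."""
    hyper = hyper or HyperParams()
    rng = rng if rng is not None else np.random.default_rng(0)
    return XChainBlock(spec, cross, in_channels_i, in_channels_d, hyper, rng, cross_after=cross_after)


# ---------------------------------------------------------------------------
# full networks


class Network:
    """A built ChronoMID classifier (any of the six variants)."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        self.rng = np.random.default_rng(seed)
        hyper = spec.hyper
        specs = chain_specs(spec.variant)

        h, w = spec.input_height, spec.input_width
        self.blocks = []
        in_i = in_d = 1
        for i, cs in enumerate(specs):
            if spec.has_diff_stream:
                blk = XChainBlock(
                    cs,
                    CrossConnectSpec(),
                    in_i,
                    in_d,
                    hyper,
                    self.rng,
                    name=f"xchain{i + 1}",
                    cross_after=spec.cross_after_regularisation,
                )
                in_i = in_d = blk.out_channels
            else:
                blk = ChainBlock(cs, in_i, hyper, self.rng, name=f"chain{i + 1}")
                in_i = blk.out_channels
            self.blocks.append(blk)
            h, w = h // 2, w // 2
            if h < 1 or w < 1:
                raise ValueError(
                    f"input {spec.input_height}x{spec.input_width} too small for "
                    f"{len(specs)} pooling stages"
                )
        self.final_h, self.final_w = h, w

        flat = h * w * in_i * (2 if spec.has_diff_stream else 1)
        flat += 1 if spec.use_timestamp else 0
        self.flatten_i = Flatten()
        self.flatten_d = Flatten()
        d1, d2 = hyper.dense_widths
        self.head = [
            Dense(flat, d1, rng=self.rng, name="dense1"),
            BatchNorm(d1, name="dense1.bn"),
            ReLU(),
            Dense(d1, d2, rng=self.rng, name="dense2"),
            BatchNorm(d2, name="dense2.bn"),
            ReLU(),
            Dense(d2, spec.n_classes, rng=self.rng, name="output"),
        ]
        self.loss = SoftmaxCrossEntropy()

    # -- parameters

    def params(self):
        out = []
        for blk in self.blocks:
            out.extend(blk.params())
        for layer in self.head:
            out.extend(layer.params())
        return out

    # -- execution

    def _prepare(self, images, diffs, weeks):
        x = np.asarray(images, dtype=np.float64) * INPUT_SCALE
        if x.ndim == 3:
            x = x[..., None]
        d = None
        if self.spec.has_diff_stream:
            if diffs is None:
                raise ValueError(f"variant {self.spec.variant} requires difference maps")
            d = np.asarray(diffs, dtype=np.float64) * INPUT_SCALE
            if d.ndim == 3:
                d = d[..., None]
        ts = None
        if self.spec.use_timestamp:
            if weeks is None:
                raise ValueError(f"variant {self.spec.variant} requires week timestamps")
            ts = inject_timestamp(self, weeks)
        return x, d, ts

    def forward(self, images, diffs=None, weeks=None, training=False):
        x, d, ts = self._prepare(images, diffs, weeks)
        if self.spec.has_diff_stream:
            for blk in self.blocks:
                x, d = blk.forward(x, d, training)
            flat = np.concatenate(
                [self.flatten_i.forward(x, training), self.flatten_d.forward(d, training)],
                axis=1,
            )
        else:
            for blk in self.blocks:
                x = blk.forward(x, training)
            flat = self.flatten_i.forward(x, training)
        if ts is not None:
            flat = np.concatenate([flat, ts], axis=1)
        self._flat_width = flat.shape[1]
        z = flat
        for layer in self.head:
            z = layer.forward(z, training)
        return z

    def backward(self, grad_logits):
        g = grad_logits
        for layer in reversed(self.head):
            g = layer.backward(g)
        if self.spec.use_timestamp:
            g = g[:, :-1]
        if self.spec.has_diff_stream:
            half = g.shape[1] // 2
            gi = self.flatten_i.backward(g[:, :half])
            gd = self.flatten_d.backward(g[:, half:])
            for blk in reversed(self.blocks):
                gi, gd = blk.backward(gi, gd)
        else:
            gi = self.flatten_i.backward(g)
            for blk in reversed(self.blocks):
                gi = blk.backward(gi)

    def predict_proba(self, images, diffs=None, weeks=None, batch_size=64):
        n = len(images)
        out = []
        for i in range(0, n, batch_size):
            logits = self.forward(
                images[i : i + batch_size],
                None if diffs is None else diffs[i : i + batch_size],
                None if weeks is None else weeks[i : i + batch_size],
                training=False,
            )
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)

    # -- reporting

    def summary(self):
        rows = []
        for p in self.params():
            rows.append((p.name, p.value.shape, p.size, p.trainable))
        return rows


def build_model(spec: ArchitectureSpec, seed: int = 0) -> Network:
    """Construct a trainable classifier from a declarative spec."""
    return Network(spec, seed=seed)


def inject_timestamp(model: Network, weeks) -> np.ndarray:
    """Validate and wire raw integer weeks as a unit-sized model input.

    Weeks enter unnormalised (week 5 enters as 5.0); supplying timestamps
    to a variant without a timestamp input is an error.
    """
    if not model.spec.use_timestamp:
        raise ValueError(f"variant {model.spec.variant} takes no timestamp input")
    ts = np.asarray(weeks, dtype=np.float64).reshape(-1, 1)
    if np.any(ts < 0):
        raise ValueError("weeks must be non-negative")
    return ts


def count_parameters(model: Network) -> int:
    """Total parameters, trainable plus non-trainable (BN moving stats)."""
    return int(sum(p.size for p in model.params()))
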