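"""TongueCaps: residual convolutional feature extractor + capsule classifier.

The network is declared as an :class:`ArchitectureSpec` — an ordered list of
:class:`LayerSpec` rows mirroring the published parameter table — from which
the package can symbolically trace output shapes, count parameters and
estimate FLOPs without instantiating weights, or build a trainable
:class:`TongueCaps` model (NumPy + the in-package autodiff).

Layer arithmetic follows the conventions stated with the architecture:
convolutions in the stem and residual blocks use 'same' padding (spatial
size ceil(n/stride)); the primary-capsule convolutions use 'valid' padding
(forced by the published 16×16 → 14×14 worked example); convolutions
followed by batch norm carry no bias.  Residual blocks come in two
variants: *a* adds an identity shortcut (requires unchanged channels and
stride 1), *b* convolves the shortcut branch (1×1 projection + BN).  The
``use_shortcuts`` flag drops every shortcut branch, producing the
plain-CNN ablation used as a baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import autograd as ag
from . import capsule
from .autograd import Tensor

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "ShapeTrace",
    "tonguecaps_spec",
    "trace_shapes",
    "count_parameters",
    "estimate_flops",
    "TongueCaps",
    "SGD",
    "Adam",
]

LAYER_KINDS = (
    "conv_bn_relu",
    "maxpool",
    "residual_a",
    "residual_b",
    "primary_caps",
    "class_caps",
    "length_head",
)


@dataclass(frozen=True)
class LayerSpec:
    """One architecture row: kind, kernel count k, kernel size m, stride s."""

    kind: str
    kernels: int = 0
    kernel_size: int = 3
    stride: int = 1
    units: int = 8  # primary caps only: number of capsule groups

    def __post_init__(self):
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind not in ("class_caps", "length_head"):
            if self.kernel_size not in (1, 3, 7):
                raise ValueError("kernel size must be 1, 3 or 7")
            if self.stride not in (1, 2):
                raise ValueError("stride must be 1 or 2")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Full network declaration: layer rows plus global settings."""

    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int] = (128, 128, 3)
    num_classes: int = 5
    class_capsule_dim: int = 16
    routing_iterations: int = 3
    use_shortcuts: bool = True

    def ablated(self) -> "ArchitectureSpec":
        """The shortcut-free twin (plain stacked-CNN feature extractor)."""
        return replace(self, use_shortcuts=False)


@dataclass
class ShapeTrace:
    """Propagated per-layer output shapes: (H, W, C) or (capsules, dim)."""

    input_shape: tuple[int, int, int]
    shapes: list[tuple[int, ...]] = field(default_factory=list)
    names: list[str] = field(default_factory=list)


def tonguecaps_spec(
    input_size: int = 128,
    width: float = 1.0,
    num_classes: int = 5,
    class_capsule_dim: int = 16,
    routing_iterations: int = 3,
    use_shortcuts: bool = True,
) -> ArchitectureSpec:
    """The default TongueCaps architecture.

    ``width`` scales every residual/primary channel count (1.0 is the
    published table; 0.5 is the reduced profile used for CPU-scale runs).
    The published table labels the 128->256-channel block as variant *a*,
    but an identity shortcut cannot change the channel count, so that row
    is realised as a stride-1 variant-*b* (projection-shortcut) block; its
    printed output shape is preserved.
    """

    def w(c: int) -> int:
        return max(1, int(round(c * width)))

    layers = (
        LayerSpec("conv_bn_relu", kernels=3, kernel_size=7, stride=1),
        LayerSpec("maxpool", kernels=3, kernel_size=3, stride=2),
        LayerSpec("residual_b", kernels=w(64), kernel_size=3, stride=2),
        LayerSpec("residual_a", kernels=w(64), kernel_size=3, stride=1),
        LayerSpec("residual_b", kernels=w(128), kernel_size=3, stride=2),
        LayerSpec("residual_a", kernels=w(128), kernel_size=3, stride=1),
        LayerSpec("residual_b", kernels=w(256), kernel_size=3, stride=1),
        LayerSpec("residual_a", kernels=w(256), kernel_size=3, stride=1),
        LayerSpec("primary_caps", kernels=w(32), kernel_size=3, stride=1, units=8),
        LayerSpec("class_caps"),
        LayerSpec("length_head"),
    )
    return ArchitectureSpec(
        layers=layers,
        input_shape=(input_size, input_size, 3),
        num_classes=num_classes,
        class_capsule_dim=class_capsule_dim,
        routing_iterations=routing_iterations,
        use_shortcuts=use_shortcuts,
    )


def _ceil_div(n: int, s: int) -> int:
    return -(-n // s)


def trace_shapes(spec: ArchitectureSpec) -> ShapeTrace:
    """Symbolically propagate output shapes through the spec (no weights)."""
    trace = ShapeTrace(input_shape=spec.input_shape)
    shape: tuple[int, ...] = spec.input_shape
    for layer in spec.layers:
        if layer.kind in ("conv_bn_relu", "maxpool", "residual_a", "residual_b"):
            h, w, c = shape
            if layer.kind == "residual_a" and (layer.kernels != c or layer.stride != 1):
                raise ValueError(
                    "identity-shortcut residual block requires unchanged "
                    f"channels and stride 1; got {c}->{layer.kernels} stride {layer.stride}"
                )
            cout = c if layer.kind == "maxpool" else layer.kernels
            shape = (_ceil_div(h, layer.stride), _ceil_div(w, layer.stride), cout)
        elif layer.kind == "primary_caps":
            h, w, c = shape
            m = layer.kernel_size
            if h < m or w < m:
                raise ValueError("primary caps input smaller than its kernel")
            oh, ow = h - m + 1, w - m + 1  # 'valid' padding, stride 1
            shape = (layer.units, oh * ow * layer.kernels)
        elif layer.kind == "class_caps":
            if len(shape) != 2:
                raise ValueError("class caps must follow primary caps")
            shape = (spec.num_classes, spec.class_capsule_dim)
        elif layer.kind == "length_head":
            shape = (shape[0],)
        trace.shapes.append(shape)
        trace.names.append(layer.kind)
    return trace


def count_parameters(spec: ArchitectureSpec) -> int:
    """Analytic trainable-parameter count.

    Conventions: conv under BN has no bias (k·m²·C_in weights + 2·C_out for
    the BN scale/shift); the primary-caps convolution (no BN) keeps its
    bias; class caps hold one D_in×D_out matrix per (input, output) capsule
    pair and no bias; shortcut projections are 1×1 conv + BN.
    """
    total = 0
    shape: tuple[int, ...] = spec.input_shape
    for layer, out_shape in zip(spec.layers, trace_shapes(spec).shapes):
        if layer.kind == "conv_bn_relu":
            cin, cout = shape[2], out_shape[2]
            total += layer.kernels * layer.kernel_size**2 * cin + 2 * cout
        elif layer.kind in ("residual_a", "residual_b"):
            cin, cout = shape[2], out_shape[2]
            m2 = layer.kernel_size**2
            total += cout * m2 * cin + 2 * cout  # first conv+BN (stride s)
            total += cout * m2 * cout + 2 * cout  # second conv+BN (stride 1)
            if layer.kind == "residual_b" and spec.use_shortcuts:
                total += cout * 1 * cin + 2 * cout  # 1×1 projection + BN
        elif layer.kind == "primary_caps":
            cin = shape[2]
            k = layer.units * layer.kernels
            total += k * layer.kernel_size**2 * cin + k  # conv with bias
        elif layer.kind == "class_caps":
            n_in, d_in = shape
            total += n_in * spec.num_classes * d_in * spec.class_capsule_dim
        shape = out_shape
    return total


def estimate_flops(spec: ArchitectureSpec, convention: str = "mac") -> int:
    """Analytic cost estimate for one forward pass.

    ``convention="mac"`` counts one multiply-accumulate per weight
    application (conv: OH·OW·k·m²·C_in; capsule transform:
    N_in·N_out·D_in·D_out; routing: r·2·N_in·N_out·D_out agreement and
    weighted-sum MACs); ``"flop"`` doubles that.  BN, ReLU, pooling and
    squash are linear in activation size and counted once per element.
    """
    if convention not in ("mac", "flop"):
        raise ValueError("convention must be 'mac' or 'flop'")
    total = 0
    shape: tuple[int, ...] = spec.input_shape
    for layer, out_shape in zip(spec.layers, trace_shapes(spec).shapes):
        if layer.kind == "conv_bn_relu":
            oh, ow, cout = out_shape
            total += oh * ow * cout * layer.kernel_size**2 * shape[2]
            total += 2 * oh * ow * cout  # BN + ReLU
        elif layer.kind == "maxpool":
            oh, ow, c = out_shape
            total += oh * ow * c * layer.kernel_size**2
        elif layer.kind in ("residual_a", "residual_b"):
            oh, ow, cout = out_shape
            m2 = layer.kernel_size**2
            total += oh * ow * cout * m2 * shape[2]
            total += oh * ow * cout * m2 * cout
            total += 5 * oh * ow * cout  # 2×BN, 2×ReLU, residual add
            if layer.kind == "residual_b" and spec.use_shortcuts:
                total += oh * ow * cout * shape[2] + 2 * oh * ow * cout
        elif layer.kind == "primary_caps":
            n, d = out_shape
            ohw = d // layer.kernels
            total += ohw * layer.units * layer.kernels * layer.kernel_size**2 * shape[2]
            total += 2 * n * d  # squash
        elif layer.kind == "class_caps":
            n_in, d_in = shape
            j, d_out = out_shape
            total += n_in * j * d_in * d_out
            total += spec.routing_iterations * 2 * n_in * j * d_out
        elif layer.kind == "length_head":
            total += spec.num_classes * spec.class_capsule_dim
        shape = out_shape
    return total * (2 if convention == "flop" else 1)


# ---------------------------------------------------------------------
# trainable layers
# ---------------------------------------------------------------------

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


class _Conv:
    def __init__(self, rng, m, cin, cout, stride, padding, bias=False):
        std = np.sqrt(2.0 / (m * m * cin))
        self.w = Tensor(rng.normal(0.0, std, (m, m, cin, cout)).astype(np.float32),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def __call__(self, x):
        return ag.conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)

    def params(self):
        return [self.w] if self.b is None else [self.w, self.b]


class _BatchNorm:
    def __init__(self, c):
        self.gamma = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)

    def __call__(self, x, training):
        if training:
            mu = ag.mean(x, axis=(0, 1, 2), keepdims=True)
            diff = ag.add(x, ag.mul(mu, -1.0))
            var = ag.mean(ag.mul(diff, diff), axis=(0, 1, 2), keepdims=True)
            m = _BN_MOMENTUM
            self.running_mean = m * self.running_mean + (1 - m) * ag.asarray(mu).ravel()
            self.running_var = m * self.running_var + (1 - m) * ag.asarray(var).ravel()
        else:
            diff = ag.add(x, -self.running_mean)
            var = self.running_var
        inv = ag.power(ag.add(var, _BN_EPS), -0.5)
        return ag.add(ag.mul(ag.mul(diff, inv), self.gamma), self.beta)

    def params(self):
        return [self.gamma, self.beta]


class _ConvBNReLU:
    """Conv ('same') -> batch norm -> ReLU; the basic feature block."""

    def __init__(self, rng, m, cin, cout, stride):
        self.conv = _Conv(rng, m, cin, cout, stride, "same")
        self.bn = _BatchNorm(cout)

    def __call__(self, x, training):
        return ag.relu(self.bn(self.conv(x), training))

    def params(self):
        return self.conv.params() + self.bn.params()


class _ResidualBlock:
    """out = ReLU(F(x) + shortcut(x)); F = ConvBNReLU -> Conv-BN.

    Variant *a*: identity shortcut (channels and stride preserved).
    Variant *b*: 1×1 Conv-BN projection shortcut.
    With shortcuts disabled: out = ReLU(F(x)).
    """

    def __init__(self, rng, variant, m, cin, cout, stride, use_shortcut):
        if variant == "a" and (cin != cout or stride != 1):
            raise ValueError("variant-a residual block requires cin == cout, stride 1")
        self.block1 = _ConvBNReLU(rng, m, cin, cout, stride)
        self.conv2 = _Conv(rng, m, cout, cout, 1, "same")
        self.bn2 = _BatchNorm(cout)
        self.variant = variant
        self.use_shortcut = use_shortcut
        self.proj = None
        if variant == "b" and use_shortcut:
            self.proj = _Conv(rng, 1, cin, cout, stride, "same")
            self.proj_bn = _BatchNorm(cout)

    def __call__(self, x, training):
        f = self.bn2(self.conv2(self.block1(x, training)), training)
        if not self.use_shortcut:
            return ag.relu(f)
        if self.variant == "a":
            shortcut = x
        else:
            shortcut = self.proj_bn(self.proj(x), training)
        return ag.relu(ag.add(f, shortcut))

    def params(self):
        p = self.block1.params() + self.conv2.params() + self.bn2.params()
        if self.proj is not None:
            p += self.proj.params() + self.proj_bn.params()
        return p


class _PrimaryCaps:
    """units × kernels 'valid' 3×3 convolutions -> per-unit flatten -> squash.

    The ``units`` groups are realised as one convolution with
    units·kernels output channels, reshaped so each group's
    (H−2)×(W−2)×kernels map becomes one capsule vector.
    """

    def __init__(self, rng, m, cin, kernels, units):
        self.conv = _Conv(rng, m, cin, units * kernels, 1, "valid", bias=True)
        self.units, self.kernels = units, kernels

    def __call__(self, x, training):
        y = self.conv(x)  # [B, OH, OW, units*kernels]
        b, oh, ow, _ = ag.asarray(y).shape
        y = ag.reshape(y, (b, oh, ow, self.units, self.kernels))
        y = ag.transpose(y, (0, 3, 1, 2, 4))  # [B, units, OH, OW, kernels]
        y = ag.reshape(y, (b, self.units, oh * ow * self.kernels))
        return capsule.squash(y)

    def params(self):
        return self.conv.params()


class _ClassCaps:
    """Affine capsule transform + dynamic routing to num_classes capsules."""

    def __init__(self, rng, n_in, d_in, n_out, d_out, iterations):
        std = np.sqrt(1.0 / d_in)
        self.W = Tensor(
            rng.normal(0.0, std, (n_in, n_out, d_in, d_out)).astype(np.float32),
            requires_grad=True,
        )
        self.iterations = iterations

    def __call__(self, u):
        u_hat = capsule.predict_vectors(u, self.W)
        v, state = capsule.dynamic_routing(u_hat, self.iterations)
        return v, state

    def params(self):
        return [self.W]


class TongueCaps:
    """The assembled network.  ``forward`` maps a [B, H, W, 3] batch of
    unit-interval HSV images to [B, num_classes] capsule lengths."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        trace = trace_shapes(spec)  # validates the spec
        rng = np.random.default_rng(seed)
        self._modules: list = []
        self.last_state: capsule.RoutingState | None = None
        shape: tuple[int, ...] = spec.input_shape
        for layer, out_shape in zip(spec.layers, trace.shapes):
            if layer.kind == "conv_bn_relu":
                mod = _ConvBNReLU(rng, layer.kernel_size, shape[2], layer.kernels, layer.stride)
            elif layer.kind == "maxpool":
                mod = ("maxpool", layer.kernel_size, layer.stride)
            elif layer.kind in ("residual_a", "residual_b"):
                mod = _ResidualBlock(
                    rng, layer.kind[-1], layer.kernel_size, shape[2],
                    layer.kernels, layer.stride, spec.use_shortcuts,
                )
            elif layer.kind == "primary_caps":
                mod = _PrimaryCaps(rng, layer.kernel_size, shape[2], layer.kernels, layer.units)
            elif layer.kind == "class_caps":
                mod = _ClassCaps(
                    rng, shape[0], shape[1], spec.num_classes,
                    spec.class_capsule_dim, spec.routing_iterations,
                )
            else:  # length_head: no weights
                mod = ("length_head",)
            self._modules.append(mod)
            shape = out_shape

    def forward(self, x, training: bool = False):
        """Returns capsule lengths [B, num_classes] (Tensor when training)."""
        h = x if isinstance(x, Tensor) else Tensor(np.asarray(x, np.float32))
        for mod in self._modules:
            if isinstance(mod, tuple) and mod[0] == "maxpool":
                h = ag.maxpool2d(h, size=mod[1], stride=mod[2], padding="same")
            elif isinstance(mod, tuple) and mod[0] == "length_head":
                h = capsule.capsule_lengths(h)
            elif isinstance(mod, _ClassCaps):
                h, self.last_state = mod(h)
            elif isinstance(mod, _PrimaryCaps) or isinstance(mod, (_ConvBNReLU, _ResidualBlock)):
                h = mod(h, training)
            else:
                h = mod(h)
        return h

    __call__ = forward

    def predict(self, x, batch_size: int = 64) -> np.ndarray:
        """Class indices for a [N, H, W, 3] array (evaluation mode)."""
        x = np.asarray(x, np.float32)
        out = []
        for i in range(0, len(x), batch_size):
            lengths = ag.asarray(self.forward(x[i : i + batch_size], training=False))
            out.append(np.argmax(lengths, axis=-1))
        return np.concatenate(out) if out else np.empty(0, int)

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for mod in self._modules:
            if not isinstance(mod, tuple):
                params += mod.params()
        return params

    def num_parameters(self) -> int:
        return int(np.sum([p.data.size for p in self.parameters()]))

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat checkpoint dict (trainable weights + BN running stats)."""
        state: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            state[f"param_{i}"] = p.data
        for i, bn in enumerate(self._batchnorms()):
            state[f"bn_{i}_mean"] = bn.running_mean
            state[f"bn_{i}_var"] = bn.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(state[f"param_{i}"], p.data.dtype).reshape(p.data.shape)
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean = np.asarray(state[f"bn_{i}_mean"], np.float32)
            bn.running_var = np.asarray(state[f"bn_{i}_var"], np.float32)

    def _batchnorms(self):
        bns = []
        for mod in self._modules:
            if isinstance(mod, _ConvBNReLU):
                bns.append(mod.bn)
            elif isinstance(mod, _ResidualBlock):
                bns += [mod.block1.bn, mod.bn2]
                if mod.proj is not None:
                    bns.append(mod.proj_bn)
        return bns

    def save(self, path) -> None:
        np.savez(path, **self.state_arrays())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_arrays(dict(data))


# ---------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------


class SGD:
    """Plain stochastic gradient descent (optional classical momentum)."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.0):
        self.params, self.lr, self.momentum = params, lr, momentum
        self._vel = [np.zeros_like(p.data) for p in params]

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data = p.data + v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: list[Tensor], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.lr = params, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]
        self._t = 0

    def step(self):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
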