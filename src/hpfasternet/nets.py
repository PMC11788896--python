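"""Executable network definitions with NumPy forward and backward passes.

Building blocks: partial convolution (PConv), grouped 3x3 convolution,
Ghost modules and the stride-1 Ghost bottleneck, the FasterNet block and the
HPFasterNet double-residual block, assembled into the four variants described
in :mod:`hpfasternet.config`.

The engine is deliberately small: layers are plain classes holding float32
arrays, gradients are hand-written, and convolutions are expressed as one
grouped correlation primitive (im2col windows + einsum) reused by the
forward pass, the weight gradient and the transposed-convolution input
gradient.  Everything is deterministic given the integer seed passed to
:func:`build_network`.
"""

from __future__ import annotations

import math

import numpy as np

from .config import GhostSpec, NetworkConfig, make_config

# ---------------------------------------------------------------------------
# activations


SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)
GELU_CUBIC = 0.044715


def relu(x):
    """max(x, 0) elementwise."""
    return np.maximum(x, 0.0)


def gelu(x):
    """tanh-approximated Gaussian error linear unit,
    0.5 x (1 + tanh(sqrt(2/pi) (x + 0.044715 x^3)))."""
    x = np.asarray(x)
    return 0.5 * x * (1.0 + np.tanh(SQRT_2_OVER_PI * (x + GELU_CUBIC * x ** 3)))


def gelu_exact(x):
    """Reference GeLU x * Phi(x) via the error function (oracle form)."""
    from scipy.special import erf

    x = np.asarray(x)
    return 0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))


def activation(x, fn: str):
    """Elementwise activation by name ('relu' or 'gelu')."""
    if fn == "relu":
        return relu(x)
    if fn == "gelu":
        return gelu(x)
    raise ValueError(f"unknown activation {fn!r}")


# ---------------------------------------------------------------------------
# grouped correlation primitive


def _windows(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Strided sliding windows of a padded NCHW tensor: (N, C, Ho, Wo, k, k)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def _corr(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """Grouped cross-correlation.  x: (N, C_in, H, W); w: (g, Co, Ci, k, k)
    with C_in = g * Ci; returns (N, g * Co, Ho, Wo)."""
    g, co, ci, k, _ = w.shape
    n = x.shape[0]
    win = _windows(x, k, stride, pad)
    ho, wo = win.shape[2], win.shape[3]
    win = win.reshape(n, g, ci, ho, wo, k, k)
    out = np.einsum("ngchwij,gocij->ngohw", win, w, optimize=True)
    return np.ascontiguousarray(out.reshape(n, g * co, ho, wo))


class Module:
    """Minimal layer protocol: forward caches, backward returns grad wrt input."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, value, grad) triples; values are mutated in place by SGD."""
        return []

    def __call__(self, x, train=False):
        return self.forward(x, train)


class Conv2d(Module):
    """Grouped 2-D convolution, no bias (normalization supplies the shift)."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 pad: int | None = None, groups: int = 1, *, rng=None):
        if c_in % groups or c_out % groups:
            raise ValueError(
                f"groups={groups} must divide C_in={c_in} and C_out={c_out}")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.stride = stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self.groups = groups
        shape = (groups, c_out // groups, c_in // groups, k, k)
        self.w = _trunc_normal(rng, shape)
        self.gw = np.zeros_like(self.w)
        self._x = None

    def forward(self, x, train=False):
        if train:
            self._x = x
        return _corr(x, self.w, self.stride, self.pad)

    def backward(self, grad):
        x, k, s, p = self._x, self.k, self.stride, self.pad
        n, _, h, wd = x.shape
        g, co, ci = self.w.shape[:3]
        ho, wo = grad.shape[2], grad.shape[3]
        # weight gradient from the same windows as the forward pass
        win = _windows(x, k, s, p).reshape(n, g, ci, ho, wo, k, k)
        gr = grad.reshape(n, g, co, ho, wo)
        self.gw += np.einsum("ngchwij,ngohw->gocij", win, gr, optimize=True)
        # input gradient = correlation of the zero-stuffed output gradient
        # with the spatially flipped, in/out-transposed kernel
        if s > 1:
            dil = np.zeros((n, g * co, (ho - 1) * s + 1, (wo - 1) * s + 1),
                           dtype=grad.dtype)
            dil[:, :, ::s, ::s] = grad
        else:
            dil = grad
        # pad so that the stride-1 correlation returns the padded input extent
        extra_h = (h + 2 * p) - (dil.shape[2] + k - 1)
        extra_w = (wd + 2 * p) - (dil.shape[3] + k - 1)
        dil = np.pad(dil, ((0, 0), (0, 0),
                           (k - 1, k - 1 + extra_h), (k - 1, k - 1 + extra_w)))
        w_flip = self.w[:, :, :, ::-1, ::-1].transpose(0, 2, 1, 3, 4)
        gx_pad = _corr(dil, np.ascontiguousarray(w_flip), 1, 0)
        return gx_pad[:, :, p:p + h, p:p + wd]

    def parameters(self):
        return [("w", self.w, self.gw)]


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.ggamma = np.zeros(c, dtype=np.float32)
        self.gbeta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma[None, :, None, None] * xhat + \
            self.beta[None, :, None, None]

    def backward(self, grad):
        xhat, inv = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.ggamma += (grad * xhat).sum(axis=(0, 2, 3))
        self.gbeta += grad.sum(axis=(0, 2, 3))
        gxhat = grad * self.gamma[None, :, None, None]
        gx = (gxhat - gxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return gx * inv[None, :, None, None]

    def parameters(self):
        return [("gamma", self.gamma, self.ggamma),
                ("beta", self.beta, self.gbeta)]


class Activation(Module):
    def __init__(self, fn: str):
        if fn not in ("relu", "gelu"):
            raise ValueError(f"unknown activation {fn!r}")
        self.fn = fn
        self._x = None

    def forward(self, x, train=False):
        if train:
            self._x = x
        return activation(x, self.fn)

    def backward(self, grad):
        x = self._x
        if self.fn == "relu":
            return grad * (x > 0)
        u = SQRT_2_OVER_PI * (x + GELU_CUBIC * x ** 3)
        t = np.tanh(u)
        du = SQRT_2_OVER_PI * (1.0 + 3.0 * GELU_CUBIC * x ** 2)
        return grad * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * du)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x, train=False):
        for m in self.mods:
            x = m.forward(x, train)
        return x

    def backward(self, grad):
        for m in reversed(self.mods):
            grad = m.backward(grad)
        return grad

    def parameters(self):
        out = []
        for i, m in enumerate(self.mods):
            out += [(f"{i}.{n}", v, g) for n, v, g in m.parameters()]
        return out


class PartialConv(Module):
    """Convolve the first Cp channels, pass the remaining C - Cp through."""

    def __init__(self, c: int, cp: int, k: int = 3, *, rng=None):
        if cp > c:
            raise ValueError(f"Cp={cp} exceeds channel count C={c}")
        self.c, self.cp = c, cp
        self.conv = Conv2d(cp, cp, k, rng=rng)

    def forward(self, x, train=False):
        if x.shape[1] != self.c:
            raise ValueError(f"expected {self.c} channels, got {x.shape[1]}")
        y = self.conv.forward(x[:, :self.cp], train)
        return np.concatenate([y, x[:, self.cp:]], axis=1)

    def backward(self, grad):
        gx1 = self.conv.backward(np.ascontiguousarray(grad[:, :self.cp]))
        return np.concatenate([gx1, grad[:, self.cp:]], axis=1)

    def parameters(self):
        return [(f"conv.{n}", v, g) for n, v, g in self.conv.parameters()]


class GhostModule(Module):
    """Primary convolution producing m intrinsic maps, cheap depthwise ops
    producing the remaining (s-1)m ghost maps; the intrinsic maps appear
    verbatim in the output (the identity branch of the cheap operations)."""

    def __init__(self, c_in: int, c_out: int, spec: GhostSpec,
                 act: bool = True, *, rng=None):
        spec.validate(c_out)
        self.m = c_out // spec.s
        self.ghosts = c_out - self.m
        self.primary = Sequential(
            Conv2d(c_in, self.m, spec.primary_kernel, rng=rng),
            BatchNorm2d(self.m),
            *( [Activation("relu")] if act else [] ),
        )
        self.cheap = None
        if self.ghosts:
            self.cheap = Sequential(
                Conv2d(self.m, self.ghosts, spec.dw_kernel, groups=self.m,
                       rng=rng),
                BatchNorm2d(self.ghosts),
                *( [Activation("relu")] if act else [] ),
            )

    def forward(self, x, train=False):
        p = self.primary.forward(x, train)
        if self.cheap is None:
            return p
        c = self.cheap.forward(p, train)
        return np.concatenate([p, c], axis=1)

    def backward(self, grad):
        if self.cheap is None:
            return self.primary.backward(grad)
        gp = np.ascontiguousarray(grad[:, :self.m])
        gc = np.ascontiguousarray(grad[:, self.m:])
        gp = gp + self.cheap.backward(gc)
        return self.primary.backward(gp)

    def parameters(self):
        out = [(f"primary.{n}", v, g) for n, v, g in self.primary.parameters()]
        if self.cheap is not None:
            out += [(f"cheap.{n}", v, g) for n, v, g in self.cheap.parameters()]
        return out


class GhostBottleneck(Module):
    """Two stacked ghost modules with an identity shortcut (stride 1)."""

    def __init__(self, c: int, spec: GhostSpec, *, rng=None):
        self.g1 = GhostModule(c, c, spec, act=True, rng=rng)
        self.g2 = GhostModule(c, c, spec, act=False, rng=rng)

    def forward(self, x, train=False):
        return x + self.g2.forward(self.g1.forward(x, train), train)

    def backward(self, grad):
        return grad + self.g1.backward(self.g2.backward(grad))

    def parameters(self):
        return ([(f"ghost1.{n}", v, g) for n, v, g in self.g1.parameters()]
                + [(f"ghost2.{n}", v, g) for n, v, g in self.g2.parameters()])


class ResidualBlock(Module):
    """x + branch(x) with shape-preserving branch."""

    def __init__(self, branch: Sequential):
        self.branch = branch

    def forward(self, x, train=False):
        y = self.branch.forward(x, train)
        if y.shape != x.shape:
            raise ValueError(
                f"residual branch changed shape {x.shape} -> {y.shape}")
        return x + y

    def backward(self, grad):
        return grad + self.branch.backward(grad)

    def parameters(self):
        return [(f"branch.{n}", v, g) for n, v, g in self.branch.parameters()]


def fasternet_block(c: int, expansion: int = 2, cp_denom: int = 4,
                    act: str = "gelu", *, rng=None) -> ResidualBlock:
    """PConv -> 1x1 expand -> BN -> act -> 1x1 reduce, residual."""
    h = expansion * c
    return ResidualBlock(Sequential(
        PartialConv(c, c // cp_denom, rng=rng),
        Conv2d(c, h, 1, rng=rng),
        BatchNorm2d(h),
        Activation(act),
        Conv2d(h, c, 1, rng=rng),
    ))


def hp_block(c: int, ghost: GhostSpec | None, expansion: int = 2,
             cp_denom: int = 4, act: str = "gelu", use_gconv: bool = True,
             *, rng=None) -> ResidualBlock:
    """FasterNet block with 3x3 group convolutions (groups = C) for
    expand/reduce and an optional Ghost bottleneck on the expanded channels
    — the double-residual HPFasterNet block."""
    h = expansion * c
    mods: list[Module] = [PartialConv(c, c // cp_denom, rng=rng)]
    if use_gconv:
        mods.append(Conv2d(c, h, 3, groups=c, rng=rng))
    else:
        mods.append(Conv2d(c, h, 1, rng=rng))
    mods += [BatchNorm2d(h), Activation(act)]
    if ghost is not None:
        mods.append(GhostBottleneck(h, ghost, rng=rng))
    if use_gconv:
        mods.append(Conv2d(h, c, 3, groups=c, rng=rng))
    else:
        mods.append(Conv2d(h, c, 1, rng=rng))
    return ResidualBlock(Sequential(*mods))


class GlobalAvgPool(Module):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w),
                               self._shape).copy()


class Linear(Module):
    def __init__(self, c_in: int, c_out: int, bias: bool = True, *, rng=None):
        self.w = _trunc_normal(rng, (c_out, c_in))
        self.gw = np.zeros_like(self.w)
        self.b = np.zeros(c_out, dtype=np.float32) if bias else None
        self.gb = np.zeros(c_out, dtype=np.float32) if bias else None
        self._x = None

    def forward(self, x, train=False):
        if train:
            self._x = x
        y = x @ self.w.T
        return y + self.b if self.b is not None else y

    def backward(self, grad):
        self.gw += grad.T @ self._x
        if self.b is not None:
            self.gb += grad.sum(axis=0)
        return grad @ self.w

    def parameters(self):
        out = [("w", self.w, self.gw)]
        if self.b is not None:
            out.append(("b", self.b, self.gb))
        return out


class ActivationVec(Activation):
    """Activation on (N, C) feature vectors (same math, 2-D tensors)."""


class Network(Module):
    """Stem -> stages with merges -> pooled head -> logits."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.Generator(np.random.PCG64(seed))
        mods: list[Module] = [
            Conv2d(3, config.stage_channels[0], config.stem_kernel,
                   stride=config.stem_stride, pad=0, rng=rng),
            BatchNorm2d(config.stage_channels[0]),
        ]
        for stage, (depth, c) in enumerate(
                zip(config.stage_depths, config.stage_channels)):
            if stage > 0:
                mods += [
                    Conv2d(config.stage_channels[stage - 1], c,
                           config.merge_kernel, stride=config.merge_stride,
                           pad=0, rng=rng),
                    BatchNorm2d(c),
                ]
            spec = config.block_spec(stage)
            for _ in range(depth):
                if config.variant == "fasternet_t0":
                    mods.append(fasternet_block(
                        c, spec.expansion, spec.partial_ratio_denom, rng=rng))
                else:
                    mods.append(hp_block(
                        c, spec.ghost if spec.uses_ghost else None,
                        spec.expansion, spec.partial_ratio_denom,
                        use_gconv=spec.uses_gconv, rng=rng))
        self.body = Sequential(*mods)
        self.pool = GlobalAvgPool()
        self.head = Sequential()  # placeholder for parameters() naming
        self.pre_head = Linear(config.stage_channels[-1], config.head_width,
                               bias=False, rng=rng)
        self.head_act = ActivationVec("gelu")
        self.classifier = Linear(config.head_width, config.num_classes,
                                 bias=True, rng=rng)

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        y = self.body.forward(x, train)
        y = self.pool.forward(y, train)
        y = self.pre_head.forward(y, train)
        y = self.head_act.forward(y, train)
        return self.classifier.forward(y, train)

    def backward(self, grad):
        g = self.classifier.backward(grad)
        g = self.head_act.backward(g)
        g = self.pre_head.backward(g)
        g = self.pool.backward(g)
        return self.body.backward(g)

    def parameters(self):
        out = [(f"body.{n}", v, g) for n, v, g in self.body.parameters()]
        out += [(f"pre_head.{n}", v, g) for n, v, g in self.pre_head.parameters()]
        out += [(f"classifier.{n}", v, g)
                for n, v, g in self.classifier.parameters()]
        return out

    def parameter_count(self) -> int:
        """Exhaustive per-tensor weight count of the instantiated network."""
        return sum(v.size for _, v, _ in self.parameters())

    def zero_grad(self):
        for _, _, g in self.parameters():
            g[...] = 0.0

    def state(self) -> dict[str, np.ndarray]:
        st = {n: v.copy() for n, v, _ in self.parameters()}
        for i, m in enumerate(self._bn_modules()):
            st[f"__bn{i}.mean"] = m.running_mean.copy()
            st[f"__bn{i}.var"] = m.running_var.copy()
        return st

    def load_state(self, st: dict[str, np.ndarray]) -> None:
        for n, v, _ in self.parameters():
            v[...] = st[n]
        for i, m in enumerate(self._bn_modules()):
            m.running_mean[...] = st[f"__bn{i}.mean"]
            m.running_var[...] = st[f"__bn{i}.var"]

    def _bn_modules(self):
        found = []

        def walk(m):
            if isinstance(m, BatchNorm2d):
                found.append(m)
            for attr in ("mods", "branch", "conv", "primary", "cheap",
                         "g1", "g2"):
                sub = getattr(m, attr, None)
                if isinstance(sub, Module):
                    walk(sub)
                elif isinstance(sub, list):
                    for s in sub:
                        walk(s)
        walk(self.body)
        return found


def _trunc_normal(rng, shape, std: float = 0.02) -> np.ndarray:
    """Truncated normal init at +-2 std (resampled), zeros without an rng."""
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(0))
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x.astype(np.float32)


def partial_conv(x: np.ndarray, cp: int, k: int = 3, *,
                 weights: np.ndarray | None = None) -> np.ndarray:
    """Functional partial convolution: K x K convolution of the first ``cp``
    channels, remaining channels passed through unchanged."""
    x = np.asarray(x, dtype=np.float32)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    layer = PartialConv(x.shape[1], cp, k)
    if weights is not None:
        layer.conv.w[...] = weights.reshape(layer.conv.w.shape)
    y = layer.forward(x)
    return y[0] if squeeze else y


def build_network(config: NetworkConfig | str, num_classes: int = 19,
                  input_size: int = 224, seed: int = 0) -> Network:
    """Instantiate an executable network for a config or a variant name."""
    if isinstance(config, str):
        config = make_config(config, num_classes=num_classes,
                             input_size=input_size)
    return Network(config, seed=seed)
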