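"""Neural-network building blocks on top of the autodiff engine.

Layers follow the familiar module convention: a ``Module`` owns parameter
tensors and submodules, ``parameters()`` walks the tree, ``train()`` /
``eval()`` toggle the stochastic layers (dropout, batch-norm statistics).
Weight initialisation is a uniform fan-in scheme, U(-1/sqrt(fan_in),
+1/sqrt(fan_in)), driven by an explicit numpy Generator so runs are fully
reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module",
    "Sequential",
    "Linear",
    "TimeLinear",
    "LayerNorm",
    "PointwiseConv1d",
    "DepthwiseConv1d",
    "Conv1d",
    "BatchNorm1d",
    "GLU",
    "Swish",
    "Dropout",
    "Flatten",
    "Adam",
    "glu",
    "softmax",
    "cross_entropy",
]


def _uniform_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Module:
    """Base class: parameter/submodule discovery plus a training flag."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, *args, **kwargs) -> Tensor:
        return self.forward(*args, **kwargs)

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, p in enumerate(self.parameters()):
            out[f"param_{i}"] = p.data.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = state[f"param_{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for param_{i}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype, copy=True)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Linear(Module):
    """Affine map applied to the last axis: ``y = x @ W + b``."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Tensor(_uniform_init(rng, (in_features, out_features), in_features, dtype),
                             requires_grad=True)
        self.bias = Tensor(_uniform_init(rng, (out_features,), in_features, dtype),
                           requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


# the time-axis reduction layer is an ordinary last-axis affine map
TimeLinear = Linear


def _norm_node(x: Tensor, weight: Tensor, bias: Tensor, axes: tuple[int, ...],
               param_axis: int, eps: float) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Shared fused normalisation node (layer / batch norm differ by axes).

    ``axes`` are the reduction axes of the statistics; ``param_axis`` is the
    axis the affine weight/bias broadcast along.  Returns the output node
    plus the batch mean/variance used (for running statistics).  The
    closed-form backward avoids the long elementwise chains the composed-op
    formulation would create.
    """
    xd = x.data
    mu = xd.mean(axis=axes, keepdims=True)
    xc = xd - mu
    var = np.mean(xc * xc, axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    shape = [1] * xd.ndim
    shape[param_axis] = xd.shape[param_axis]
    w = weight.data.reshape(shape)
    out = xhat * w + bias.data.reshape(shape)
    sum_axes = tuple(ax for ax in range(xd.ndim) if ax != param_axis)

    def backward(g):
        gxhat = g * w
        m1 = gxhat.mean(axis=axes, keepdims=True)
        m2 = (gxhat * xhat).mean(axis=axes, keepdims=True)
        gx = inv * (gxhat - m1 - xhat * m2)
        gw = (g * xhat).sum(axis=sum_axes)
        gb = g.sum(axis=sum_axes)
        return gx, gw, gb

    return Tensor._node(out, (x, weight, bias), backward), mu, var


class LayerNorm(Module):
    """Normalise the last axis to zero mean / unit variance, then scale+shift."""

    def __init__(self, normalized_shape: int, dtype=np.float32, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Tensor(np.ones(normalized_shape, dtype=dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(normalized_shape, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        out, _, _ = _norm_node(x, self.weight, self.bias, (x.ndim - 1,),
                               x.ndim - 1, self.eps)
        return out


class PointwiseConv1d(Module):
    """1x1 convolution over channels of a (batch, channels, length) tensor."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Tensor(_uniform_init(rng, (in_channels, out_channels), in_channels, dtype),
                             requires_grad=True)
        self.bias = Tensor(_uniform_init(rng, (out_channels,), in_channels, dtype),
                           requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        # fused node: out[b,o,l] = sum_c W[c,o] x[b,c,l] + bias[o], one
        # broadcast GEMM per direction, no transpose copies
        w, b = self.weight, self.bias
        out = np.matmul(w.data.T, x.data) + b.data[None, :, None]

        def backward(g):
            gx = np.matmul(w.data, g)
            gw = np.einsum("bcl,bol->co", x.data, g, optimize=True)
            return gx, gw, g.sum(axis=(0, 2))

        return Tensor._node(out, (x, w, b), backward)


def depthwise_conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Valid per-channel 1-D convolution as a single autodiff node.

    Forward (a per-channel correlation) and both backward contractions are
    evaluated as circular correlations through real FFTs of length equal to
    the input, which is exact for the valid part and far cheaper than
    materialising the (batch, channels, L_out, k) window tensor the generic
    autodiff path would build and scatter back through.
    """
    from scipy import fft as sfft

    channels, k = weight.shape
    length = x.shape[-1]
    l_out = length - k + 1
    if l_out < 1:
        raise ValueError(f"input length {length} shorter than kernel {k}")
    xd, wd = x.data, weight.data
    xf = sfft.rfft(xd, n=length, axis=-1)
    wf = sfft.rfft(wd, n=length, axis=-1)
    out = sfft.irfft(xf * wf.conj(), n=length, axis=-1)[..., :l_out]
    out = out.astype(xd.dtype, copy=False) + bias.data[None, :, None]

    def backward(g):
        gf = sfft.rfft(g, n=length, axis=-1)
        gx = sfft.irfft(gf * wf, n=length, axis=-1).astype(xd.dtype, copy=False)
        gw = sfft.irfft((xf * gf.conj()).sum(axis=0), n=length, axis=-1)[:, :k]
        return gx, gw.astype(wd.dtype, copy=False), g.sum(axis=(0, 2))

    return Tensor._node(out, (x, weight, bias), backward)


def full_conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Valid all-channel 1-D convolution (weight: (C_out, C_in, k))."""
    c_out, c_in, k = weight.shape
    length = x.shape[-1]
    l_out = length - k + 1
    if l_out < 1:
        raise ValueError(f"input length {length} shorter than kernel {k}")
    xd, wd = x.data, weight.data
    out = np.zeros((xd.shape[0], c_out, l_out), dtype=xd.dtype)
    for j in range(k):
        out += np.einsum("oi,bil->bol", wd[:, :, j], xd[:, :, j:j + l_out])
    out += bias.data[None, :, None]

    def backward(g):
        gw = np.empty_like(wd)
        gx = np.zeros_like(xd)
        for j in range(k):
            gw[:, :, j] = np.einsum("bol,bil->oi", g, xd[:, :, j:j + l_out])
            gx[:, :, j:j + l_out] += np.einsum("oi,bol->bil", wd[:, :, j], g)
        return gx, gw, g.sum(axis=(0, 2))

    return Tensor._node(out, (x, weight, bias), backward)


class DepthwiseConv1d(Module):
    """Per-channel (grouped) 1-D convolution with valid padding."""

    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.channels = channels
        self.kernel_size = kernel_size
        self.weight = Tensor(_uniform_init(rng, (channels, kernel_size), kernel_size, dtype),
                             requires_grad=True)
        self.bias = Tensor(_uniform_init(rng, (channels,), kernel_size, dtype),
                           requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return depthwise_conv1d(x, self.weight, self.bias)


class Conv1d(Module):
    """Full (all-channel) valid 1-D convolution."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size
        self.weight = Tensor(
            _uniform_init(rng, (out_channels, in_channels, kernel_size), fan_in, dtype),
            requires_grad=True)
        self.bias = Tensor(_uniform_init(rng, (out_channels,), fan_in, dtype),
                           requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return full_conv1d(x, self.weight, self.bias)


class BatchNorm1d(Module):
    """Batch normalisation over (batch, length) per channel with running stats."""

    def __init__(self, channels: int, dtype=np.float32, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = _norm_node(x, self.weight, self.bias, (0, 2), 1, self.eps)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.reshape(-1)
            return out
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = (self.weight.data * inv).reshape(1, -1, 1)
        shift = (self.bias.data - self.weight.data * self.running_mean * inv)
        centred = x * Tensor(scale)
        return centred + Tensor(shift.reshape(1, -1, 1))


def glu(x: Tensor, axis: int = 1) -> Tensor:
    """Gated linear unit: split channels in half, ``a * sigmoid(b)``.

    Fused into one node: the backward writes both gradient halves straight
    into a single buffer instead of scattering through two slice nodes.
    """
    from scipy.special import expit

    n = x.shape[axis]
    if n % 2 != 0:
        raise ValueError(f"GLU needs an even channel count, got {n} on axis {axis}")
    half = n // 2
    sl_a = [slice(None)] * x.ndim
    sl_b = [slice(None)] * x.ndim
    sl_a[axis] = slice(0, half)
    sl_b[axis] = slice(half, n)
    sl_a, sl_b = tuple(sl_a), tuple(sl_b)
    a = x.data[sl_a]
    sig = expit(x.data[sl_b])
    out = a * sig

    def backward(g):
        gx = np.empty_like(x.data)
        np.multiply(g, sig, out=gx[sl_a])
        np.multiply(g * a, sig * (1.0 - sig), out=gx[sl_b])
        return (gx,)

    return Tensor._node(out, (x,), backward)


class GLU(Module):
    def __init__(self, axis: int = 1):
        super().__init__()
        self.axis = axis

    def forward(self, x: Tensor) -> Tensor:
        return glu(x, self.axis)


class Swish(Module):
    """x * sigmoid(x), no learnable slope (fused single node)."""

    def forward(self, x: Tensor) -> Tensor:
        from scipy.special import expit

        sig = expit(x.data)
        out = x.data * sig
        # d/dx [x*s(x)] = s(x) * (1 + x * (1 - s(x)))
        return Tensor._node(out, (x,), lambda g: (g * (sig * (1.0 + x.data - out)),))


class Dropout(Module):
    """Inverted dropout driven by an injected Generator (reproducible)."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * Tensor(mask)


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


def softmax(logits: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (shift by the detached row max)."""
    shift = Tensor(logits.data.max(axis=axis, keepdims=True))
    z = (logits - shift).exp()
    return z / z.sum(axis=axis, keepdims=True)


def log_softmax(logits: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(logits.data.max(axis=axis, keepdims=True))
    z = (logits - shift).exp()
    return (logits - shift) - z.sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under the softmax."""
    labels = np.asarray(labels)
    n_classes = logits.shape[-1]
    if labels.ndim != 1 or labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"labels must be integers in [0, {n_classes}), got {labels!r}")
    logp = log_softmax(logits, axis=-1)
    picked = logp[np.arange(labels.shape[0]), labels]
    return -picked.mean()


class Adam:
    """Adam optimiser (Kingma & Ba) over a flat parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / bias1
            v_hat = self.v[i] / bias2
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
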