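"""Minimal numpy neural-network engine: layers, explicit gradients, Adam.

Feature maps travel through a model as batched arrays. Planar stacks are
``(N, C, H, W)``; group stacks are kept *folded* as ``(N, C*|G|, H, W)`` with
the group axis fastest, so ReLU, spatial pooling and the convolution
primitive apply uniformly to both. :class:`GroupPool` unfolds the channel
axis to reduce over the group.

Each layer implements ``forward(x, *, train, rng)`` and ``backward(grad)``
and exposes its parameters/gradients by name; :class:`Sequential` chains
them and :class:`Adam` updates them. Everything is float64 and fully
deterministic given the seeds supplied by the caller.
"""

from __future__ import annotations

import numpy as np

from . import conv_engine as ce
from .groups import SymmetryGroup

__all__ = [
    "Layer",
    "Conv2d",
    "LiftingConv2d",
    "GroupConv2d",
    "ReLU",
    "MaxPool2d",
    "GroupPool",
    "Dropout",
    "Flatten",
    "Linear",
    "Sequential",
    "Adam",
    "softmax_cross_entropy",
    "he_normal",
]


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """He (Kaiming) normal initialization: N(0, sqrt(2/fan_in))."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Layer:
    """Base layer; stateless layers only override forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, *, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def describe(self) -> str:
        return type(self).__name__


class Conv2d(Layer):
    """Ordinary planar convolution (cross-correlation) with bias."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1, padding=0, *, rng):
        super().__init__()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding
        fan_in = in_channels * kernel_size**2
        self.params = {
            "weight": he_normal(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in),
            "bias": np.zeros(out_channels),
        }

    def forward(self, x, *, train=False, rng=None):
        out, self._cache = ce.conv2d_forward(
            x, self.params["weight"], self.params["bias"], self.stride, self.padding
        )
        return out

    def backward(self, grad):
        gx, gw, gb = ce.conv2d_backward(grad, self._cache)
        self.grads = {"weight": gw, "bias": gb}
        return gx

    def describe(self):
        return (
            f"Conv2d({self.in_channels}->{self.out_channels}, k={self.kernel_size}, "
            f"s={self.stride}, p={self.padding})"
        )


class LiftingConv2d(Layer):
    """Input-layer G-convolution: planar input -> folded group stack.

    Stores one planar kernel per (out, in) channel pair; at forward time all
    |G| transformed copies are expanded and dispatched to the planar
    primitive. Bias is shared over the group axis, preserving equivariance.
    """

    def __init__(self, in_channels, out_channels, kernel_size, group: SymmetryGroup,
                 stride=1, padding=0, *, rng):
        super().__init__()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding
        self.group = group
        fan_in = in_channels * kernel_size**2
        self.params = {
            "weight": he_normal(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in),
            "bias": np.zeros(out_channels),
        }

    def forward(self, x, *, train=False, rng=None):
        w_exp = ce.expand_lifting_kernel(self.params["weight"], self.group)
        b_exp = ce.expand_bias(self.params["bias"], self.group)
        out, self._cache = ce.conv2d_forward(x, w_exp, b_exp, self.stride, self.padding)
        return out

    def backward(self, grad):
        gx, gw_exp, gb_exp = ce.conv2d_backward(grad, self._cache)
        self.grads = {
            "weight": ce.collapse_lifting_grad(gw_exp, self.group),
            "bias": ce.collapse_bias_grad(gb_exp, self.group),
        }
        return gx

    def describe(self):
        return (
            f"LiftingConv2d({self.in_channels}->{self.out_channels}x{self.group.order}, "
            f"k={self.kernel_size}, s={self.stride}, p={self.padding}, {self.group.name})"
        )


class GroupConv2d(Layer):
    """Group-stack to group-stack convolution (regular representation)."""

    def __init__(self, in_channels, out_channels, kernel_size, group: SymmetryGroup,
                 stride=1, padding=0, *, rng):
        super().__init__()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding
        self.group = group
        # fan-in counts the group axis: each output unit sees ic*|G| kernel windows
        fan_in = in_channels * group.order * kernel_size**2
        self.params = {
            "weight": he_normal(
                rng, (out_channels, in_channels, group.order, kernel_size, kernel_size), fan_in
            ),
            "bias": np.zeros(out_channels),
        }

    def forward(self, x, *, train=False, rng=None):
        w_exp = ce.expand_group_kernel(self.params["weight"], self.group)
        b_exp = ce.expand_bias(self.params["bias"], self.group)
        out, self._cache = ce.conv2d_forward(x, w_exp, b_exp, self.stride, self.padding)
        return out

    def backward(self, grad):
        gx, gw_exp, gb_exp = ce.conv2d_backward(grad, self._cache)
        self.grads = {
            "weight": ce.collapse_group_grad(gw_exp, self.group),
            "bias": ce.collapse_bias_grad(gb_exp, self.group),
        }
        return gx

    def describe(self):
        return (
            f"GroupConv2d({self.in_channels}->{self.out_channels} on {self.group.name}, "
            f"k={self.kernel_size}, s={self.stride}, p={self.padding})"
        )


class ReLU(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    def __init__(self, kernel_size, stride=None, padding=0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride if stride is not None else kernel_size
        self.padding = padding

    def forward(self, x, *, train=False, rng=None):
        out, self._cache = ce.maxpool_forward(x, self.kernel_size, self.stride, self.padding)
        return out

    def backward(self, grad):
        return ce.maxpool_backward(grad, self._cache)

    def describe(self):
        return f"MaxPool2d(k={self.kernel_size}, s={self.stride}, p={self.padding})"


class GroupPool(Layer):
    """Max over the group axis of a folded (N, C*|G|, H, W) stack."""

    def __init__(self, group: SymmetryGroup):
        super().__init__()
        self.group = group

    def forward(self, x, *, train=False, rng=None):
        n, cg, h, w = x.shape
        go = self.group.order
        xr = x.reshape(n, cg // go, go, h, w)
        self._arg = xr.argmax(axis=2)
        self._shape = xr.shape
        return np.take_along_axis(xr, self._arg[:, :, None], axis=2)[:, :, 0]

    def backward(self, grad):
        gx = np.zeros(self._shape, dtype=grad.dtype)
        np.put_along_axis(gx, self._arg[:, :, None], grad[:, :, None], axis=2)
        n, c, go, h, w = self._shape
        return gx.reshape(n, c * go, h, w)

    def describe(self):
        return f"GroupPool({self.group.name})"


class Dropout(Layer):
    """Inverted dropout; active only in training mode with an rng supplied."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, *, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask

    def describe(self):
        return f"Dropout({self.rate})"


class Flatten(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features, out_features, *, rng):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        self.params = {
            "weight": he_normal(rng, (out_features, in_features), in_features),
            "bias": np.zeros(out_features),
        }

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return x @ self.params["weight"].T + self.params["bias"]

    def backward(self, grad):
        self.grads = {"weight": grad.T @ self._x, "bias": grad.sum(axis=0)}
        return grad @ self.params["weight"]

    def describe(self):
        return f"Linear({self.in_features}->{self.out_features})"


class Sequential:
    """Ordered layer stack with a single forward/backward pass."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, *, train: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def named_params(self):
        for i, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                yield f"{i}.{type(layer).__name__}.{name}", layer, name, value

    def param_count(self) -> int:
        return sum(layer.param_count() for layer in self.layers)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over a batch; returns (loss, grad wrt logits)."""
    n = logits.shape[0]
    shifted = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    log_probs = shifted - logsumexp
    loss = -log_probs[np.arange(n), labels].mean()
    grad = np.exp(log_probs)
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


class Adam:
    """Adam with the conventional defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, model: Sequential, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for key, layer, name, value in self.model.named_params():
            grad = layer.grads[name]
            m = self._m.setdefault(key, np.zeros_like(value))
            v = self._v.setdefault(key, np.zeros_like(value))
            m += (1 - b1) * (grad - m)
            v += (1 - b2) * (grad * grad - v)
            value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
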