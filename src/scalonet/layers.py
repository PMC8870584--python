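"""Minimal NumPy layer library backing the scalogram classifier.

Implements exactly the building blocks the architecture needs — 2-D "same"
convolution, ReLU, 2x2 max pooling, dense layers and a softmax/cross-entropy
head — with explicit forward/backward passes so the training loop and
Grad-CAM can share one computational core.  Convolutions use an im2col +
matrix-multiply formulation; everything is single-threaded NumPy and
deterministic for a fixed seed.

Array convention: batches are (N, C, H, W); dense activations (N, features).
Weights initialise He-uniform (fan-in), biases at zero.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "ReLU",
    "MaxPool2x2",
    "Flatten",
    "Dense",
    "Network",
    "softmax",
    "softmax_cross_entropy",
]


def _he_uniform(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base class: stateless unless it carries parameters."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def output_shape(self, in_shape: tuple) -> tuple:
        raise NotImplementedError


class Conv2D(Layer):
    """2-D convolution with "same" zero padding and unit stride.

    Forward, weight gradient and input gradient are all expressed as einsum
    contractions over a sliding-window view of the zero-padded input, which
    avoids materializing an im2col matrix.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float64) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        self.W = _he_uniform(rng, (out_channels, in_channels, kernel_size,
                                   kernel_size), fan_in, dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._cache = None
        #: set True (by the trainer) for the lowest parameterized layer,
        #: whose input gradient nothing below consumes
        self.skip_input_grad = False

    def _windows(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel_size
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) strided view
        return np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        win = self._windows(x.astype(self.W.dtype, copy=False))
        out = np.einsum("nchwij,ocij->nohw", win, self.W, optimize=True)
        out += self.b[None, :, None, None]
        self._cache = win if train else None
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        win = self._cache
        self.grads[0][...] = np.einsum("nchwij,nohw->ocij", win, grad_out,
                                       optimize=True)
        self.grads[1][...] = grad_out.sum(axis=(0, 2, 3))
        if self.skip_input_grad:
            return grad_out  # placeholder; nothing below consumes it
        # dx = full correlation of the padded output gradient with the
        # spatially flipped kernel, summed over output channels
        k = self.kernel_size
        p = k // 2
        gp = np.pad(grad_out, ((0, 0), (0, 0), (p, p), (p, p)))
        gwin = np.lib.stride_tricks.sliding_window_view(gp, (k, k), axis=(2, 3))
        w_flip = self.W[:, :, ::-1, ::-1]
        return np.einsum("nohwij,ocij->nchw", gwin, w_flip, optimize=True)

    def output_shape(self, in_shape: tuple) -> tuple:
        c, h, w = in_shape
        return (self.out_channels, h, w)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        self._mask = x > 0 if train else None
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask

    def output_shape(self, in_shape: tuple) -> tuple:
        return in_shape


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2, no padding (odd trailing rows/cols dropped)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
        out = xt.max(axis=(3, 5))
        if train:
            self._mask = xt == out[:, :, :, None, :, None]
            self._in_shape = (n, c, h, w)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        h2, w2 = h // 2, w // 2
        # ties (rare with float activations) split the gradient
        counts = self._mask.sum(axis=(3, 5), keepdims=True)
        g = (self._mask / counts) * grad_out[:, :, :, None, :, None]
        dx = np.zeros((n, c, h, w), dtype=grad_out.dtype)
        dx[:, :, : h2 * 2, : w2 * 2] = g.reshape(n, c, h2 * 2, w2 * 2)
        return dx

    def output_shape(self, in_shape: tuple) -> tuple:
        c, h, w = in_shape
        return (c, h // 2, w // 2)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._in_shape)

    def output_shape(self, in_shape: tuple) -> tuple:
        return (int(np.prod(in_shape)),)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float64) -> None:
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.W = _he_uniform(rng, (out_features, in_features), in_features, dtype)
        self.b = np.zeros(out_features, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.skip_input_grad = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x if train else None
        return x.astype(self.W.dtype, copy=False) @ self.W.T + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.grads[0][...] = grad_out.T @ self._x
        self.grads[1][...] = grad_out.sum(axis=0)
        if self.skip_input_grad:
            return grad_out
        return grad_out @ self.W

    def output_shape(self, in_shape: tuple) -> tuple:
        return (self.out_features,)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient with respect to the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


class Network:
    """An ordered stack of layers with shared forward/backward machinery."""

    def __init__(self, layers: list[Layer], n_classes: int,
                 input_shape: tuple) -> None:
        self.layers = layers
        self.n_classes = n_classes
        self.input_shape = input_shape  # (C, H, W)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray, stop_after: int = 0) -> np.ndarray:
        """Backpropagate from the logits; returns the gradient flowing out of
        ``layers[stop_after]`` (i.e. with respect to that layer's output when
        stopping early, or the input gradient for ``stop_after=0``)."""
        for i in range(len(self.layers) - 1, stop_after - 1, -1):
            grad = self.layers[i].backward(grad)
        return grad

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def first_param_layer_index(self) -> int:
        """Index of the lowest layer that carries trainable parameters."""
        for i, layer in enumerate(self.layers):
            if layer.params:
                return i
        raise ValueError("network has no trainable parameters")

    def forward_from(self, layer_index: int, activation: np.ndarray) -> np.ndarray:
        """Run the tail of the network given the output of ``layers[layer_index]``."""
        x = activation
        for layer in self.layers[layer_index + 1:]:
            x = layer.forward(x, train=False)
        return x

    def activation_gradient(self, x: np.ndarray, class_index: int,
                            layer_index: int, wrt: str = "logit"):
        """Activation A at ``layers[layer_index]`` and d(score_c)/dA.

        ``wrt="logit"`` takes the class score as the pre-softmax logit;
        ``wrt="probability"`` differentiates through the softmax.
        """
        a = x
        for layer in self.layers[: layer_index + 1]:
            a = layer.forward(a, train=True)
        logits = a
        for layer in self.layers[layer_index + 1:]:
            logits = layer.forward(logits, train=True)
        if not 0 <= class_index < self.n_classes:
            raise ValueError(
                f"class_index {class_index} out of range for {self.n_classes} classes"
            )
        if wrt == "logit":
            grad = np.zeros_like(logits)
            grad[:, class_index] = 1.0
        elif wrt == "probability":
            p = softmax(logits)
            grad = -p[:, [class_index]] * p
            grad[:, class_index] += p[:, class_index]
        else:
            raise ValueError("wrt must be 'logit' or 'probability'")
        for i in range(len(self.layers) - 1, layer_index, -1):
            grad = self.layers[i].backward(grad)
        return a, grad, logits

    def parameters(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params]
        if len(flat) != len(weights):
            raise ValueError("weight list does not match network parameters")
        for p, w in zip(flat, weights):
            p[...] = w

    def sgd_step(self, lr: float, momentum: float = 0.0,
                 velocities: list | None = None):
        if momentum and velocities is None:
            velocities = [np.zeros_like(p) for p, _ in self.parameters()]
        for i, (p, g) in enumerate(self.parameters()):
            if momentum:
                velocities[i] = momentum * velocities[i] - lr * g
                p += velocities[i]
            else:
                p -= lr * g
        return velocities
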