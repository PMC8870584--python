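"""The 20-layer scalogram CNN: specification, construction, training, inference.

The reference architecture takes one 128x128 grayscale tile and stacks three
convolutional blocks — 4 conv layers 11x11 at depth 32, 4 at 9x9/64, 4 at
7x7/128, each conv followed by ReLU and each block closed by a 2x2 max pool —
then a fully connected ReLU head of widths 128, 64, 32, 16 and a final
softmax layer over the classes.  The spatial chain is 128 -> 64 -> 32 -> 16,
so the final feature map entering the head is 16x16x128.  Counting the 12
convolutions, 3 pools and 5 fully connected layers gives the advertised 20
layers (the input layer and the elementwise ReLUs are not counted; the
mapping is emitted by :func:`describe`).

Training is plain stochastic gradient descent on the softmax cross-entropy
(defaults: batch size 50, learning rate 1e-5, 40 epochs), with fresh
He-uniform weights per model and full determinism under a fixed seed.
Reduced-scale variants of the same three-block topology are available via
:meth:`CnnSpec.reduced` for experiments that must run in minutes on a CPU.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .layers import (
    Conv2D,
    Dense,
    Flatten,
    MaxPool2x2,
    Network,
    ReLU,
    softmax_cross_entropy,
)

__all__ = [
    "ConvBlock",
    "CnnSpec",
    "TrainConfig",
    "build_cnn",
    "describe",
    "train",
    "predict_proba",
    "predict",
    "decide",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ConvBlock:
    """One convolutional block: ``n_convs`` same-padded conv+ReLU layers of
    ``depth`` feature maps with square ``kernel_size`` kernels, then a 2x2
    max pool."""

    kernel_size: int
    depth: int
    n_convs: int = 4


@dataclass(frozen=True)
class CnnSpec:
    """Architecture description; the default is the reference 20-layer net.

    ``stem_pools`` prepends that many 2x2 max-pool layers before the first
    block, downsampling the input; it is 0 in the reference network and is
    used by the reduced preset to cut the cost of full-resolution
    convolutions on a CPU.
    """

    input_size: int = 128
    in_channels: int = 1
    blocks: tuple[ConvBlock, ...] = (
        ConvBlock(11, 32, 4),
        ConvBlock(9, 64, 4),
        ConvBlock(7, 128, 4),
    )
    head: tuple[int, ...] = (128, 64, 32, 16)
    stem_pools: int = 0

    def __post_init__(self) -> None:
        size = self.input_size
        for _ in range(self.stem_pools):
            if size % 2 != 0:
                raise ValueError("stem pooling must halve the input cleanly")
            size //= 2
        for b in self.blocks:
            if b.kernel_size % 2 != 1:
                raise ValueError("conv kernels must be odd for same padding")
            if size % 2 != 0:
                raise ValueError(
                    f"spatial size {size} not divisible by 2 before pooling; "
                    "the pooling chain must halve cleanly"
                )
            size //= 2
        if not self.head:
            raise ValueError("head must contain at least one dense layer")

    @property
    def final_spatial(self) -> int:
        return self.input_size // (2 ** (len(self.blocks) + self.stem_pools))

    @property
    def final_feature_shape(self) -> tuple[int, int, int]:
        """(depth, h, w) of the feature map entering the dense head."""
        return (self.blocks[-1].depth, self.final_spatial, self.final_spatial)

    @classmethod
    def reduced(cls) -> "CnnSpec":
        """Scaled-down preset sharing the three-block topology (one conv per
        block, depths 4/8/16, small kernels, a 2x downsampling stem) for
        CPU-budget experiments."""
        return cls(
            blocks=(ConvBlock(5, 4, 1), ConvBlock(5, 8, 1), ConvBlock(3, 16, 1)),
            head=(32, 16),
            stem_pools=1,
        )


@dataclass
class TrainConfig:
    """Optimization regime; defaults follow the reference setup."""

    batch_size: int = 50
    learning_rate: float = 1e-5
    epochs: int = 40
    momentum: float = 0.0
    seed: int = 0
    shuffle: bool = True
    dtype: str = "float64"


def build_cnn(
    spec: CnnSpec | None = None,
    n_classes: int = 2,
    seed: int = 0,
    dtype: str = "float64",
    allow_any_n_classes: bool = False,
) -> Network:
    """Construct an initialized network from a :class:`CnnSpec`.

    Weight initialization is He-uniform, seeded and deterministic; biases
    start at zero.  ``n_classes`` outside {2, 3} requires
    ``allow_any_n_classes=True`` (a warning is still emitted).
    """
    if spec is None:
        spec = CnnSpec()
    if n_classes not in (2, 3):
        if not allow_any_n_classes:
            raise ValueError(
                f"n_classes must be 2 or 3 (got {n_classes}); pass "
                "allow_any_n_classes=True to override"
            )
        warnings.warn(f"building a {n_classes}-class head outside the usual 2/3")
    np_dtype = np.dtype(dtype)
    rng = np.random.default_rng(seed)
    layers = []
    for _ in range(spec.stem_pools):
        layers.append(MaxPool2x2())
    in_c = spec.in_channels
    for block in spec.blocks:
        for _ in range(block.n_convs):
            layers.append(Conv2D(in_c, block.depth, block.kernel_size, rng, np_dtype))
            layers.append(ReLU())
            in_c = block.depth
        layers.append(MaxPool2x2())
    layers.append(Flatten())
    in_f = int(np.prod(spec.final_feature_shape))
    for width in spec.head:
        layers.append(Dense(in_f, width, rng, np_dtype))
        layers.append(ReLU())
        in_f = width
    layers.append(Dense(in_f, n_classes, rng, np_dtype))
    net = Network(layers, n_classes, (spec.in_channels, spec.input_size, spec.input_size))
    net.spec = spec
    return net


def describe(net: Network) -> dict:
    """Per-layer audit of the network: output shapes and the layer-counting
    convention (conv + pool + fully connected = the advertised total; input
    and activation layers are not counted)."""
    rows = []
    shape = net.input_shape
    counts = {"conv": 0, "pool": 0, "fully_connected": 0}
    for layer in net.layers:
        shape = layer.output_shape(shape)
        kind = type(layer).__name__
        row = {"layer": kind, "output_shape": tuple(shape)}
        if isinstance(layer, Conv2D):
            counts["conv"] += 1
            row.update(kernel=layer.kernel_size, depth=layer.out_channels,
                       padding="same")
        elif isinstance(layer, MaxPool2x2):
            counts["pool"] += 1
            row.update(kernel=2, padding="none")
        elif isinstance(layer, Dense):
            counts["fully_connected"] += 1
            row.update(width=layer.out_features)
        rows.append(row)
    return {
        "layers": rows,
        "counts": counts,
        "counted_layers": sum(counts.values()),
        "n_classes": net.n_classes,
        "final_feature_shape": getattr(net, "spec", None)
        and net.spec.final_feature_shape,
    }


def _as_batch(images: np.ndarray, net: Network, dtype) -> np.ndarray:
    x = np.asarray(images, dtype=dtype)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = x[:, None, :, :]
    expected = net.input_shape
    if x.shape[1:] != expected:
        raise ValueError(
            f"tiles of shape {x.shape[1:]} do not match the network input "
            f"{expected}"
        )
    return x


def train(
    net: Network,
    images: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig | None = None,
) -> pd.DataFrame:
    """Train in place with mini-batch SGD; returns the per-epoch history.

    Mini-batches are reshuffled each epoch from a seeded stream; the final
    short batch is used rather than dropped.  Raises on a single-class
    training set and on a non-finite loss (naming the epoch).
    """
    if config is None:
        config = TrainConfig()
    labels = np.asarray(labels, dtype=np.int64)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError(
            f"training set contains a single class ({classes.tolist()}); "
            "at least two are required"
        )
    if labels.max() >= net.n_classes or labels.min() < 0:
        raise ValueError(
            f"labels must lie in [0, {net.n_classes}), got range "
            f"[{labels.min()}, {labels.max()}]"
        )
    dtype = np.dtype(config.dtype)
    x = _as_batch(images, net, dtype)
    n = x.shape[0]
    rng = np.random.default_rng(config.seed)
    velocities = None
    history = []
    # nothing below the lowest parameterized layer consumes an input
    # gradient, so backprop stops there
    stop_at = net.first_param_layer_index()
    net.layers[stop_at].skip_input_grad = True
    try:
        for epoch in range(config.epochs):
            order = rng.permutation(n) if config.shuffle else np.arange(n)
            epoch_loss = 0.0
            correct = 0
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                logits = net.forward(x[idx], train=True)
                loss, dlogits = softmax_cross_entropy(logits, labels[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch + 1}; "
                        "reduce the learning rate"
                    )
                net.backward(dlogits.astype(dtype, copy=False),
                             stop_after=stop_at)
                velocities = net.sgd_step(config.learning_rate,
                                          config.momentum, velocities)
                epoch_loss += loss * idx.size
                correct += int((logits.argmax(axis=1) == labels[idx]).sum())
            history.append(
                {
                    "epoch": epoch + 1,
                    "loss": epoch_loss / n,
                    "accuracy": correct / n,
                }
            )
    finally:
        net.layers[stop_at].skip_input_grad = False
    return pd.DataFrame(history)


def predict_proba(net: Network, images: np.ndarray,
                  batch_size: int = 256) -> np.ndarray:
    """Class probabilities for a stack of tiles (batched for memory)."""
    x = _as_batch(images, net, net.layers[0].W.dtype
                  if hasattr(net.layers[0], "W") else np.float64)
    out = [net.predict_proba(x[i : i + batch_size])
           for i in range(0, x.shape[0], batch_size)]
    return np.concatenate(out, axis=0)


def decide(probs: np.ndarray, threshold: float | None = 0.5) -> np.ndarray:
    """Turn probability rows into labels.

    Binary: label 1 iff P(class 1) >= threshold (ties go to the positive
    class).  Multi-class (or ``threshold=None``): argmax with lowest-index
    tie-break.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    if probs.shape[1] == 2 and threshold is not None:
        if not 0.0 <= threshold <= 1.0:
            raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
        return (probs[:, 1] >= threshold).astype(np.int64)
    return probs.argmax(axis=1).astype(np.int64)


def predict(net: Network, images: np.ndarray,
            threshold: float | None = 0.5) -> np.ndarray:
    """Predicted labels in {0, 1, 2} for a stack of tiles."""
    return decide(predict_proba(net, images), threshold)


def save_checkpoint(net: Network, path: str | Path) -> None:
    """Serialize weights (npz) plus a JSON architecture descriptor."""
    path = Path(path).with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    weights = {f"w{i}": w for i, w in enumerate(net.get_weights())}
    np.savez(path, **weights)
    spec = getattr(net, "spec", None)
    desc = {
        "n_classes": net.n_classes,
        "input_shape": list(net.input_shape),
        "spec": asdict(spec) if spec is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(desc, indent=2))


def load_checkpoint(path: str | Path) -> Network:
    path = Path(path).with_suffix(".npz")
    desc_path = path.with_suffix(".json")
    if not path.exists() or not desc_path.exists():
        raise FileNotFoundError(f"checkpoint pair not found at {path}")
    desc = json.loads(desc_path.read_text())
    spec_d = desc["spec"]
    spec = CnnSpec(
        input_size=spec_d["input_size"],
        in_channels=spec_d["in_channels"],
        blocks=tuple(ConvBlock(**b) for b in spec_d["blocks"]),
        head=tuple(spec_d["head"]),
        stem_pools=spec_d.get("stem_pools", 0),
    )
    net = build_cnn(spec, n_classes=desc["n_classes"], seed=0,
                    allow_any_n_classes=True)
    with np.load(path) as data:
        net.set_weights([data[f"w{i}"] for i in range(len(data.files))])
    return net
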